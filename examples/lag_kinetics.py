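"""Lag-phase analysis of simulated assembly-then-hydrolysis kinetics.

Simulates phosphate release for a GTPase that must hexamerise before it
can turn over, at four enzyme concentrations with the accessory subunit in
a fixed 4:1 ratio, then runs the straight-line lag analysis.  The
mechanistic signature that complete assembly precedes hydrolysis: the
per-enzyme steady-state rate is concentration-independent while the
apparent initiation rate (1/lag) rises with concentration.
"""

from oligoring import kinetics as kin
from oligoring.simulate import (
    AssemblyParams,
    McrCCoupling,
    simulate_assembly,
    simulate_pi_trace,
)

traces = []
for conc in (0.25, 0.5, 1.0, 2.0):
    params = AssemblyParams(mcrC_coupling=McrCCoupling())
    state = simulate_assembly(params, conc, total_mcrC=conc / 4,
                              t_end=120, n_points=500)
    traces.append(simulate_pi_trace(state, noise_sd_um=0.01 * state.pi[-1],
                                    seed=1))

print(f"{'[McrB] uM':>10} {'rate uM/s':>10} {'per-enzyme /s':>14} "
      f"{'lag s':>8} {'initiation /s':>14}")
for trace in traces:
    fit = kin.lag_fit(trace)
    print(f"{trace.mcrB_conc_um:>10.2f} {fit.steady_state_rate:>10.3f} "
          f"{fit.per_enzyme_rate:>14.3f} {fit.relaxation_time:>8.2f} "
          f"{fit.initiation_rate:>14.4f}")

res = kin.analyze_series(traces)
print(f"\nper-enzyme rate CV: {res.per_enzyme_rate_cv:.3f}")
print(f"initiation rate strictly increasing: {res.initiation_strictly_increasing}")

print()
print("A small CV with monotonically rising initiation rates says the")
print("hydrolysing unit is identical at every concentration and only the")
print("mass-action assembly step speeds up — oligomerisation comes first.")
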