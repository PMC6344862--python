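"""Mass-action model of nucleotide-driven ring assembly and hydrolysis.

The scheme encodes the working hypothesis that complete oligomerisation
precedes steady-state NTP hydrolysis:

    B   -> B*          nucleotide binding, pseudo-first-order k_bind
                       (NTP saturating; depletion not modelled)
    B*  -> B           nucleotide release, k_unbind
    B* + B* -> O2      nucleation, k_assoc
    O_i + B* -> O_i+1  stepwise growth, k_assoc   (i = 2 .. n-1)
    O_i -> O_i-1 + B*  stepwise loss, k_dissoc    (O2 -> 2 B*)
    O_n + C <-> O_nC   accessory-subunit binding, k_on_C / k_off_C
    O_n  -> O_n  + n Pi * k_cat            only the complete ring hydrolyses
    O_nC -> O_nC + n Pi * k_cat * stim     accessory subunit stimulates

Only nucleotide-loaded monomers polymerise; growth is strictly
monomer-by-monomer; no ring-ring joins.  These are modelling choices — the
minimal scheme consistent with a hydrolysis lag caused by assembly — not
measured mechanism.  All rate constants are invented simulator plumbing;
no kinetic scheme with fitted constants exists for this system.

Concentrations are in uM, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["McrCCoupling", "AssemblyParams", "SimState", "simulate_assembly"]


@dataclass(frozen=True)
class McrCCoupling:
    """Accessory (endonuclease) subunit binding to the complete ring."""

    k_on_c: float = 10.0  # 1/uM/s
    k_off_c: float = 0.001  # 1/s; tight binding, near-stoichiometric
    stimulation_factor: float = 10.0  # fold increase of per-subunit k_cat

    def __post_init__(self) -> None:
        if self.k_on_c < 0 or self.k_off_c < 0:
            raise ValueError("coupling rates must be non-negative")
        if self.stimulation_factor < 1:
            raise ValueError("stimulation_factor must be >= 1")


@dataclass(frozen=True)
class AssemblyParams:
    """Rate constants of the binding -> hexamerisation -> hydrolysis scheme."""

    n_ring: int = 6
    k_bind: float = 5.0  # 1/s, pseudo-first-order at saturating nucleotide
    k_unbind: float = 0.5  # 1/s
    k_assoc: float = 10.0  # 1/uM/s, per growth step
    k_dissoc: float = 0.1  # 1/s, per shrink step
    k_cat: float = 1.0  # 1/s per subunit of a complete ring
    ring_closure_factor: float = 1e-3  # scales k_dissoc for opening a complete ring
    mcrC_coupling: Optional[McrCCoupling] = None
    trp_enhancement: float = 0.20  # fractional gain of nucleotide-loaded subunits

    def __post_init__(self) -> None:
        if self.n_ring < 2:
            raise ValueError("n_ring must be >= 2")
        for name in ("k_bind", "k_unbind", "k_assoc", "k_dissoc", "k_cat",
                     "ring_closure_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.trp_enhancement < 0:
            raise ValueError("trp_enhancement must be non-negative")


@dataclass
class SimState:
    """Integrated trajectory of the assembly scheme.

    Species (uM): apo monomer ``b``, nucleotide-loaded monomer ``b_star``,
    intermediates ``oligomers[:, i]`` = O_{i+2} for i = 0 .. n-2 (the last
    column is the complete ring O_n), accessory-bound ring ``ring_c``,
    free accessory subunit ``mcrC``, released phosphate ``pi``.
    """

    time_s: np.ndarray
    b: np.ndarray
    b_star: np.ndarray
    oligomers: np.ndarray  # shape (n_t, n_ring - 1)
    ring_c: np.ndarray
    mcrC: np.ndarray
    pi: np.ndarray
    params: AssemblyParams = field(repr=False, default=None)
    total_monomer: float = 0.0
    total_mcrC: float = 0.0

    @property
    def ring(self) -> np.ndarray:
        """Complete-ring concentration O_n (uM)."""
        return self.oligomers[:, -1]

    def subunit_total(self) -> np.ndarray:
        """B + B* + sum_i i*O_i + n*O_nC at every time point (uM)."""
        n = self.params.n_ring
        sizes = np.arange(2, n + 1)
        return (
            self.b
            + self.b_star
            + self.oligomers @ sizes.astype(float)
            + n * self.ring_c
        )

    def loaded_fraction(self) -> np.ndarray:
        """Fraction of subunits carrying nucleotide (monomeric or oligomeric)."""
        total = self.subunit_total()
        loaded = total - self.b
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, loaded / total, 0.0)

    def assembled_fraction(self) -> np.ndarray:
        """Fraction of subunits residing in complete rings (free or bound)."""
        n = self.params.n_ring
        total = self.subunit_total()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, n * (self.ring + self.ring_c) / total, 0.0)


def _rhs(t, y, p: AssemblyParams, coupled: bool):
    n = p.n_ring
    b, b_star = y[0], y[1]
    olig = y[2 : 2 + (n - 1)]  # O_2 .. O_n
    ring_c = y[2 + (n - 1)]
    mcrC = y[3 + (n - 1)]

    dy = np.zeros_like(y)
    # nucleotide binding / release
    bind = p.k_bind * b
    unbind = p.k_unbind * b_star
    dy[0] = -bind + unbind
    dy[1] = bind - unbind

    # nucleation: 2 B* -> O2; the reverse of the final association step is
    # ring opening, slowed by ring_closure_factor (closing the ring forms
    # two interfaces at once and is strongly stabilised)
    nucl = p.k_assoc * b_star * b_star
    denucl = p.k_dissoc * (p.ring_closure_factor if n == 2 else 1.0) * olig[0]
    dy[1] += -2.0 * nucl + 2.0 * denucl
    dy[2] += nucl - denucl

    # growth/shrink: O_i + B* <-> O_{i+1}, i = 2 .. n-1
    for j in range(0, n - 2):  # olig[j] = O_{j+2}
        grow = p.k_assoc * olig[j] * b_star
        k_rev = p.k_dissoc * (p.ring_closure_factor if j == n - 3 else 1.0)
        shrink = k_rev * olig[j + 1]
        dy[1] += -grow + shrink
        dy[2 + j] += -grow + shrink
        dy[2 + j + 1] += grow - shrink

    # accessory binding to the complete ring
    if coupled:
        c = p.mcrC_coupling
        on = c.k_on_c * olig[-1] * mcrC
        off = c.k_off_c * ring_c
        dy[2 + (n - 2)] += -on + off
        dy[2 + (n - 1)] += on - off
        dy[3 + (n - 1)] += -on + off
        stim = c.stimulation_factor
    else:
        stim = 1.0

    # phosphate release: every subunit of a complete ring hydrolyses
    dy[-1] = n * p.k_cat * (olig[-1] + stim * ring_c)
    return dy


def simulate_assembly(
    params: AssemblyParams,
    total_monomer: float,
    total_mcrC: float = 0.0,
    t_end: float = 60.0,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimState:
    """Integrate the assembly scheme and return the trajectory.

    ``total_monomer`` and ``total_mcrC`` are initial apo concentrations in
    uM.  The integrator is stiff-aware (LSODA); a failure to converge names
    the stiffest rate constant to point at the culprit.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if total_monomer < 0 or total_mcrC < 0:
        raise ValueError("concentrations must be non-negative")
    coupled = params.mcrC_coupling is not None and total_mcrC > 0

    n = params.n_ring
    y0 = np.zeros(2 + (n - 1) + 2 + 1)
    y0[0] = total_monomer
    y0[3 + (n - 1)] = total_mcrC
    t_eval = np.linspace(0.0, t_end, n_points)

    sol = solve_ivp(
        _rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        args=(params, coupled),
    )
    if not sol.success:
        rates = {
            "k_bind": params.k_bind,
            "k_unbind": params.k_unbind,
            "k_assoc*[monomer]": params.k_assoc * total_monomer,
            "k_dissoc": params.k_dissoc,
            "k_cat": params.k_cat,
        }
        stiffest = max(rates, key=rates.get)
        raise RuntimeError(
            f"assembly ODE integration failed ({sol.message}); "
            f"stiffest rate is {stiffest} = {rates[stiffest]:g}/s"
        )

    y = sol.y
    # tiny negative excursions from the integrator are clipped to zero
    y = np.where((y < 0) & (y > -10 * atol - 1e-15), 0.0, y)
    return SimState(
        time_s=sol.t,
        b=y[0],
        b_star=y[1],
        oligomers=y[2 : 2 + (n - 1)].T.copy(),
        ring_c=y[2 + (n - 1)],
        mcrC=y[3 + (n - 1)],
        pi=y[-1],
        params=params,
        total_monomer=total_monomer,
        total_mcrC=total_mcrC,
    )
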