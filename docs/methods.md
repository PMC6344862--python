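# Methods

This note records the models behind each analysis stage, the simulator
that generates their inputs, the defaults and why they were chosen, and
what the synthetic tests do and do not demonstrate about real data.

## Gel-filtration calibration

The partition coefficient K<sub>av</sub> = (V<sub>e</sub> − V<sub>o</sub>)/(V<sub>t</sub> − V<sub>o</sub>)
is regressed (ordinary least squares) on log₁₀(mass/kDa).  The base of the
logarithm is a pure reporting convention — apparent masses are identical in
any base — and base 10 is fixed so that slope/intercept values are
reproducible.  K<sub>av</sub> outside [0, 1] (oligomer peaks near the void
volume) warns and extrapolates rather than failing, because sizing
near-void peaks, however badly, is exactly what users do before turning to
absolute methods.  Peak apexes are localised by a three-point parabola so
V<sub>e</sub> does not quantise to the volume grid.

The module reports its own fit statistics.  For the bundled five-standard
set the OLS R² is 0.971; vendor-software values reported for nominally the
same standards are not reproducible from the printed points alone and are
not asserted anywhere.  SEC masses are shape-biased; the package treats
them as a triage step before MALS/SAXS.

## SEC-MALS and DLS

Per elution slice, concentration comes from the excess refractive index
via dn/dc (default 0.186 × 10⁻³ per mg/ml, the standard protein value) and
mass from the Debye plot in the Zimm form: K\*c/R(θ) against sin²(θ/2),
intercept 1/M, with slope/intercept = (16π²/3λ²)R<sub>g</sub>².  λ is the
in-medium wavelength — vacuum wavelength (default 658 nm) divided by the
solvent refractive index (1.33, aqueous buffer) — on both the generator
and analyser sides, so noiseless round trips are exact.  The instrument
constant K\* maps raw counts to Rayleigh ratios and is carried
symmetrically; absolute (toluene-standard) calibration is out of scope.
The Zimm model is used at single concentration (flow mode), with no
second-virial extrapolation.  Slices below 1% of the apex concentration
are excluded from region averages since per-slice mass diverges as c → 0.
Fitted slopes at or below numerical zero report R<sub>g</sub> = 0
(isotropic point scatterer).

DLS autocorrelations are fitted with the single-exponential Siegert form
g₂(τ) = 1 + β exp(−2Dq²τ) — a first-order-cumulant stand-in for vendor
analyses; multimodal decays are out of scope.  Stokes–Einstein uses
k<sub>B</sub> = 1.380649 × 10⁻²³ J/K and a default viscosity of
9.3 × 10⁻⁴ Pa·s (9.3 × 10⁻³ P, a measured aqueous-buffer value).

## SAXS

The Guinier window is chosen iteratively with the straight-line rule:
fit ln I on q², compute R<sub>g</sub>, move the upper limit to the last
point with q·R<sub>g</sub> ≤ 1.3, repeat to a fixed point (period-2 cycles
take the tighter window).  The *reported* R<sub>g</sub> and I₀ then come
from a quadratic-in-q² refit on that window: over a finite window the pure
straight line carries a systematic ~2% overestimate on compact globular
particles (ln I curves beyond second order), while the quadratic's linear
coefficient estimates the true q² → 0 slope to ~0.1% on sphere oracles.
Weights are 1/σ² when an uncertainty column is present.  A positive
ln I-vs-q² slope (no Guinier regime) is an explicit error.

The high-q truncation point is the smallest q at which a 5-point
moving-median-smoothed intensity falls to I₀/10²·²⁵ (≈ 1/178); the median
filter buys robustness to counting noise.  The Porod invariant
Q = ∫q²I dq is computed by trapezoid after extending the curve to q = 0
with the Guinier model, V = 2π²I₀/Q, and mass uses the common protein
approximation 1.66 Å³/Da.  No vendor correction polynomial is applied, so
volume-route masses validate against analytic sphere oracles rather than
instrument outputs.  Note the truncation direction: cutting the invariant
integral short *inflates* V (and hence mass), and mass decreases
monotonically as q_max grows.  All q are Å⁻¹ internally; nm⁻¹ input is
rescaled at read time via a units flag.

Percent mass difference is reported as 100·(calculated − measured)/calculated
to one decimal, positive when the scattering-derived mass underestimates.

## Stoichiometry

Composition inference is deliberately brute force: enumerate counts
(default 0–16 per subunit, or user constraints such as "multiples of 6"
or an explicit set like {0, 1, 2}), rank by |percent difference| with
ties broken toward fewer subunits.  The ring size is configuration, never
hard-coded — the hexamer-vs-heptamer question is the reason the module
exists.  Reported masses round to 3 significant figures (the usual kDa
precision); exact values are retained.  The 720 kDa worked example shows
why the geometric constraint is load-bearing: unconstrained arithmetic
ranks compositions no ring geometry can realise above the
two-hexamers-plus-two-endonuclease answer.

## Lag-phase kinetics

Calibration: a linear standard curve whose linear range is found by
iteratively dropping the top concentration while a quadratic-vs-linear
lack-of-fit F-test is significant (α = 0.01) — saturating detectors bend
downward.  Calibrated points mapping outside the linear range are flagged,
not dropped.  Blank subtraction is the caller's responsibility (the CLI
offers `--blank`).

The lag analysis fits a straight line to the steady-state phase.  The
window policy is explicit and recorded: the terminal slope is estimated on
the final 40% of points and the window extends backwards while a 5-point
local slope stays within 5% of it.  On any trace whose tail is exactly
affine this is machine-precision exact regardless of the policy knobs.
Reported quantities: slope (µM Pi/s), X-intercept (relaxation/lag time, s;
clamped to 0 with a warning for burst-like traces), its reciprocal
(apparent initiation rate, 1/s), and slope/[enzyme] (per-enzyme rate) —
both rate normalisations are always reported.  The concentration-series
test requires ≥ 3 concentrations at a fixed subunit ratio (default 4:1)
and uses exact rank agreement (Spearman ρ = 1) for the
initiation-monotonicity flag: distribution-free and appropriate for short
series.  Single-exponential misfit is diagnosed by a Wald–Wolfowitz runs
test on residual signs; sequential-assembly signals leave serially
correlated residuals that the test flags.

## 2D rotational symmetry

Images are resampled bilinearly on polar coordinates about the ring
centre (256 angles per 1-pixel radial step), the angular Fourier power of
each ring is summed over an annular band with radius weighting, and the
spectrum is normalised by the order-0 power — making it exactly invariant
to global intensity scaling and, to interpolation tolerance, to image
rotation.  The default band [12.5, 47.5] Å covers pore radius to outer
radius of a ~95 Å ring with a <25 Å pore and is overridable, since band
choice dominates sensitivity.  Centres are estimated by intensity centroid
refined on a ±2 px grid maximising the variance of the circular-average
radial profile (a decentred ring smears its annulus).  Detection requires
the winning order to carry ≥ 10⁻³ of the order-0 power (a uniform ring has
essentially none) and ≥ 3× the median power of the other candidates, with
the winner's harmonics excluded from that denominator.  Fuzzy or
asymmetric particles fail the test and return None — the honest answer
for heterogeneous class averages.  Only relative peak structure is
interpreted; absolute normalisation conventions differ between programs.

## The assembly simulator

The kinetic scheme is the minimal mass-action embodiment of
"assembly precedes hydrolysis":

    B → B*            pseudo-first-order binding k_bind (NTP saturating,
    B* → B            no depletion: mM nucleotide vs sub-µM protein)
    B* + B* ⇌ O₂      nucleation k_assoc / k_dissoc
    Oᵢ + B* ⇌ Oᵢ₊₁    stepwise growth, i = 2..n−1
    Oₙ + C ⇌ OₙC      accessory binding k_on_C / k_off_C
    d[Pi]/dt = n·k_cat·([Oₙ] + stim·[OₙC])

Only nucleotide-loaded monomers polymerise, growth is strictly
monomer-by-monomer, and only the complete ring hydrolyses.  These are
modelling choices, not measured mechanism; no fitted rate constants exist
for this system and all defaults are invented simulator plumbing chosen to
land in a regime a stopped-flow experiment would resolve (lags of tens of
seconds at sub-µM protein):
n_ring 6, k_bind 5 /s, k_unbind 0.5 /s, k_assoc 10 /µM/s, k_dissoc
0.1 /s, k_cat 1 /s per subunit, stimulation 10×.

Two choices deserve emphasis:

* **Ring-closure stabilisation.**  The reverse of the final association
  step is scaled by `ring_closure_factor` (default 10⁻³): closing the ring
  forms two interfaces at once.  Without it a strictly stepwise scheme
  either kinetically traps in partial oligomers (irreversible limit — a
  uniform speed-up of all association rates only rescales time and
  freezes a dimer-rich mixture) or, at equilibrium with uniform step
  constants, retains a large intermediate population, so "complete
  assembly before steady state" would be unreachable at any rate scale.
  With the stabilised ring as a sink, fast reversible steps anneal the
  system to ≈ all-ring, and the terminal hydrolysis rate per monomer
  approaches k_cat — the closed-form check used in the tests.
* **Tight accessory binding.**  k_off_C defaults to 10⁻³ /s so ring–C
  binding is near-stoichiometric at every concentration in a 4:1 ladder;
  with weak binding the bound (stimulated) fraction would vary with
  concentration and the per-enzyme-rate invariance the concentration
  series tests for could not hold even in principle.

The accessory subunit binds only the completed ring; whether it can join
earlier is unknown and deliberately not modelled.  The full
two-ring/two-C architecture is handled only in stoichiometry — no rate
data exist for ring pairing.  Integration uses LSODA at rtol 10⁻⁸ /
atol 10⁻¹²; subunit conservation holds to better than 10⁻⁶ relative in
every test trajectory, and phosphate is non-decreasing.  Integration
failures name the stiffest rate constant.

The tryptophan-like signal is baseline·(1 + enhancement·f(t)) with f the
fraction of nucleotide-loaded subunits and enhancement defaulting to 0.20
(a typical γ-phosphate-dependent fluorescence gain).  Whether such a
signal reports binding, oligomerisation or both is genuinely unresolved
for the real system; loaded-fraction is a declared stand-in, good enough
to generate biphasic traces that misfit a single exponential.

Detector generators mirror their analysers (Gaussian elution peaks on a
uniform volume grid; MALS signals K\*·c·M·P(θ) with the one-term
form-factor expansion; sphere-form-factor SAXS curves with
σ = max(floor, fraction·I); linear standard tables), all with additive
Gaussian noise and integer seeds giving bit-identical repeats.

### What the synthetic tests do and do not show

The generators share their signal models with the analysers, so round-trip
tests demonstrate correctness of the estimators and their numerical
conditioning — not robustness to the pathologies of real data
(band-broadening between detectors, inter-particle interference and
buffer-subtraction errors in SAXS, CTF effects and alignment errors in
class averages, product inhibition or nucleotide depletion in long
kinetic runs).  None of those are modelled, by design.  Problem sizes are
deliberately desk-scale — hundreds of ODE time points, 800-point
scattering curves, 160² images, ≤ 50-seed Monte-Carlo loops — chosen so
the whole suite exercises every stage in seconds.

## Known limitations

* No peak deconvolution of overlapping SEC species; no partitioning
  theory beyond the empirical line.
* No SAXS P(r)/indirect transform, shape reconstruction or buffer
  handling; the V/1.66 mass conversion is approximate by construction.
* No global inverse modelling of the ODE rate constants from data —
  recovery is assessed through lag statistics only.
* No stochastic (Gillespie) simulation; deterministic mass action only.
* Symmetry analysis assumes an approximately axial ("top") view; no
  alignment, CTF or 3D treatment.
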