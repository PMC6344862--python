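# oligoring

Solution-state characterisation of ring-forming AAA+ oligomers.

Many AAA+ NTPases — including the GTP-hydrolysing restriction-enzyme motor
McrB and its endonuclease partner McrC — are active only as oligomeric
rings, and two of the recurring questions about them are *how many subunits
the ring has* (hexamer or heptamer?) and *whether the ring must finish
assembling before steady-state NTP hydrolysis begins*.  `oligoring`
packages the quantitative analyses that answer both from standard
biophysical measurements, together with a mass-action simulator that
generates every input the pipeline consumes, so each stage is testable
end to end.

## What it computes

| Stage | Model / statistic |
| --- | --- |
| `oligoring.sec` | Partition coefficient K<sub>av</sub> = (V<sub>e</sub> − V<sub>o</sub>)/(V<sub>t</sub> − V<sub>o</sub>); OLS line of K<sub>av</sub> vs log₁₀ M; apparent mass by inversion |
| `oligoring.mals` | Debye plot (Zimm form) K\*c/R(θ) vs sin²(θ/2): intercept = 1/M, slope → R<sub>g</sub>; R<sub>h</sub> = k<sub>B</sub>T/(6πηD) |
| `oligoring.saxs` | Guinier fit ln I = ln I₀ − q²R<sub>g</sub>²/3 under the q·R<sub>g</sub> ≤ 1.3 rule; Porod invariant Q = ∫q²I dq, V = 2π²I₀/Q, M ≈ V/1.66 |
| `oligoring.stoichiometry` | Exhaustive composition search under ring-geometry constraints, ranked by \|% difference\| |
| `oligoring.kinetics` | Straight-line lag analysis: steady-state rate = slope, relaxation time = −intercept/slope, initiation rate = its reciprocal; concentration-series invariance test |
| `oligoring.symmetry` | Rotational (angular Fourier) power spectrum of ring images; symmetry order by prominence test |
| `oligoring.simulate` | Mass-action ODE of nucleotide binding → stepwise hexamerisation → hydrolysis, plus detector-signal generators for all stages |

## Worked example

Calibrate a 24 ml gel-filtration column from five standards and size the
monomer peak (this is `examples/sec_calibration.py`):

```python
from oligoring import sec

column = sec.ColumnConstants(vo=8.4, vt=24.0)
standards = [
    sec.CalibrationStandard("beta-amylase", 200.0, 12.3),
    sec.CalibrationStandard("alcohol dehydrogenase", 150.0, 13.3),
    sec.CalibrationStandard("bovine serum albumin", 66.0, 14.3),
    sec.CalibrationStandard("ovalbumin", 43.0, 15.7),
    sec.CalibrationStandard("carbonic anhydrase", 29.0, 16.8),
]
cal = sec.fit_calibration(standards, column)
print(round(sec.apparent_mass(14.85, cal), 1))
```

prints

```
calibration: Kav = -0.3214 * log10(M/kDa) + 0.9936
fit R^2 = 0.9707
monomer peak: Ve = 14.85 ml -> apparent mass 63.8 kDa
```

i.e. the 14.85 ml peak sizes as ~64 kDa — a 54 kDa protein running
slightly large, consistent with a monomer.  The other examples follow the
same pattern: `mals_mass.py` recovers a 325.2 kDa hexamer from a synthetic
18-angle MALS run (prints 324.7 kDa at 1% noise) and a 6.08 nm
hydrodynamic radius from D = 3.86 × 10⁻¹¹ m²/s; `saxs_mass.py` recovers
R<sub>g</sub> = 39.86 Å for a 51.51 Å sphere (analytic 39.90 Å);
`lag_kinetics.py` shows a per-enzyme steady-state rate CV of 0.076 with
strictly rising initiation rates across a 4:1 concentration ladder — the
signature that complete oligomerisation precedes hydrolysis; and
`ring_symmetry.py` reads a noisy 95 Å / 25 Å-pore ring at 1.33 Å/px as
six-fold.

A thin CLI mirrors the library (`oligoring sec-calib`, `mals`, `saxs`,
`stoich`, `kinetics`, `symmetry`, `simulate`); run `oligoring --help`.

## Layout

```
src/oligoring/       library (sec, mals, saxs, stoichiometry, kinetics,
                     symmetry, simulate/, io, cli)
examples/            one narrative script per capability
tests/               pytest suite
docs/methods.md      models, assumptions, parameter choices, limitations
scripts/acceptance.py
```
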