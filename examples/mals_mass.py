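"""Absolute molar mass of a ring oligomer from a synthetic SEC-MALS run.

Generates an 18-angle MALS run for a 325.2 kDa hexamer (6 x 54.2 kDa) with
1% detector noise, Debye-fits every elution slice and reports the
concentration-weighted average mass, plus a hydrodynamic radius from a DLS
diffusion coefficient via Stokes-Einstein.
"""

from oligoring import mals
from oligoring.simulate import make_mals_run

run = make_mals_run(true_mass_kda=325.2, rg_nm=6.0, noise_frac=0.01, seed=42)
profile = mals.mass_profile(run)
mw = mals.weight_average_mass(profile)
print(f"slices analysed: {len(profile.mass_kda)}")
print(f"weight-average mass: {mw:.1f} kDa (generator truth 325.2 kDa)")

r_h = mals.stokes_einstein(3.86e-11, temperature_k=298.15, viscosity_pa_s=9.3e-4)
print(f"hydrodynamic radius for D = 3.86e-11 m^2/s: {r_h:.2f} nm")

print()
print("The Debye-plot mass is shape-independent, so ~325 kDa identifies a")
print("hexamer of a 54.2 kDa subunit; ~6.1 nm is the matching Rh scale.")
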