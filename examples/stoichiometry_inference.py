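"""Infer subunit composition of a 720 kDa complex from monomer masses.

A 54.2 kDa GTPase subunit assembles into hexameric rings; its 40 kDa
endonuclease partner binds in low copy number.  Ranking compositions with
and without the whole-ring constraint shows why the geometric constraint
matters: raw mass arithmetic alone prefers compositions no ring geometry
can realise.
"""

from oligoring.stoichiometry import SubunitSpec, infer_composition, nmer_mass

mcrb = SubunitSpec("McrB", 54.2)
mcrc = SubunitSpec("McrC", 40.0)

print("theoretical ring masses:")
for n in (6, 7):
    print(f"  {n}-mer of McrB: {nmer_mass(mcrb, n)[0]:.0f} kDa")

print("\n720 kDa complex, McrB in whole hexamer units, McrC in 0-2 copies:")
for comp in infer_composition(
    720.0, [mcrb, mcrc],
    constraints={"McrB": {"multiple_of": 6}, "McrC": {0, 1, 2}},
    top_n=3,
):
    counts = ", ".join(f"{n} {name}" for name, n in comp.counts)
    print(f"  {counts}: {comp.total_mass_kda:.1f} kDa "
          f"({comp.percent_difference:+.2f} % vs measured)")

print("\nsame mass, no geometric constraint (top 3):")
for comp in infer_composition(720.0, [mcrb, mcrc], top_n=3):
    counts = ", ".join(f"{n} {name}" for name, n in comp.counts)
    print(f"  {counts}: {comp.total_mass_kda:.1f} kDa "
          f"({comp.percent_difference:+.2f} %)")

print()
print("Under the ring constraint the winner is 12 McrB + 2 McrC (two hexamers")
print("bridged by two McrC) at 730.4 kDa; unconstrained arithmetic ranks")
print("geometrically impossible mixtures higher, which is the cautionary tale.")
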