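"""Hexamer-vs-heptamer discrimination from a 2D ring image.

Renders noisy top views of six- and seven-membered rings (95 A outer
diameter, 25 A pore, 1.33 A/pixel — the geometry of a AAA+ GTPase ring in
cryoEM class averages) and detects the symmetry order from the rotational
power spectrum.
"""

from oligoring.simulate import RingImageSpec, make_ring_image
from oligoring.symmetry import detect_symmetry_order, rotational_power_spectrum

for n_fold in (6, 7, 0):
    spec = RingImageSpec(n_fold=n_fold, noise_sd=0.05, seed=7)
    image = make_ring_image(spec)
    spectrum = rotational_power_spectrum(image, center=image.center)
    order = detect_symmetry_order(spectrum)
    label = f"{n_fold}-fold ring" if n_fold else "uniform ring"
    top = sorted(enumerate(spectrum.normalized[1:], start=1),
                 key=lambda kv: kv[1], reverse=True)[:3]
    peaks = ", ".join(f"n={k}: {v:.3g}" for k, v in top)
    print(f"{label:>13}: detected order = {order}  (top powers {peaks})")

print()
print("The blob count appears as the dominant angular Fourier order; the")
print("uniform ring has no significant peak and honestly reports None —")
print("the same logic that separates a clean hexamer from a fuzzy average.")
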