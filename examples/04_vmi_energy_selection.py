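"""Full knee study: VMIs, conventional image, noise/CNR energy selection.

Runs the whole chain on the synthetic knee (acquisition, decomposition,
reconstruction, VMI synthesis 40-110 keV, merged-bin conventional image)
and prints the image-quality table, the selected optimal energies and
the tissue energy fingerprints.
"""

import kneespec as ks

res = ks.run_knee_study(seed=0)

print("image-quality table (cartilage noise SD in HU, CNR cartilage vs joint space):")
print(res.quality.to_string(index=False, float_format=lambda v: f"{v:8.2f}"))

sel = res.optimal
print(f"\noptimal energy by CNR:   {sel['energy_max_cnr']:.0f} keV")
print(f"optimal energy by noise: {sel['energy_min_noise']:.0f} keV")

fp = res.fingerprints.pivot(index="energy_kev", columns="tissue", values="mean_hu")
print("\ntissue energy fingerprints (mean HU per VMI energy):")
print(fp.to_string(float_format=lambda v: f"{v:8.1f}"))

print("\nEach tissue's attenuation falls with energy at its own rate, so the")
print("curves act as fingerprints; cartilage stays above soft tissue at all")
print("energies, which is what makes unenhanced cartilage imaging feasible.")
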