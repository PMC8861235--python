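"""Build the digital knee phantom and inspect its contents.

The phantom is a stylized axial femoro-patellar section: two bone bodies
(cortical rim + trabecular interior) facing each other across a
fluid-filled joint space, cartilage on both articular surfaces, soft
tissue around, plus planted subchondral cysts and cartilage
calcifications with ground-truth masks.
"""

import numpy as np

import kneespec as ks

phantom = ks.make_knee_phantom(ks.KneePhantomConfig(), seed=0)

print(f"grid: {phantom.shape}, voxel size {phantom.voxel_size} mm")
print("\ntissue inventory (voxels):")
names = {lab: m.name for lab, m in phantom.label_to_material.items()}
for lab, count in zip(*np.unique(phantom.labels, return_counts=True)):
    m = phantom.label_to_material[int(lab)]
    print(f"  {names[int(lab)]:16s} {count:6d}   mu(60 keV) = {m.mu(60.0):.3f} /cm")

n_cysts = int(phantom.truth_masks["cysts"].max())
print(f"\nplanted cysts: {n_cysts} "
      f"({int((phantom.truth_masks['cysts'] > 0).sum())} voxels total)")
print("measurement ROIs:", ", ".join(sorted(phantom.rois)))
print("\nThe label grid drives the simulator; the ROIs reproduce the image-")
print("analysis geometry (noise disc in cartilage, the two CNR lines, the")
print("medial/lateral split) and the truth masks validate segmentation.")
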