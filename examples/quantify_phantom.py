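"""Quantify infarct size on a synthetic LGE stack with known ground truth.

Generates a 9-slice magnitude-IR phantom (90-degree transmural septal
infarct, coil gradient, noise), runs the six-step pipeline with the LAD
extent model, and compares the weighted estimate against the generated
truth.
"""

import ewa

spec = ewa.PhantomSpec(seed=1)
img, seg, ins, truth = ewa.generate(spec)

res = ewa.run_ewa(img, seg, culprit="LAD", insertions=ins)

print(f"true infarct size : {truth.pct_lvm:6.2f} %LVM")
print(f"weighted estimate : {res.infarct_pct_lvm:6.2f} %LVM")
print(f"binary core + MVO : {res.core_pct_lvm:6.2f} %LVM")
print(f"EM threshold t*   : {res.threshold:6.2f}")
print(f"MVO volume        : {res.mvo_volume_ml:6.2f} mL")
print()
print("The weighted size down-weights partial-volume border voxels; the")
print("binary size counts every segmented voxel fully. t* is the")
print("equal-posterior intensity between the two fitted Gaussians.")
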