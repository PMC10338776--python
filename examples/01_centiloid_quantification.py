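"""Quantify one amyloid-PET scan on the Centiloid scale.

Builds a synthetic subject with known ground truth (true SUVR 1.40,
rigidly misaligned PET, 2% noise), runs the full MRI-guided pipeline
(rigid coregistration -> affine template normalization -> one
resampling -> SUVR over the CTX/WhlCbl VOIs -> CL), and compares the
recovered Centiloid value with the ground truth.
"""

import numpy as np

from centiz import make_template, run_centiloid
from centiz.phantom import PhantomSpec, make_subject
from centiz.transforms import RigidParams

template, masks = make_template()
spec = PhantomSpec(
    true_suvr=1.40,
    noise_sd_frac=0.02,
    applied_transform=RigidParams(translations=[2, -1, 3], rotations=np.deg2rad([1, -2, 1])),
    pet_misalign=RigidParams(translations=[4, 2, -3], rotations=np.deg2rad([2, 1, -2])),
    seed=42,
)
subject = make_subject(template, masks, spec)

quant, artifacts = run_centiloid(
    subject.pet, subject.structural,
    template=template, ctx=masks["CTX"], whlcbl=masks["WhlCbl"],
)

print(f"target (CTX) mean      : {quant.mean_target:.4f}")
print(f"reference (WhlCbl) mean: {quant.mean_reference:.4f}")
print(f"SUVR                   : {quant.suvr:.4f}   (truth {subject.truth['suvr']:.4f})")
print(f"Centiloid              : {quant.cl:.2f}     (truth {subject.truth['cl']:.2f})")
print(f"VOI coverage           : {quant.voi_coverage:.3f}")
# SUVR is the cortical-to-cerebellar uptake ratio; CL maps it to the
# harmonized 0-100 amyloid scale (CL = 175.2 x SUVR - 182.2).  The
# recovered CL should sit within ~2 CL of the ground truth.
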