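"""Build tissue-equalization loss weights for a training cohort.

Bone occupies a small fraction of the volume, so a plain voxel-wise loss all
but ignores it.  The contributing factor CF_T is each tissue's voxel
fraction; the enhancing factor EF_T = 1 / mean(CF_T) up-weights rare
tissues; the equalization map MAP_eq = 1 + sum_T EF_T * MAP_T carries those
weights into the loss, with the all-ones term keeping background air in play.
"""

import numpy as np

from mrsct import PhantomSpec, build_atlas, generate_cohort
from mrsct.core import TISSUES

cohort = generate_cohort(PhantomSpec(seed=5), 4)
atlas = build_atlas([(p.patient_id, p.mri, p.ct, p.body) for p in cohort], out_shape=(96, 96))

print("per-tissue contributing factors (fraction of volume) and enhancing factors:")
for t in TISSUES:
    cfs = np.array(atlas.weights.cfs[t])
    ef = atlas.weights.efs[t]
    print(f"  {t:7s} CF = {cfs.mean():.4f} +/- {cfs.std():.4f}   EF = {ef:6.2f}   EF*mean(CF) = {ef * cfs.mean():.6f}")
# EF * mean(CF) = 1 exactly: each tissue contributes equally in expectation.

patient = atlas.patients[0]
print("\nequalization-map weights for patient 0:")
print(f"  outside body: {patient.eqmap[~patient.maps.body].mean():.2f} (the all-ones term)")
for t in ("fat", "muscle", "bone"):
    m = patient.maps[t]
    print(f"  {t:7s}: {patient.eqmap[m].mean():.2f}")
# A bone voxel weighs 1 + EF_body + EF_bone — the rarer the tissue, the
# larger its per-voxel say in the training loss.
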