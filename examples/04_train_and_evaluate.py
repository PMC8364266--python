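"""Train a small U-NET on phantoms and measure tissue-wise MAE.

A deliberately small configuration (half-scale 48x48 phantoms, depth-2
network, 20 epochs, equalized L1 loss) that runs in about a minute on a
laptop CPU and still shows the method working: the synthetic CT's
whole-body MAE falls far below the untrained baseline and bone remains the
hardest tissue.
"""

import pandas as pd

from mrsct import PhantomSpec, TrainConfig, UNetConfig, generate_cohort
from mrsct.evaluate import ExperimentConfig, capacity_per_patient, run_split

spec = PhantomSpec(seed=0).scaled((4, 48, 48), 0.5)
cohort = generate_cohort(spec, 6)
train, test = cohort[:4], cohort[4:]

config = ExperimentConfig(
    unet=UNetConfig(depth=2, base_filters=8),
    train=TrainConfig(epochs=20, seed=0, loss_mode="weighted-l1", augment_mode="none"),
    out_shape=(48, 48),
    eval_epochs=[1, 5, 10, 15, 18, 19, 20],
)
records = run_split(train, test, config)

print("test MAE (HU) by epoch, averaged over the 2 held-out phantoms:")
print(records.groupby("epoch")[["body", "fat", "muscle", "bone"]].mean().round(1))

capacity = capacity_per_patient(records, window=3)
print("\nlearning capacity (mean over the last 3 evaluated epochs):")
print(capacity.mean().round(1))
# Bone MAE stays the largest of the four tissues — exactly the imbalance the
# equalized loss is built to fight at full scale.
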