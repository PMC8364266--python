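"""Cross-validate and compare protocol variants with paired t-tests.

Runs a small 2-fold cross-validation, then a one-factor-at-a-time grid
comparing the unweighted loss against the main (equalized-loss) protocol on
an identical train/test split, with a paired Student t-test on per-patient
learning-capacity MAE.
"""

from mrsct import PhantomSpec, TrainConfig, UNetConfig, generate_cohort
from mrsct.evaluate import ExperimentConfig, cross_validate, run_experiment_grid, summarize

spec = PhantomSpec(seed=2).scaled((4, 48, 48), 0.5)
cohort = generate_cohort(spec, 6)

config = ExperimentConfig(
    unet=UNetConfig(depth=2, base_filters=8),
    train=TrainConfig(epochs=10, seed=0, augment_mode="none"),
    out_shape=(48, 48),
    eval_epochs=[8, 9, 10],
    capacity_window=3,
)

records = cross_validate(cohort, k=2, config=config)
print("2-fold cross-validation, per-tissue MAE (mean +/- SD across patients):")
print(summarize(records, window=3).round(1).to_string(index=False))

import dataclasses

variant = dataclasses.replace(
    config, train=dataclasses.replace(config.train, loss_mode="unweighted-l1")
)
_, comparisons = run_experiment_grid(cohort, {"unweighted": variant}, config, n_test=2, window=3)
print("\nunweighted loss vs main protocol (paired per-patient comparison):")
print(
    comparisons[["variant", "tissue", "variant_mae", "main_mae", "mean_diff", "p"]]
    .round(2)
    .to_string(index=False)
)
# mean_diff > 0 means the variant's MAE is higher (worse) than the main
# protocol's; with only two test phantoms the p-values are illustrative.
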