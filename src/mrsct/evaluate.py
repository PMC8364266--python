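"""Tissue-wise evaluation, cross-validation and the experiment harness.

The figure of merit throughout is the mean absolute error (MAE, in HU)
between the synthetic and the reference CT, computed separately inside each
of the four classification maps (body, fat, muscle, bone) of the *reference*
CT.  A dataset's *learning capacity* is estimated as the mean test MAE over
the final few epochs (default window 5) of a training run — the plateau the
MAE-vs-epoch curve settles on once additional epochs stop helping.

``cross_validate`` runs k-fold cross-validation with the enhancing factors
recomputed from each training fold (never from test patients), and
``run_experiment_grid`` performs one-factor-at-a-time comparisons against a
main configuration with a paired Student t-test on per-patient MAE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas, PatientAtlas, build_atlas
from .core import FAT, MUSCLE, TISSUES, TissueMaps, Volume3D
from .model import UNet, UNetConfig, build_unet, predict_sct
from .phantom import PhantomPatient
from .preprocess import extract_landmarks, standardize_mri
from .train import TrainConfig, run_training


def tissue_mae(
    sct: Volume3D, ct_ref: Volume3D, maps: TissueMaps
) -> dict[str, float | None]:
    """Per-tissue mean absolute error in HU.

    A tissue whose map is empty has no defined MAE and is reported as None
    (excluded from downstream means).
    """
    if sct.shape != ct_ref.shape or maps.shape != ct_ref.shape:
        raise ValueError("sct/ct/maps must share one grid")
    err = np.abs(sct.data - ct_ref.data)
    out: dict[str, float | None] = {}
    for tissue, m in maps:
        out[tissue] = float(err[m].mean()) if m.any() else None
    return out


def learning_capacity(
    mae_by_epoch, window: int = 5, last_epoch: int | None = None
) -> float:
    """Mean MAE over the final ``window`` epochs ending at ``last_epoch``.

    ``mae_by_epoch`` is indexed by epoch starting at 1 (a plain sequence is
    read as epochs 1..len).  With ``last_epoch=50`` and ``window=5`` this
    averages epochs 46-50.
    """
    values = np.asarray(list(mae_by_epoch), dtype=np.float64)
    n = values.size
    if last_epoch is None:
        last_epoch = n
    if not 1 <= window <= last_epoch <= n:
        raise ValueError(
            f"window {window} ending at epoch {last_epoch} not covered by {n} epochs"
        )
    return float(values[last_epoch - window : last_epoch].mean())


@dataclass
class ExperimentConfig:
    """One full experiment: architecture, training protocol, atlas options.

    ``standardize`` applies the landmark-based MRI standardization before
    atlas construction (the main protocol trains on original intensities;
    standardization is one of the grid variants).  ``eval_epochs`` limits
    test-set evaluation to the listed 1-based epochs (None = every epoch).
    """

    unet: UNetConfig = field(default_factory=lambda: UNetConfig(depth=3, base_filters=16))
    train: TrainConfig = field(default_factory=TrainConfig)
    out_shape: tuple[int, int] = (96, 96)
    standardize: bool = False
    eval_epochs: list[int] | None = None
    capacity_window: int = 5


def _prepare(patient: PhantomPatient, standardize: bool):
    """(pid, mri, ct, body) tuple for atlas construction."""
    mri = patient.mri
    if standardize:
        landmarks = extract_landmarks(
            mri, patient.labels == MUSCLE, patient.labels == FAT
        )
        mri = standardize_mri(mri, landmarks)
    return (patient.patient_id, mri, patient.ct, patient.body)


def predict_patient(model: UNet, patient: PatientAtlas) -> Volume3D:
    """Synthetic-CT volume (HU) for every slice of one atlas patient."""
    slices = [predict_sct(model, ex) for ex in sorted(patient.examples, key=lambda e: e.slice_index)]
    return patient.ct.with_data(np.stack(slices))


def evaluate_model(model: UNet, test_atlas: Atlas) -> list[dict]:
    """Per-patient tissue MAE of a model on a test atlas."""
    records = []
    for patient in test_atlas.patients:
        sct = predict_patient(model, patient)
        mae = tissue_mae(sct, patient.ct, patient.maps)
        records.append({"patient": patient.patient_id, **mae})
    return records


def run_split(
    train_patients: list[PhantomPatient],
    test_patients: list[PhantomPatient],
    config: ExperimentConfig,
    fold: int = 0,
) -> pd.DataFrame:
    """Train on one patient split and record per-epoch test-set tissue MAE.

    Enhancing factors come from the training patients only and are frozen
    into the test atlas.  Returns one row per (patient, evaluated epoch).
    """
    train_ids = {p.patient_id for p in train_patients}
    if train_ids & {p.patient_id for p in test_patients}:
        raise ValueError("train/test patient overlap")
    train_atlas = build_atlas(
        [_prepare(p, config.standardize) for p in train_patients], config.out_shape
    )
    test_atlas = build_atlas(
        [_prepare(p, config.standardize) for p in test_patients],
        config.out_shape,
        weights=train_atlas.weights,
    )
    model = build_unet(replace(config.unet, seed=config.train.seed + 7919 * (fold + 1)))
    eval_epochs = (
        set(config.eval_epochs)
        if config.eval_epochs is not None
        else set(range(1, config.train.epochs + 1))
    )
    rows: list[dict] = []

    def hook(epoch_idx: int, m: UNet):
        epoch = epoch_idx + 1
        if epoch not in eval_epochs:
            return None
        for rec in evaluate_model(m, test_atlas):
            rows.append(
                {
                    "fold": fold,
                    "epoch": epoch,
                    "loss_mode": config.train.loss_mode,
                    "augment_mode": config.train.augment_mode,
                    "train_size": len(train_patients),
                    **rec,
                }
            )
        return None

    run_training(train_atlas, model, config.train, eval_hook=hook)
    return pd.DataFrame(rows)


def _partition(cohort: list, k: int, seed: int) -> list[list]:
    order = np.random.default_rng(seed).permutation(len(cohort))
    groups: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        groups[pos % k].append(cohort[idx])
    return groups


def cross_validate(
    cohort: list[PhantomPatient], k: int = 3, config: ExperimentConfig | None = None
) -> pd.DataFrame:
    """k-fold cross-validation; every patient is tested exactly once.

    Each fold trains on the other k-1 groups with fold-specific enhancing
    factors.  Returns the concatenated per-epoch test records.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cohort) < k:
        raise ValueError("cohort smaller than the number of folds")
    config = config or ExperimentConfig()
    groups = _partition(cohort, k, config.train.seed)
    frames = []
    for fold in range(k):
        test = groups[fold]
        train = [p for g in range(k) if g != fold for p in groups[g]]
        frames.append(run_split(train, test, config, fold=fold))
    return pd.concat(frames, ignore_index=True)


def summarize(records: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Learning-capacity mean ± SD across test patients (sample SD, n-1).

    For each patient the MAE is first averaged over the final ``window``
    evaluated epochs; the summary is then taken across patients and folds.
    """
    last_epochs = sorted(records["epoch"].unique())[-window:]
    tail = records[records["epoch"].isin(last_epochs)]
    per_patient = tail.groupby(["fold", "patient"])[list(TISSUES)].mean()
    rows = []
    for tissue in TISSUES:
        vals = per_patient[tissue].dropna()
        rows.append(
            {
                "tissue": tissue,
                "mae_mean": float(vals.mean()),
                "mae_sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n_patients": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def capacity_per_patient(records: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Per-patient learning-capacity MAE (mean over the final epochs)."""
    last_epochs = sorted(records["epoch"].unique())[-window:]
    tail = records[records["epoch"].isin(last_epochs)]
    return tail.groupby("patient")[list(TISSUES)].mean()


def paired_ttest(a, b) -> dict:
    """Two-sided paired Student t-test on matched per-patient values.

    Zero-variance difference vectors are flagged as degenerate instead of
    returning NaN: identical samples give t = 0, p = 1; a constant non-zero
    shift gives p = 0 with the sign of the shift.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    diffs = a - b
    if np.ptp(diffs) == 0.0:
        mean = float(diffs[0])
        return {
            "t": 0.0 if mean == 0 else float(np.sign(mean)) * float("inf"),
            "p": 1.0 if mean == 0 else 0.0,
            "mean_diff": mean,
            "degenerate": True,
        }
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_diff": float(diffs.mean()), "degenerate": False}


def run_experiment_grid(
    cohort: list[PhantomPatient],
    variants: dict[str, ExperimentConfig],
    base: ExperimentConfig | None = None,
    n_test: int | None = None,
    window: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-factor-at-a-time comparison against a main configuration.

    The cohort is split once (last ``n_test`` patients held out, default one
    third); the main configuration and every variant train on the identical
    split, and per-tissue paired t-tests compare each variant's per-patient
    learning-capacity MAE with the main run's.  Returns (records,
    comparisons).
    """
    base = base or ExperimentConfig()
    n_test = n_test or max(1, len(cohort) // 3)
    train, test = cohort[:-n_test], cohort[-n_test:]
    all_records = []
    capacities: dict[str, pd.DataFrame] = {}
    for name, cfg in {"main": base, **variants}.items():
        rec = run_split(train, test, cfg)
        rec["variant"] = name
        all_records.append(rec)
        capacities[name] = capacity_per_patient(rec, window)
    records = pd.concat(all_records, ignore_index=True)
    comparisons = []
    main_cap = capacities["main"]
    for name in variants:
        cap = capacities[name].reindex(main_cap.index)
        if cap.isna().any().any():
            raise ValueError(f"variant {name!r} evaluated a different patient set")
        for tissue in TISSUES:
            test_result = paired_ttest(cap[tissue].values, main_cap[tissue].values)
            comparisons.append(
                {
                    "variant": name,
                    "tissue": tissue,
                    "variant_mae": float(cap[tissue].mean()),
                    "main_mae": float(main_cap[tissue].mean()),
                    **test_result,
                }
            )
    return records, pd.DataFrame(comparisons)


def dataset_size_curve(
    cohort: list[PhantomPatient],
    test_patients: list[PhantomPatient],
    sizes: list[int],
    config: ExperimentConfig,
    window: int = 5,
) -> pd.DataFrame:
    """Learning-capacity MAE as a function of training-set size.

    Uses nested subsets (a patient in the s-patient dataset stays in every
    larger one) so the curve varies only through added patients.
    """
    from .train import nested_subsets

    subsets = nested_subsets(cohort, sizes, seed=config.train.seed)
    rows = []
    for size, train in subsets.items():
        rec = run_split(train, test_patients, config)
        cap = capacity_per_patient(rec, window)
        for tissue in TISSUES:
            rows.append(
                {
                    "train_size": size,
                    "tissue": tissue,
                    "mae": float(cap[tissue].mean()),
                }
            )
    return pd.DataFrame(rows)


def desk_benchmark(
    master_seed: int = 1,
    n_seeds: int = 3,
    n_patients: int = 12,
    n_test: int = 4,
    epochs: int = 15,
    depth: int = 3,
    base_filters: int = 16,
    out_shape: tuple[int, int] = (96, 96),
    capacity_window: int = 5,
) -> dict[str, float]:
    """The desk-scale ablation benchmark on a phantom cohort.

    Trains the U-NET on 8 phantoms and tests on 4 (96x96 slices, depth 3,
    base 16, 15 epochs, batch 4 by default) under three protocols that differ
    by one factor each — the main method (equalized L1 loss, per-epoch
    augmentation), the unweighted loss, and no augmentation — repeated over
    ``n_seeds`` training seeds.  Reports median learning-capacity MAE per
    tissue for the main method, the bone-MAE comparison for each ablation,
    and the untrained-model baseline.
    """
    from .phantom import PhantomSpec, generate_cohort

    spec = PhantomSpec(seed=master_seed)
    cohort = generate_cohort(spec, n_patients)
    train_patients, test_patients = cohort[:-n_test], cohort[-n_test:]
    eval_epochs = list(range(epochs - capacity_window + 1, epochs + 1))
    arms = {
        "main": ("weighted-l1", "per-epoch"),
        "unweighted": ("unweighted-l1", "per-epoch"),
        "noaug": ("weighted-l1", "none"),
    }
    seeds = [master_seed * 10 + 1 + i for i in range(n_seeds)]
    caps: dict[str, list[pd.DataFrame]] = {name: [] for name in arms}
    baselines = []
    for seed in seeds:
        for name, (loss_mode, augment_mode) in arms.items():
            cfg = ExperimentConfig(
                unet=UNetConfig(depth=depth, base_filters=base_filters),
                train=TrainConfig(
                    epochs=epochs, seed=seed, loss_mode=loss_mode, augment_mode=augment_mode
                ),
                out_shape=out_shape,
                eval_epochs=eval_epochs,
                capacity_window=capacity_window,
            )
            rec = run_split(train_patients, test_patients, cfg)
            caps[name].append(capacity_per_patient(rec, capacity_window))
        # untrained baseline with the same initialization as the trained nets
        test_atlas = build_atlas(
            [_prepare(p, False) for p in test_patients], out_shape
        )
        untrained = build_unet(
            UNetConfig(depth=depth, base_filters=base_filters, seed=seed + 7919)
        )
        base = pd.DataFrame(evaluate_model(untrained, test_atlas))
        baselines.append(float(base["body"].mean()))

    def med(arm: str, tissue: str) -> float:
        return float(np.median([c[tissue].mean() for c in caps[arm]]))

    result = {f"{t}_mae_main": med("main", t) for t in TISSUES}
    result.update(
        {
            "body_mae_untrained": float(np.median(baselines)),
            "bone_mae_weighted": med("main", "bone"),
            "bone_mae_unweighted": med("unweighted", "bone"),
            "bone_mae_noaug": med("noaug", "bone"),
        }
    )
    result["weighted_loss_bone_improvement_pct"] = 100.0 * (
        1.0 - result["bone_mae_weighted"] / result["bone_mae_unweighted"]
    )
    result["augmentation_bone_improvement_pct"] = 100.0 * (
        1.0 - result["bone_mae_weighted"] / result["bone_mae_noaug"]
    )
    result["trained_vs_untrained_body_ratio"] = (
        result["body_mae_main"] / result["body_mae_untrained"]
    )
    return result


def plot_mae_vs_epoch(records: pd.DataFrame, path=None):
    """MAE-vs-epoch curves per tissue (patient-first averaging)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for tissue in TISSUES:
        curve = records.groupby("epoch")[tissue].mean()
        ax.plot(curve.index, curve.values, label=tissue)
    ax.set_xlabel("epoch")
    ax.set_ylabel("test MAE (HU)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_mae_vs_size(curve: pd.DataFrame, path=None):
    """MAE-vs-training-set-size curves per tissue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for tissue in TISSUES:
        sub = curve[curve["tissue"] == tissue].sort_values("train_size")
        ax.plot(sub["train_size"], sub["mae"], marker="o", label=tissue)
    ax.set_xlabel("patients in training")
    ax.set_ylabel("learning-capacity MAE (HU)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
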