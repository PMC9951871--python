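"""Orchestration of the experiment matrix on phantom (or user) data.

Three canned experiments mirror the evaluation protocol for inpainting-based
self-supervised pretraining:

* **design grid** -- pretrain once per (task, patch size, sampler) strategy,
  fine-tune every pretrained model in an identical manner with the same seed
  across the label-limited subsets, and tabulate test Dice alongside the
  supervised baseline;
* **scaling sweep** -- vary the amount of pretraining data (0% = supervised
  baseline) and fit the Dice-vs-data power law per labeled fraction;
* **SSL vs supervised comparison** -- clinically-relevant tissue metrics
  (volume / mean T2 for MRI, cross-sectional area / mean HU for CT) with
  per-image percent-error tables and Wilcoxon summaries.

Default sizes are phantom scale -- 96 x 96 images, a depth-3 U-Net with 8
base filters, a few dozen images and short early-stopped schedules -- chosen
so the full default plan runs on a single CPU in minutes while exercising
every stage end-to-end.  They are not the sizes one would use on real
cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from inpaintseg import metrics as M
from inpaintseg.corruption import build_mask_bank
from inpaintseg.nn import ModelConfig, build_model, transfer_weights
from inpaintseg.phantom import PhantomSpec, Sample, generate_sample
from inpaintseg.preprocess import Standardizer, stack_ct_channels
from inpaintseg.stats import fit_power_law, wilcoxon_one_sided
from inpaintseg.training import (
    OptimConfig,
    Strategy,
    finetune,
    make_label_subsets,
    predict_labels,
    pretrain,
    train_supervised_baseline,
)

__all__ = ["ExperimentPlan", "PhantomData", "prepare_phantom_data",
           "run_design_grid", "run_scaling_sweep", "compare_ssl_supervised"]

N_CLASSES = 4


@dataclass(frozen=True)
class ExperimentPlan:
    """Sizes, grids and seeds for one experiment run."""

    modality: str = "mri"
    image_size: int = 96
    n_unlabeled: int = 16
    n_labeled: int = 10
    n_val: int = 4
    n_test: int = 4
    label_fractions: tuple[float, ...] = (1.0, 0.5)
    pretrain_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0)  # % of unlabeled set
    strategies: tuple[Strategy, ...] = (Strategy(initial_lr=1e-2),)
    depth: int = 3
    base_filters: int = 8
    groupnorm_groups: int = 8
    batch_size: int = 4
    lr: float = 1e-2
    pretrain_max_epochs: int = 15
    pretrain_patience: int = 4
    finetune_max_epochs: int = 40
    finetune_patience: int = 8
    noise_sigma: float = 5.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if sorted(self.pretrain_levels) != list(self.pretrain_levels):
            raise ValueError("pretrain_levels must be sorted ascending")
        if self.image_size % 2 ** (self.depth - 1):
            raise ValueError("image_size must be divisible by 2^(depth-1)")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:8]

    def model_config(self) -> ModelConfig:
        in_ch = 1 if self.modality == "mri" else 3
        return ModelConfig(in_channels=in_ch, depth=self.depth,
                           base_filters=self.base_filters,
                           groupnorm_groups=self.groupnorm_groups, seed=self.seed)

    def optim(self, max_epochs, patience) -> OptimConfig:
        return OptimConfig(initial_lr=self.lr, batch_size=self.batch_size,
                           early_stop_patience=patience, max_epochs=max_epochs,
                           seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        strategies = raw.pop("strategies", None)
        plan = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if strategies is not None:
            plan = replace(plan, strategies=tuple(Strategy(**s) for s in strategies))
        return plan


@dataclass
class PhantomData:
    """Prepared (normalized) arrays plus raw samples for clinical metrics."""

    unlabeled: np.ndarray           # (Nu, C, H, W) normalized
    train_images: np.ndarray        # (Nl, C, H, W) normalized
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    test_samples: list[Sample] = field(repr=False)
    modality: str = "mri"


def _network_input(sample: Sample, modality: str) -> np.ndarray:
    """Windowed + standardized network input for one phantom slice, (C, H, W)."""
    if modality == "ct":
        channels = stack_ct_channels(sample.image)
        return Standardizer("per_channel").fit_transform(channels)
    return Standardizer("per_volume").fit_transform(sample.image)[None]


def prepare_phantom_data(plan: ExperimentPlan) -> PhantomData:
    """Generate and preprocess the phantom splits for a plan.

    Index layout: test, validation, labeled training, then unlabeled, so
    growing one split never changes the members of another.
    """
    spec = PhantomSpec(height=plan.image_size, width=plan.image_size,
                       modality=plan.modality, noise_sigma=plan.noise_sigma,
                       seed=plan.seed)
    n = {"test": plan.n_test, "val": plan.n_val,
         "train": plan.n_labeled, "unlabeled": plan.n_unlabeled}
    idx = 0
    arrays: dict[str, list] = {k: [] for k in n}
    samples: dict[str, list] = {k: [] for k in n}
    for split, count in n.items():
        for _ in range(count):
            s = generate_sample(spec, idx)
            samples[split].append(s)
            arrays[split].append(_network_input(s, plan.modality))
            idx += 1
    labels = {k: np.stack([s.label_map for s in samples[k]])
              for k in ("test", "val", "train")}
    return PhantomData(
        unlabeled=np.stack(arrays["unlabeled"]),
        train_images=np.stack(arrays["train"]), train_labels=labels["train"],
        val_images=np.stack(arrays["val"]), val_labels=labels["val"],
        test_images=np.stack(arrays["test"]), test_labels=labels["test"],
        test_samples=samples["test"], modality=plan.modality,
    )


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _pretrain_strategy(plan, data, strategy, n_images=None):
    """Pretrain one strategy on the first ``n_images`` unlabeled images."""
    images = data.unlabeled if n_images is None else data.unlabeled[:n_images]
    bank = build_mask_bank(strategy.task, strategy.sampler, strategy.patch_size,
                           images.shape[-2:], n_base=50, rng=plan.seed)
    model = build_model(plan.model_config(), "inpainting")
    bundle, history = pretrain(
        model, images, bank,
        plan.optim(plan.pretrain_max_epochs, plan.pretrain_patience),
        val_images=data.val_images,
    )
    return bundle, bank, history


def _finetune_subset(plan, data, strategy, bundle, fraction, subsets):
    ids = list(subsets[fraction])
    model = build_model(plan.model_config(), "segmentation")
    transfer_weights(bundle, model, strategy.transfer_scope)
    model, history = finetune(
        model, data.train_images[ids], data.train_labels[ids], strategy,
        plan.optim(plan.finetune_max_epochs, plan.finetune_patience),
        data.val_images, data.val_labels,
    )
    return model, history


def _baseline_subset(plan, data, fraction, subsets):
    ids = list(subsets[fraction])
    return train_supervised_baseline(
        data.train_images[ids], data.train_labels[ids],
        plan.optim(plan.finetune_max_epochs, plan.finetune_patience),
        plan.model_config(), data.val_images, data.val_labels,
    )


def _test_dice_rows(model, data, tag, fraction):
    """Per-image per-class Dice on the test set."""
    pred = predict_labels(model, data.test_images)
    rows = []
    for i, s in enumerate(data.test_samples):
        per_class = [M.dice_score(pred[i], data.test_labels[i], c)
                     for c in range(1, N_CLASSES + 1)]
        rows.append({"image_id": s.metadata["id"], "strategy": tag,
                     "regime": fraction, "class_dice": per_class,
                     "mean_dice": float(np.mean(per_class))})
    return pred, rows


def _provenance(plan) -> dict:
    return {"seed": plan.seed, "config_hash": plan.config_hash()}


def _maybe_write(plan, name, df: pd.DataFrame):
    if plan.out_dir:
        out = Path(plan.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_design_grid(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Pretrain/fine-tune every strategy of the plan across label fractions.

    Every strategy is fine-tuned in an identical manner with the same seed;
    the supervised baseline is trained per fraction.  Returns ``summary``
    (one row per (strategy, fraction) with mean test Dice) and ``scores``
    (paired per-image Dice for strategy ranking).  A failing cell is recorded
    in the summary and the run continues.
    """
    data = prepare_phantom_data(plan)
    subsets = make_label_subsets(list(range(plan.n_labeled)),
                                 plan.label_fractions, seed=plan.seed)
    summary_rows, score_rows = [], []
    baseline_scores: dict[float, list] = {}
    for fraction in plan.label_fractions:
        model, _ = _baseline_subset(plan, data, fraction, subsets)
        _, rows = _test_dice_rows(model, data, "supervised", fraction)
        baseline_scores[fraction] = rows
        summary_rows.append({"strategy": "supervised", "fraction": fraction,
                             "mean_dice": float(np.mean([r["mean_dice"] for r in rows])),
                             "error": "", **_provenance(plan)})
    for strategy in plan.strategies:
        tag = strategy.label()
        try:
            bundle, _, _ = _pretrain_strategy(plan, data, strategy)
        except Exception as exc:  # noqa: BLE001 - record and continue
            for fraction in plan.label_fractions:
                summary_rows.append({"strategy": tag, "fraction": fraction,
                                     "mean_dice": np.nan, "error": str(exc),
                                     **_provenance(plan)})
            continue
        for fraction in plan.label_fractions:
            try:
                model, _ = _finetune_subset(plan, data, strategy, bundle,
                                            fraction, subsets)
                _, rows = _test_dice_rows(model, data, tag, fraction)
                summary_rows.append({
                    "strategy": tag, "fraction": fraction,
                    "mean_dice": float(np.mean([r["mean_dice"] for r in rows])),
                    "error": "", **_provenance(plan)})
                for ssl_row, sup_row in zip(rows, baseline_scores[fraction]):
                    score_rows.append({
                        "strategy": tag, "dataset": plan.modality,
                        "image_id": ssl_row["image_id"], "regime": fraction,
                        "dice_ssl": ssl_row["mean_dice"],
                        "dice_supervised": sup_row["mean_dice"]})
            except Exception as exc:  # noqa: BLE001
                summary_rows.append({"strategy": tag, "fraction": fraction,
                                     "mean_dice": np.nan, "error": str(exc),
                                     **_provenance(plan)})
    summary = pd.DataFrame(summary_rows)
    scores = pd.DataFrame(score_rows)
    _maybe_write(plan, "design_grid_summary.csv", summary)
    _maybe_write(plan, "design_grid_scores.csv", scores)
    return {"summary": summary, "scores": scores}


def run_scaling_sweep(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Mean test Dice as a function of the amount of pretraining data.

    The 0% level is the supervised baseline (same computation, no pretrain).
    Power-law fits (a, k, c, S) are produced per label fraction whenever at
    least four distinct levels are available.
    """
    if len(plan.pretrain_levels) < 3 or 0.0 not in plan.pretrain_levels:
        raise ValueError("need >= 3 pretraining levels including 0")
    data = prepare_phantom_data(plan)
    subsets = make_label_subsets(list(range(plan.n_labeled)),
                                 plan.label_fractions, seed=plan.seed)
    strategy = plan.strategies[0]
    point_rows = []
    for level in plan.pretrain_levels:
        bundle = None
        if level > 0:
            n_images = max(1, int(round(level / 100 * plan.n_unlabeled)))
            bundle, _, _ = _pretrain_strategy(plan, data, strategy, n_images)
        for fraction in plan.label_fractions:
            if bundle is None:
                model, _ = _baseline_subset(plan, data, fraction, subsets)
            else:
                model, _ = _finetune_subset(plan, data, strategy, bundle,
                                            fraction, subsets)
            _, rows = _test_dice_rows(model, data, strategy.label(), fraction)
            point_rows.append({"x_percent": level, "fraction": fraction,
                               "mean_dice": float(np.mean([r["mean_dice"] for r in rows])),
                               **_provenance(plan)})
    points = pd.DataFrame(point_rows)
    fit_rows = []
    for fraction, g in points.groupby("fraction"):
        if g["x_percent"].nunique() >= 4:
            fit = fit_power_law(g["x_percent"].to_numpy(), g["mean_dice"].to_numpy())
            fit_rows.append({"fraction": fraction, "a": fit.a, "k": fit.k,
                             "c": fit.c, "S": fit.s, **_provenance(plan)})
    fits = pd.DataFrame(fit_rows)
    _maybe_write(plan, "scaling_points.csv", points)
    _maybe_write(plan, "scaling_fits.csv", fits)
    return {"points": points, "fits": fits}


def compare_ssl_supervised(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Clinical-metric percent errors: SSL arm vs supervised arm.

    Trains both arms per label fraction, derives the modality's clinical
    metrics (tissue volume and mean T2 for MRI; cross-sectional area and
    mean HU for CT) from predicted and ground-truth segmentations of every
    test image, and tabulates percent errors plus the per-image paired
    comparison averaged over classes and regimes (with and without class
    exclusions) and a Wilcoxon summary of paired Dice scores.
    """
    data = prepare_phantom_data(plan)
    subsets = make_label_subsets(list(range(plan.n_labeled)),
                                 plan.label_fractions, seed=plan.seed)
    strategy = plan.strategies[0]
    bundle, _, _ = _pretrain_strategy(plan, data, strategy)
    error_rows, dice_rows = [], []
    for fraction in plan.label_fractions:
        sup_model, _ = _baseline_subset(plan, data, fraction, subsets)
        ssl_model, _ = _finetune_subset(plan, data, strategy, bundle, fraction, subsets)
        for arm, model in (("supervised", sup_model), ("ssl", ssl_model)):
            pred = predict_labels(model, data.test_images)
            for i, s in enumerate(data.test_samples):
                spacing = s.metadata["pixel_spacing"]
                thick = s.metadata["slice_thickness"]
                for c in range(1, N_CLASSES + 1):
                    if data.modality == "mri":
                        metric_pairs = {
                            "volume": (M.tissue_volume(pred[i], spacing, thick, c),
                                       M.tissue_volume(s.label_map, spacing, thick, c)),
                            "mean_t2": (M.mean_t2(s.t2_map, pred[i], c),
                                        M.mean_t2(s.t2_map, s.label_map, c)),
                        }
                    else:
                        metric_pairs = {
                            "csa": (M.cross_sectional_area(pred[i], spacing, c),
                                    M.cross_sectional_area(s.label_map, spacing, c)),
                            "mean_hu": (M.mean_hu(s.image, pred[i], c),
                                        M.mean_hu(s.image, s.label_map, c)),
                        }
                    for name, (pv, gv) in metric_pairs.items():
                        error_rows.append({
                            "arm": arm, "image_id": s.metadata["id"],
                            "class_id": c, "regime": fraction, "metric": name,
                            "predicted": pv, "ground_truth": gv,
                            "percent_error": M.percent_error(pv, gv),
                            **_provenance(plan)})
                dice_rows.append({
                    "arm": arm, "image_id": s.metadata["id"], "regime": fraction,
                    "mean_dice": float(np.mean([
                        M.dice_score(pred[i], s.label_map, c)
                        for c in range(1, N_CLASSES + 1)]))})
    errors = pd.DataFrame(error_rows)
    dice = pd.DataFrame(dice_rows)
    comparisons = {}
    for metric, g in errors.groupby("metric"):
        sup = g[g["arm"] == "supervised"]
        ssl = g[g["arm"] == "ssl"]
        comparisons[metric] = M.per_image_comparison(sup, ssl)
    paired = dice.pivot_table(index=["image_id", "regime"], columns="arm",
                              values="mean_dice").reset_index()
    try:
        p = wilcoxon_one_sided(paired["ssl"], paired["supervised"], "greater")
    except ValueError:
        p = np.nan
    summary = pd.DataFrame([{"p_value_ssl_gt_supervised": p,
                             "mean_dice_ssl": paired["ssl"].mean(),
                             "mean_dice_supervised": paired["supervised"].mean(),
                             **_provenance(plan)}])
    per_image = pd.concat(
        {m: c for m, c in comparisons.items()}, names=["metric", "image_id"]
    ).reset_index()
    _maybe_write(plan, "clinical_errors.csv", errors)
    _maybe_write(plan, "clinical_per_image.csv", per_image)
    _maybe_write(plan, "compare_summary.csv", summary)
    return {"errors": errors, "per_image": per_image, "summary": summary,
            "paired_dice": paired}
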