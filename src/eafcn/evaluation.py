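"""Classification metrics, stratified five-fold cross-validation, and
mean +/- SD reporting.

Metrics are computed from integer confusion counts with AD as the positive
class: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
F1 = 2TP/(2TP+FN+FP), and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Any degenerate denominator yields 0 rather than NaN so aggregation stays
total; this convention is applied uniformly and documented.

The full pipeline evaluation trains the patch FCN per fold, selects the
ROI on validation data only, trains the fusion MLPs, and scores the
held-out fold; results are aggregated as mean +/- standard deviation over
repeats x folds per model variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .backbone import TrainConfig, build_network, fcn_spec_default, train_fcn
from .fusion import (MLPSpec, assemble_features, fit_demographic_standardizer,
                     predict_mlp, train_mlp)
from .inference import dense_probability_map, extract_roi_features, mcc_heatmap, select_roi
from .volume_io import LABEL_TO_INDEX, normalize_intensity

logger = logging.getLogger("eafcn")

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldPlan",
    "PipelineConfig",
    "derive_seed",
    "confusion",
    "metric_accuracy",
    "metric_sensitivity",
    "metric_specificity",
    "metric_f1",
    "metric_mcc",
    "all_metrics",
    "make_fold_plan",
    "cross_validate",
    "report_frame",
    "format_report_table",
]

METRIC_NAMES = ("accu", "sens", "spec", "f1", "mcc")


def derive_seed(*parts) -> int:
    """A deterministic child seed (< 2^31) from integer parts."""
    return int(np.random.SeedSequence([int(p) % (2 ** 31) for p in parts]).generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


def confusion(preds, labels, positive_class="AD") -> ConfusionCounts:
    """Exact confusion counts; inputs may be label strings or {0,1} indices."""
    def to_idx(v):
        if v in LABEL_TO_INDEX:
            return LABEL_TO_INDEX[v]
        return int(v)

    p = np.array([to_idx(v) for v in preds])
    y = np.array([to_idx(v) for v in labels])
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    pos = to_idx(positive_class)
    return ConfusionCounts(
        tp=int(np.sum((p == pos) & (y == pos))),
        tn=int(np.sum((p != pos) & (y != pos))),
        fp=int(np.sum((p == pos) & (y != pos))),
        fn=int(np.sum((p != pos) & (y == pos))),
    )


def _ratio(num, den):
    return num / den if den > 0 else 0.0


def metric_accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def metric_sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def metric_specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp)


def metric_f1(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)


def metric_mcc(c: ConfusionCounts) -> float:
    den = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if den == 0:
        return 0.0
    return float((c.tp * c.tn - c.fp * c.fn) / den)


def all_metrics(c: ConfusionCounts) -> dict:
    return {
        "accu": metric_accuracy(c),
        "sens": metric_sensitivity(c),
        "spec": metric_specificity(c),
        "f1": metric_f1(c),
        "mcc": metric_mcc(c),
    }


@dataclass
class MetricsReport:
    """Per-metric mean and SD plus the retained raw per-fold values."""

    raw: dict = field(default_factory=lambda: {m: [] for m in METRIC_NAMES})
    missing: int = 0

    def add(self, metrics: dict):
        for m in METRIC_NAMES:
            self.raw[m].append(float(metrics[m]))

    def mean(self, metric):
        v = self.raw[metric]
        return float(np.mean(v)) if v else float("nan")

    def sd(self, metric):
        v = self.raw[metric]
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> dict:
        return {m: (self.mean(m), self.sd(m)) for m in METRIC_NAMES}


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignments keyed by subject id."""

    n_folds: int
    assignments: tuple          # sorted (subject_id, fold) pairs
    stratified: bool
    seed: int
    repeats_fcn: int = 5
    repeats_mlp: int = 3

    def fold_of(self, subject_id) -> int:
        return dict(self.assignments)[subject_id]

    def fold_ids(self, fold) -> list:
        return [sid for sid, f in self.assignments if f == fold]


def make_fold_plan(records, seed: int, n_folds: int = 5, stratified: bool = True,
                   repeats_fcn: int = 5, repeats_mlp: int = 3) -> FoldPlan:
    """Deterministic stratified k-fold split over sorted subject ids.

    Sorting by id before splitting makes the plan invariant to the input
    order of the records.
    """
    recs = sorted(records, key=lambda r: r.subject_id)
    ids = [r.subject_id for r in recs]
    labels = [r.label for r in recs]
    if stratified:
        counts = {lab: labels.count(lab) for lab in set(labels)}
        if min(counts.values()) < n_folds:
            raise ValueError(f"need >= {n_folds} subjects per class, got {counts}")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2 ** 31))
        assign = {}
        for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ids)), labels)):
            for i in test_idx:
                assign[ids[i]] = fold
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        assign = {ids[i]: int(j % n_folds) for j, i in enumerate(perm)}
    return FoldPlan(n_folds=n_folds, assignments=tuple(sorted(assign.items())),
                    stratified=stratified, seed=seed,
                    repeats_fcn=repeats_fcn, repeats_mlp=repeats_mlp)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end evaluation needs."""

    profile: str = "desk"
    attention: str = "none"                    # none | self | external
    attention_kwargs: tuple = ()
    # desk-scale training calibration: 200 iterations need a faster learning
    # rate than the full-scale default (see docs/methods.md)
    fcn_train: TrainConfig = TrainConfig(iterations=200, learning_rate=1e-3,
                                         patches_per_subject=6)
    mlp_train: TrainConfig = TrainConfig(iterations=300, batch_size=16, learning_rate=1e-2)
    mlp_hidden: int = 32
    roi_k: int = 10
    threshold: float = 0.5
    modes: tuple = ("A", "B", "C")
    normalize_low: float = 1.0
    normalize_high: float = 99.0
    seed: int = 0


def _normalize_cohort(cohort, cfg: PipelineConfig):
    return [(rec, vol if vol.normalized else
             normalize_intensity(vol, cfg.normalize_low, cfg.normalize_high))
            for rec, vol in cohort]


def run_fold_pipeline(cohort_by_id, train_ids, val_ids, test_ids, cfg: PipelineConfig, seed: int):
    """Train FCN on train_ids, select ROI on val_ids, train the fusion MLPs
    and score test_ids.  Returns {mode: ConfusionCounts} plus artifacts."""
    spec = fcn_spec_default(cfg.profile, attention=cfg.attention,
                            attention_kwargs=dict(cfg.attention_kwargs))
    model = build_network(spec, seed=derive_seed(seed, 11))
    fcn_cfg = TrainConfig(**{**cfg.fcn_train.__dict__, "seed": derive_seed(seed, 23)})
    train_subjects = [cohort_by_id[i] for i in train_ids]
    val_subjects = [cohort_by_id[i] for i in val_ids]
    model, history = train_fcn(model, train_subjects, val_subjects, fcn_cfg)

    maps = {sid: dense_probability_map(model, cohort_by_id[sid][1])
            for sid in (*train_ids, *val_ids, *test_ids)}
    heat = mcc_heatmap([(maps[sid], cohort_by_id[sid][0].label) for sid in val_ids],
                       threshold=cfg.threshold)
    roi = select_roi(heat, min(cfg.roi_k, heat.values.size))  # small volumes have few sites
    standardizer = fit_demographic_standardizer(
        [cohort_by_id[i][0] for i in (*train_ids, *val_ids)])

    def feats(sid, mode):
        rec = cohort_by_id[sid][0]
        rf = extract_roi_features(maps[sid], roi) if mode in ("A", "C") else None
        return assemble_features(mode, roi_feats=rf, record=rec, standardizer=standardizer)

    per_mode = {}
    for mode in cfg.modes:
        Xtr = np.stack([feats(i, mode) for i in train_ids])
        ytr = [cohort_by_id[i][0].label for i in train_ids]
        Xval = np.stack([feats(i, mode) for i in val_ids])
        yval = [cohort_by_id[i][0].label for i in val_ids]
        Xte = np.stack([feats(i, mode) for i in test_ids])
        yte = [cohort_by_id[i][0].label for i in test_ids]
        per_mode[mode] = (Xtr, ytr, Xval, yval, Xte, yte)
    return model, history, heat, roi, standardizer, per_mode


def cross_validate(cohort, cfg: PipelineConfig, plan: FoldPlan) -> dict:
    """Repeated stratified cross-validation of the full pipeline.

    Per FCN repeat r and fold f: fold f is held out for testing, one other
    fold is the FCN validation fold (heatmap/ROI source; it rotates with
    r), the rest train the FCN.  The fusion MLPs are trained per MLP
    repeat on the training folds with the validation fold for checkpoint
    selection, then scored on the held-out fold.  Fold failures are logged
    and counted as missing, never imputed.

    Returns {mode: MetricsReport}.
    """
    cohort = _normalize_cohort(cohort, cfg)
    cohort_by_id = {rec.subject_id: (rec, vol) for rec, vol in cohort}
    plan_ids = {sid for sid, _ in plan.assignments}
    if plan_ids != set(cohort_by_id):
        raise ValueError("fold plan does not cover the cohort")
    reports = {mode: MetricsReport() for mode in cfg.modes}
    for r in range(plan.repeats_fcn):
        for f in range(plan.n_folds):
            val_fold = (f + 1 + (r % (plan.n_folds - 1))) % plan.n_folds
            test_ids = plan.fold_ids(f)
            val_ids = plan.fold_ids(val_fold)
            train_ids = [sid for sid, fold in plan.assignments if fold not in (f, val_fold)]
            try:
                _, _, _, _, _, per_mode = run_fold_pipeline(
                    cohort_by_id, train_ids, val_ids, test_ids, cfg,
                    seed=derive_seed(cfg.seed, r, f))
                for m_rep in range(plan.repeats_mlp):
                    for mode in cfg.modes:
                        Xtr, ytr, Xval, yval, Xte, yte = per_mode[mode]
                        mlp_cfg = TrainConfig(**{**cfg.mlp_train.__dict__,
                                                 "seed": derive_seed(cfg.seed, r, f, m_rep, 5)})
                        spec = MLPSpec(input_dim=Xtr.shape[1], hidden_dim=cfg.mlp_hidden)
                        clf = train_mlp(Xtr, ytr, spec, mlp_cfg, Xval, yval)
                        pred, _ = predict_mlp(clf, Xte)
                        reports[mode].add(all_metrics(confusion(pred, yte)))
            except Exception:
                logger.exception("fold %d (repeat %d) failed; marked missing", f, r)
                for mode in cfg.modes:
                    reports[mode].missing += 1
    return reports


def report_frame(reports: dict) -> pd.DataFrame:
    """Long-format DataFrame: variant, metric, mean, sd, raw values."""
    rows = []
    for variant, rep in reports.items():
        for m in METRIC_NAMES:
            rows.append({
                "variant": f"MLP-{variant}" if variant in ("A", "B", "C") else variant,
                "metric": m,
                "mean": rep.mean(m),
                "sd": rep.sd(m),
                "n": len(rep.raw[m]),
                "raw": ";".join(f"{v:.6f}" for v in rep.raw[m]),
            })
    return pd.DataFrame(rows)


def format_report_table(reports: dict) -> str:
    """Human-readable mean +/- SD table, one row per variant."""
    lines = [f"{'variant':<10}" + "".join(f"{m:>18}" for m in METRIC_NAMES)]
    for variant, rep in reports.items():
        name = f"MLP-{variant}" if variant in ("A", "B", "C") else str(variant)
        cells = "".join(f"{rep.mean(m):>9.4f}±{rep.sd(m):<8.4f}" for m in METRIC_NAMES)
        lines.append(f"{name:<10}" + cells)
    return "\n".join(lines)
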