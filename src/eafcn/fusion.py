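"""Second-stage MLP classifiers fusing imaging features with demographics.

Three fusion modes mirror the ablation design:

- mode A: ROI probabilities only (k features),
- mode B: demographics only (standardized age, sex as {F=0, M=1},
  standardized MMSE — 3 features),
- mode C: both blocks concatenated (k + 3 features).

ROI probabilities are already bounded in [0, 1] and are passed through
raw; age and MMSE are z-scored with training-fold statistics only (a
constant feature gets scale 1, hence standardizes to 0).  The classifier
is a two-layer MLP (hidden width 32 by default) with batch normalization,
Leaky ReLU and dropout, trained with Adam + cross-entropy; tied logits
predict NC by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .volume_io import LABEL_TO_INDEX, SubjectRecord

__all__ = [
    "FusionMode",
    "Standardizer",
    "MLPSpec",
    "MLPClassifier",
    "fit_demographic_standardizer",
    "assemble_features",
    "train_mlp",
    "predict_mlp",
]

FusionMode = str  # "A" | "B" | "C"
_MODES = ("A", "B", "C")


@dataclass(frozen=True)
class Standardizer:
    """Per-feature centering/scaling parameters (training fold only)."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, x):
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.scale


def fit_demographic_standardizer(records) -> Standardizer:
    """Mean/SD of (age, mmse) over the training-fold records."""
    vals = np.array([[r.age, r.mmse] for r in records], dtype=np.float64)
    mean = vals.mean(axis=0)
    scale = vals.std(axis=0)
    scale[scale == 0] = 1.0
    return Standardizer(mean=mean, scale=scale)


def assemble_features(mode: FusionMode, roi_feats=None, record: SubjectRecord | None = None,
                      standardizer: Standardizer | None = None) -> np.ndarray:
    """Build one subject's feature vector for the given fusion mode.

    Layout is (roi block | demographic block); blocks are present per mode.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    parts = []
    if mode in ("A", "C"):
        if roi_feats is None:
            raise ValueError(f"mode {mode} requires ROI features")
        parts.append(np.asarray(roi_feats, dtype=np.float64).ravel())
    if mode in ("B", "C"):
        if record is None or standardizer is None:
            raise ValueError(f"mode {mode} requires a subject record and a standardizer")
        age_z, mmse_z = standardizer.transform([record.age, record.mmse])
        sex = 1.0 if record.sex == "M" else 0.0
        parts.append(np.array([age_z, sex, mmse_z], dtype=np.float64))
    return np.concatenate(parts)


@dataclass(frozen=True)
class MLPSpec:
    """Two fully connected layers with BN, Leaky ReLU, dropout in between."""

    input_dim: int
    hidden_dim: int = 32
    leaky_slope: float = 0.01
    dropout_p: float = 0.1
    n_classes: int = 2


class MLPClassifier:
    def __init__(self, spec: MLPSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 557]))
        self.net = _nn.Sequential([
            _nn.Linear(spec.input_dim, spec.hidden_dim, rng=rng),
            _nn.BatchNorm1d(spec.hidden_dim),
            _nn.LeakyReLU(spec.leaky_slope),
            _nn.Dropout(spec.dropout_p),
            _nn.Linear(spec.hidden_dim, spec.n_classes, rng=rng),
        ])

    def forward(self, x, training=False, rng=None):
        return self.net.forward(np.asarray(x, dtype=np.float32), training=training, rng=rng)

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)


def train_mlp(features, labels, spec: MLPSpec, cfg, val_features=None, val_labels=None) -> MLPClassifier:
    """Train the fusion MLP with Adam + cross-entropy.

    ``labels`` are "AD"/"NC" strings or {0, 1} indices.  When a validation
    set is supplied, the best-validation-accuracy weights (ties earliest)
    are restored; otherwise the final weights are kept.  Deterministic
    given ``cfg.seed``.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.array([LABEL_TO_INDEX.get(l, l) for l in labels], dtype=int)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(f"features must be (n, {spec.input_dim}), got {X.shape}")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = MLPClassifier(spec, seed=cfg.seed)
    if cfg.iterations == 0:
        return clf
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2 ** 31), 811]))
    opt = _nn.Adam(clf.net.params(), lr=cfg.learning_rate)
    has_val = val_features is not None and val_labels is not None
    if has_val:
        Xv = np.asarray(val_features, dtype=np.float64)
        yv = np.array([LABEL_TO_INDEX.get(l, l) for l in val_labels], dtype=int)
    best_acc, best_state = -1.0, None
    n = len(X)
    for it in range(1, cfg.iterations + 1):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        opt.zero_grad()
        logits = clf.forward(X[idx], training=True, rng=rng)
        loss, d = _nn.softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"MLP training diverged at iteration {it}")
        clf.net.backward(d)
        opt.step()
        if has_val and (it % cfg.validate_every == 0 or it == cfg.iterations):
            pred, _ = predict_mlp(clf, Xv)
            acc = float(np.mean(pred == yv))
            if acc > best_acc:
                best_acc, best_state = acc, clf.get_state()
    if best_state is not None:
        clf.set_state(best_state)
    return clf


def predict_mlp(classifier: MLPClassifier, features):
    """Class predictions and p(AD) for one or more feature vectors.

    Returns (labels, p_ad) as arrays; exactly tied logits predict NC.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != classifier.spec.input_dim:
        raise ValueError(f"feature dimension {X.shape[1]} != spec.input_dim {classifier.spec.input_dim}")
    logits = classifier.forward(X, training=False)
    p = _nn.softmax(logits.astype(np.float64), axis=1)
    p_ad = p[:, LABEL_TO_INDEX["AD"]]
    pred = (p_ad > 0.5).astype(int)   # ties (p_ad == 0.5) -> NC
    return pred, p_ad
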