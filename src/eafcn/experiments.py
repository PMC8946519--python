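"""Desk-scale validation study: planted-lesion recovery and fusion ordering.

This is the package's standard end-to-end experiment on the default
synthetic cohort (20 AD + 20 NC, 64^3 voxels, one planted lesion sphere).
For each of several training seeds it

1. assigns subjects to stratified folds (3 folds train the FCN, one is the
   validation fold, one is held out for the fusion stage),
2. trains the desk-profile FCN for a fixed number of iterations,
3. computes the validation-fold MCC heatmap, selects the top-k ROI and
   measures how far the top site's receptive-field center lies from the
   planted lesion center,
4. trains MLP-A/B/C on FCN-derived features of the training folds (the
   validation fold steers checkpoint selection) and scores the held-out
   fold.

The returned dictionary carries every measured quantity; nothing is
asserted here — the test suite and the acceptance script interpret it.
"""

from __future__ import annotations

import numpy as np

from .backbone import TrainConfig, build_network, fcn_spec_default, train_fcn
from .evaluation import confusion, derive_seed, make_fold_plan, metric_accuracy
from .fusion import (MLPSpec, assemble_features, fit_demographic_standardizer,
                     predict_mlp, train_mlp)
from .inference import dense_probability_map, extract_roi_features, mcc_heatmap, select_roi
from .synthetic import CohortSpec, simulate_cohort
from .volume_io import normalize_intensity

__all__ = ["desk_study"]


def desk_study(seed: int = 101, n_seeds: int = 3, iterations: int = 200,
               roi_k: int = 10, profile: str = "desk", attention: str = "none",
               attention_kwargs: dict | None = None) -> dict:
    """Run the desk-scale study; see the module docstring."""
    cohort_spec = CohortSpec(seed=derive_seed(seed, 1))
    cohort = [(rec, normalize_intensity(vol)) for rec, vol in simulate_cohort(cohort_spec)]
    by_id = {rec.subject_id: (rec, vol) for rec, vol in cohort}
    plan = make_fold_plan([rec for rec, _ in cohort], seed=derive_seed(seed, 13))
    lesion_center = np.array(cohort_spec.lesion_centers[0], dtype=float)

    per_seed = []
    for s in range(n_seeds):
        test_fold = s % plan.n_folds
        val_fold = (s + 1) % plan.n_folds
        test_ids = plan.fold_ids(test_fold)
        val_ids = plan.fold_ids(val_fold)
        train_ids = [sid for sid, f in plan.assignments if f not in (test_fold, val_fold)]

        model = build_network(
            fcn_spec_default(profile, attention=attention,
                             attention_kwargs=attention_kwargs or {}),
            seed=derive_seed(seed, s, 11))
        cfg = TrainConfig(iterations=iterations, learning_rate=1e-3,
                          patches_per_subject=6, seed=derive_seed(seed, s, 23))
        model, history = train_fcn(model, [by_id[i] for i in train_ids],
                                   [by_id[i] for i in val_ids], cfg)
        val_acc = max((h["val_accuracy"] for h in history), default=float("nan"))
        n_val_patches = cfg.patches_per_subject * len(val_ids)

        maps = {sid: dense_probability_map(model, by_id[sid][1]) for sid in by_id}
        heat = mcc_heatmap([(maps[sid], by_id[sid][0].label) for sid in val_ids])
        roi = select_roi(heat, roi_k)
        top_center = np.array(heat.site_center(roi.sites[0]), dtype=float)
        dist = float(np.linalg.norm(top_center - lesion_center))

        standardizer = fit_demographic_standardizer(
            [by_id[i][0] for i in (*train_ids, *val_ids)])

        def feats(sid, mode):
            rec = by_id[sid][0]
            rf = extract_roi_features(maps[sid], roi) if mode in ("A", "C") else None
            return assemble_features(mode, roi_feats=rf, record=rec,
                                     standardizer=standardizer)

        mlp_acc = {}
        for mode in ("A", "B", "C"):
            Xtr = np.stack([feats(i, mode) for i in train_ids])
            ytr = [by_id[i][0].label for i in train_ids]
            Xval = np.stack([feats(i, mode) for i in val_ids])
            yval = [by_id[i][0].label for i in val_ids]
            Xte = np.stack([feats(i, mode) for i in test_ids])
            yte = [by_id[i][0].label for i in test_ids]
            mlp_cfg = TrainConfig(iterations=300, batch_size=16, learning_rate=1e-2,
                                  seed=derive_seed(seed, s, 5))
            clf = train_mlp(Xtr, ytr, MLPSpec(input_dim=Xtr.shape[1]), mlp_cfg, Xval, yval)
            pred, _ = predict_mlp(clf, Xte)
            mlp_acc[mode] = metric_accuracy(confusion(pred, yte))

        per_seed.append({
            "seed_index": s,
            "val_accuracy": float(val_acc),
            "n_val_patches": int(n_val_patches),
            "top_site": tuple(int(v) for v in roi.sites[0]),
            "top_center": tuple(float(v) for v in top_center),
            "dist_to_lesion": dist,
            "heat_max": float(heat.values.max()),
            "mlp_accuracy": mlp_acc,
        })

    radius = float(cohort_spec.lesion_radius)
    hits = sum(p["dist_to_lesion"] <= 2 * radius for p in per_seed)
    mean_mlp = {m: float(np.mean([p["mlp_accuracy"][m] for p in per_seed]))
                for m in ("A", "B", "C")}
    return {
        "cohort": {"n_ad": cohort_spec.n_ad, "n_nc": cohort_spec.n_nc,
                   "volume_shape": cohort_spec.volume_shape,
                   "lesion_center": tuple(float(v) for v in lesion_center),
                   "lesion_radius": radius,
                   "effect_size": cohort_spec.effect_size},
        "iterations": iterations,
        "per_seed": per_seed,
        "lesion_recovery_hits": int(hits),
        "n_seeds": n_seeds,
        "mean_mlp_accuracy": mean_mlp,
    }
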