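"""Dense inference and ROI selection.

Applying the patch-trained FCN convolutionally to a whole volume yields a
lattice of two-class logits; the softmax AD channel is the disease
probability map.  The lattice geometry is fixed by the network: stride 4
voxels per step and offset 23 (the 0-based center of the first 47^3
window), so lattice site i sits at voxel offset + 4*i.

Across subjects, thresholding each site's probability at 0.5 and comparing
with the subject labels yields a per-site confusion table whose Matthews
correlation coefficient forms the MCC heatmap; the k highest-MCC sites are
the regions of interest whose probabilities feed the fusion MLP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import softmax
from .backbone import FCNModel, PATCH_SIZE
from .volume_io import LABEL_TO_INDEX, BrainVolume

__all__ = [
    "ProbabilityMap",
    "MCCHeatmap",
    "ROIMask",
    "dense_probability_map",
    "probability_at",
    "mcc_heatmap",
    "select_roi",
    "extract_roi_features",
    "upsample_to_voxels",
    "plot_map_slices",
]


@dataclass
class ProbabilityMap:
    """Lattice of p(AD) values over a subject volume."""

    probs: np.ndarray        # 3D lattice, values in [0, 1]
    stride: int
    offset: int
    subject_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 3:
            raise ValueError("probability map must be a 3D lattice")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def site_center(self, site) -> tuple:
        """Voxel coordinate of a lattice site's receptive-field center."""
        return tuple(self.offset + self.stride * int(i) for i in site)


@dataclass
class MCCHeatmap:
    """Per-lattice-site MCC of the FCN's thresholded predictions."""

    values: np.ndarray
    stride: int
    offset: int
    n_subjects: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.size and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("MCC values must lie in [-1, 1]")

    def site_center(self, site) -> tuple:
        return tuple(self.offset + self.stride * int(i) for i in site)


@dataclass(frozen=True)
class ROIMask:
    """Ordered lattice sites (best MCC first, ties lexicographic)."""

    sites: tuple
    k: int


def _check_volume(model: FCNModel, volume: BrainVolume):
    rf = PATCH_SIZE
    if any(s < rf for s in volume.shape):
        raise ValueError(f"volume {volume.shape} smaller than the receptive field {rf}")


def dense_probability_map(model: FCNModel, volume: BrainVolume, exact: bool = False) -> ProbabilityMap:
    """Whole-volume convolutional inference -> p(AD) lattice.

    ``exact=True`` runs the float64 reproducible convolution path (used
    where dense and patchwise outputs are compared numerically).
    """
    _check_volume(model, volume)
    x = volume.voxels[None, None]
    if exact:
        logits = model.forward_exact(x)
    else:
        logits = model.forward(np.asarray(x, dtype=np.float32), training=False)
    probs = softmax(logits.astype(np.float64), axis=1)[0, LABEL_TO_INDEX["AD"]]
    return ProbabilityMap(probs=probs, stride=model.stride, offset=model.offset,
                          subject_id=volume.subject_id)


def probability_at(model: FCNModel, volume: BrainVolume, center, exact: bool = False) -> float:
    """p(AD) of the single 47^3 patch centered at ``center``."""
    _check_volume(model, volume)
    half = PATCH_SIZE // 2
    start = tuple(int(c) - half for c in center)
    for st, s in zip(start, volume.shape):
        if st < 0 or st + PATCH_SIZE > s:
            raise ValueError(f"patch at center {tuple(center)} falls outside volume {volume.shape}")
    cube = volume.voxels[start[0]:start[0] + PATCH_SIZE,
                         start[1]:start[1] + PATCH_SIZE,
                         start[2]:start[2] + PATCH_SIZE][None, None]
    if exact:
        logits = model.forward_exact(cube)
    else:
        logits = model.forward(np.asarray(cube, dtype=np.float32), training=False)
    p = softmax(logits.reshape(-1).astype(np.float64), axis=0)
    return float(p[LABEL_TO_INDEX["AD"]])


def mcc_heatmap(maps_with_labels, threshold: float = 0.5) -> MCCHeatmap:
    """Cross-subject per-site MCC of thresholded probability maps.

    Each subject contributes one prediction per lattice site (AD iff
    p > threshold); predictions are compared with the subject label and the
    per-site confusion counts give the site's MCC.  Sites with a zero MCC
    denominator (e.g. a constant prediction) are set to 0.
    """
    if len(maps_with_labels) < 2:
        raise ValueError("need at least two subjects for a heatmap")
    labels = [lab for _, lab in maps_with_labels]
    if len({lab for lab in labels}) < 2:
        raise ValueError("both classes must be present")
    first = maps_with_labels[0][0]
    shape = first.probs.shape
    for m, _ in maps_with_labels:
        if m.probs.shape != shape or m.stride != first.stride or m.offset != first.offset:
            raise ValueError("probability maps must share lattice geometry")
    tp = np.zeros(shape, dtype=np.int64)
    tn = np.zeros(shape, dtype=np.int64)
    fp = np.zeros(shape, dtype=np.int64)
    fn = np.zeros(shape, dtype=np.int64)
    for m, lab in maps_with_labels:
        pred_ad = m.probs > threshold
        if lab == "AD":
            tp += pred_ad
            fn += ~pred_ad
        else:
            fp += pred_ad
            tn += ~pred_ad
    tp_f, tn_f, fp_f, fn_f = (a.astype(np.float64) for a in (tp, tn, fp, fn))
    num = tp_f * tn_f - fp_f * fn_f
    den = np.sqrt((tp_f + fp_f) * (tp_f + fn_f) * (tn_f + fp_f) * (tn_f + fn_f))
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return MCCHeatmap(values=values, stride=first.stride, offset=first.offset,
                      n_subjects=len(maps_with_labels))


def select_roi(heatmap: MCCHeatmap, k: int) -> ROIMask:
    """The k lattice sites with the largest MCC (ties lexicographic)."""
    n_sites = heatmap.values.size
    if k > n_sites:
        raise ValueError(f"k={k} exceeds the {n_sites} lattice sites")
    flat = heatmap.values.reshape(-1)
    # stable sort on -value keeps lexicographic (C-order) tie-breaking
    order = np.argsort(-flat, kind="stable")[:k]
    sites = tuple(tuple(int(v) for v in np.unravel_index(i, heatmap.values.shape)) for i in order)
    return ROIMask(sites=sites, k=k)


def extract_roi_features(pmap: ProbabilityMap, roi: ROIMask) -> np.ndarray:
    """p(AD) at the ROI sites, in ROI order (the MLP's imaging features)."""
    out = np.empty(roi.k, dtype=np.float64)
    for j, site in enumerate(roi.sites):
        for ax, i in enumerate(site):
            if not (0 <= i < pmap.probs.shape[ax]):
                raise ValueError(f"ROI site {site} outside lattice {pmap.probs.shape}")
        out[j] = pmap.probs[site]
    return out


def upsample_to_voxels(hm, volume_shape) -> np.ndarray:
    """Trilinear upsampling of a lattice map to voxel resolution.

    Visualization only — every quantitative path works on the lattice.
    """
    from scipy.ndimage import map_coordinates
    values = hm.values if hasattr(hm, "values") else hm.probs
    coords = np.meshgrid(*[(np.arange(s) - hm.offset) / hm.stride for s in volume_shape],
                         indexing="ij")
    return map_coordinates(values, coords, order=1, mode="nearest")


def plot_map_slices(hm, path, title=""):
    """Minimal orthogonal-slice figure for a lattice map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    values = hm.values if hasattr(hm, "values") else hm.probs
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    centers = [s // 2 for s in values.shape]
    slices = [values[centers[0]], values[:, centers[1]], values[:, :, centers[2]]]
    for ax, sl, name in zip(axes, slices, ("axial", "coronal", "sagittal")):
        im = ax.imshow(sl.T, origin="lower", cmap="coolwarm")
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
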