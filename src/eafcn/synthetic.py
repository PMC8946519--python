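"""Synthetic cohorts with planted class-discriminative lesions.

Each subject's volume is a smooth noise field; for disease-class (AD)
subjects the intensity inside one or more spherical "lesions" is reduced by
a fixed effect size before smoothing, emulating the localized gray-matter
contrast that distinguishes patients from controls in registered T1 scans.
Demographics (age, sex, MMSE) are drawn from class-conditional truncated
normals matching the published cohort summary for 307 AD / 243 NC subjects:
age 76.3 (57-92) vs 79.4 (65-87) years, MMSE 22.8 (19-27) vs 28.6 (26-30),
male fractions 180/307 vs 101/243.  MMSE barely overlaps between classes,
so demographics carry real class signal, as they do in the clinical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .volume_io import BrainVolume, SubjectRecord, write_subject_table, write_volume

__all__ = ["CohortSpec", "DEMOGRAPHICS", "sample_demographics", "simulate_cohort", "write_cohort"]

#: class-conditional (mean, low, high) for age and MMSE, and male fraction.
#: The truncated-normal SD is (high - low) / 4 so ~95% of the untruncated
#: mass falls inside the published range.
DEMOGRAPHICS = {
    "AD": {"age": (76.3, 57.0, 92.0), "mmse": (22.8, 19, 27), "male_frac": 180 / 307},
    "NC": {"age": (79.4, 65.0, 87.0), "mmse": (28.6, 26, 30), "male_frac": 101 / 243},
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one synthetic cohort.

    Defaults are the desk-scale study conditions: 20+20 subjects, 64^3
    volumes, one lesion sphere of radius 8 at the off-center voxel
    (24, 24, 24), intensity deficit 0.6 against background noise SD 0.2,
    lightly smoothed (sigma 1 voxel) after lesion insertion so lesion
    borders are not trivially sharp.
    """

    n_ad: int = 20
    n_nc: int = 20
    volume_shape: tuple = (64, 64, 64)
    lesion_centers: tuple = ((24, 24, 24),)
    lesion_radius: float = 8.0
    effect_size: float = 0.6
    noise_sd: float = 0.2
    smoothing_sigma: float = 1.0
    background_mean: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_ad < 0 or self.n_nc < 0:
            raise ValueError("subject counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for c in self.lesion_centers:
            for ax in range(3):
                if c[ax] - self.lesion_radius < 0 or c[ax] + self.lesion_radius > self.volume_shape[ax] - 1:
                    raise ValueError(
                        f"lesion sphere at {c} (radius {self.lesion_radius}) "
                        f"extends outside volume {self.volume_shape}")


def _truncnorm(mean, low, high, rng):
    sd = (high - low) / 4.0
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_demographics(label: str, rng: np.random.Generator):
    """Draw (age, sex, mmse) from the class-conditional distributions."""
    d = DEMOGRAPHICS[label]
    age = _truncnorm(*d["age"], rng)
    sex = "M" if rng.random() < d["male_frac"] else "F"
    mmse = int(np.clip(round(_truncnorm(*d["mmse"], rng)), d["mmse"][1], d["mmse"][2]))
    return age, sex, mmse


def _lesion_mask(shape, centers, radius):
    mask = np.zeros(shape, dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    for c in centers:
        dist2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        mask |= dist2 <= radius ** 2
    return mask


def simulate_cohort(spec: CohortSpec) -> list[tuple[SubjectRecord, BrainVolume]]:
    """Generate the full cohort, reproducibly from ``spec.seed``.

    AD subjects get the lesion deficit; NC subjects are pure background.
    Volumes are returned unnormalized (raw intensities); run
    :func:`eafcn.volume_io.normalize_intensity` before feeding the network.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2 ** 31), 17]))
    mask = _lesion_mask(spec.volume_shape, spec.lesion_centers, spec.lesion_radius)
    cohort = []
    labels = ["AD"] * spec.n_ad + ["NC"] * spec.n_nc
    for i, label in enumerate(labels):
        raw = rng.normal(spec.background_mean, spec.noise_sd, size=spec.volume_shape)
        if label == "AD" and spec.effect_size > 0:
            raw[mask] -= spec.effect_size
        if spec.smoothing_sigma > 0:
            raw = ndimage.gaussian_filter(raw, sigma=spec.smoothing_sigma)
        sid = f"sub-{i:03d}"
        age, sex, mmse = sample_demographics(label, rng)
        rec = SubjectRecord(subject_id=sid, label=label, age=round(age, 1), sex=sex, mmse=mmse,
                            volume_path=f"{sid}.nii.gz")
        vol = BrainVolume(voxels=raw.astype(np.float32), subject_id=sid)
        cohort.append((rec, vol))
    return cohort


def write_cohort(cohort, outdir) -> Path:
    """Write volumes + subjects.csv in the layout ``read_subject_table`` expects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for rec, vol in cohort:
        path = outdir / rec.volume_path
        write_volume(vol, path)
        records.append(rec)
    table = outdir / "subjects.csv"
    write_subject_table(records, table)
    return table
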