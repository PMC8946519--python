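"""Volume and subject-table I/O plus per-volume intensity normalization.

Volumes are NIfTI files (one 3D image per subject); subject metadata lives
in a CSV with columns ``subject_id, label, age, sex, mmse, volume_path``.
Intensity normalization is percentile clipping (default 1st-99th) followed
by a linear rescale to [0, 1], computed per volume, which suppresses
background outliers without reference to any other subject.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainVolume",
    "SubjectRecord",
    "LABELS",
    "LABEL_TO_INDEX",
    "read_volume",
    "write_volume",
    "normalize_intensity",
    "read_subject_table",
    "write_subject_table",
    "write_map",
]

LABELS = ("NC", "AD")
#: class indices used throughout: channel/label 0 = NC, 1 = AD
LABEL_TO_INDEX = {"NC": 0, "AD": 1}

SUBJECT_COLUMNS = ["subject_id", "label", "age", "sex", "mmse", "volume_path"]


@dataclass
class BrainVolume:
    """A subject's 3D intensity grid.

    Attributes
    ----------
    voxels : (D, H, W) float array, always finite
    subject_id : identifier string
    normalized : True once intensities have been mapped to [0, 1]
    """

    voxels: np.ndarray
    subject_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"BrainVolume requires a 3D grid, got ndim={self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"BrainVolume axes must be >= 1, got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("BrainVolume voxels must all be finite")
        if self.normalized:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"normalized volume outside [0, 1]: range [{lo}, {hi}]")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the subject table: diagnosis plus demographics."""

    subject_id: str
    label: str          # "AD" or "NC"
    age: float          # years, > 0
    sex: str            # "M" or "F"
    mmse: int           # Mini-Mental State Examination, 0-30
    volume_path: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"mmse must be in [0, 30], got {self.mmse}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")


def read_volume(path) -> BrainVolume:
    """Load a NIfTI file as a :class:`BrainVolume`.

    4D files holding a single frame are squeezed to 3D; anything that is not
    3D after squeezing is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image after squeeze, got shape {data.shape}")
    return BrainVolume(voxels=np.asarray(data, dtype=np.float32), subject_id=path.stem.replace(".nii", ""))


def write_volume(volume: BrainVolume, path) -> Path:
    """Write a volume as NIfTI with an identity affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def normalize_intensity(volume: BrainVolume, low_pct: float = 1.0, high_pct: float = 99.0) -> BrainVolume:
    """Percentile-clip then min-max rescale a volume's intensities to [0, 1].

    Values below the ``low_pct`` percentile (or above ``high_pct``) saturate
    at 0 (or 1); the mapping is affine in between, hence monotone.  A volume
    with zero clipped range maps to all zeros.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    v = volume.voxels
    if v.size == 0:
        raise ValueError("cannot normalize an empty volume")
    lo, hi = np.percentile(v, [low_pct, high_pct])
    if hi <= lo:
        out = np.zeros_like(v, dtype=np.float32)
    else:
        out = (np.clip(v, lo, hi) - lo) / (hi - lo)
        out = out.astype(np.float32)
    return BrainVolume(voxels=out, subject_id=volume.subject_id, normalized=True)


def read_subject_table(path) -> list[SubjectRecord]:
    """Read the subject CSV; labels and ranges are validated row by row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subject table not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "label": str, "sex": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(SubjectRecord(
            subject_id=str(row.subject_id),
            label=str(row.label),
            age=float(row.age),
            sex=str(row.sex),
            mmse=int(row.mmse),
            volume_path=str(row.volume_path),
        ))
    return records


def write_subject_table(records, path) -> Path:
    path = Path(path)
    df = pd.DataFrame([{
        "subject_id": r.subject_id,
        "label": r.label,
        "age": r.age,
        "sex": r.sex,
        "mmse": r.mmse,
        "volume_path": r.volume_path,
    } for r in records], columns=SUBJECT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def write_map(grid: np.ndarray, reference: BrainVolume, path, stride: int = 1, offset: int = 0) -> Path:
    """Write a lattice-valued map (probabilities, MCC, ...) as NIfTI.

    ``stride``/``offset`` record the lattice-to-voxel geometry in the NIfTI
    header (zooms and origin translation) so overlays align with the source
    volume the map was computed from.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"map grid must be 3D, got shape {grid.shape}")
    if not np.all(np.isfinite(grid)):
        raise ValueError("map grid contains non-finite values")
    affine = np.diag([float(stride)] * 3 + [1.0])
    affine[:3, 3] = float(offset)
    img = nib.Nifti1Image(grid.astype(np.float32), affine=affine)
    nib.save(img, str(path))
    return Path(path)


def read_map(path) -> tuple[np.ndarray, int, int]:
    """Read a map written by :func:`write_map`; returns (grid, stride, offset)."""
    img = nib.load(str(path))
    grid = np.squeeze(np.asanyarray(img.dataobj)).astype(np.float32)
    stride = int(round(float(img.affine[0, 0])))
    offset = int(round(float(img.affine[0, 3])))
    return grid, stride, offset
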