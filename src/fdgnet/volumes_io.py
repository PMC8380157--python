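"""Volume I/O, cropping and intensity standardization.

Volumes are single-channel 3D intensity grids read from NIfTI-1 files via
nibabel.  The stored axis order is taken as-is — no reorientation is
attempted — with the working grid convention (axis0, axis1, axis2) =
(80, 100, 76) for full-resolution FDG-PET.  Datasets pair each volume with
a subject ID, scan ID and a diagnosis label in {NC, MCI, AD}; a CSV
manifest (columns: path, subject_id, scan_id, label) ties the files
together on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

LABELS = ("NC", "MCI", "AD")

DEFAULT_SHAPE = (80, 100, 76)


@dataclass
class Volume:
    """Single-channel 3D intensity grid with optional voxel spacing (mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError(f"volume axes must be positive, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class Sample:
    volume: Volume
    subject_id: str
    scan_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class Dataset:
    """Ordered collection of samples; each subject carries a single label."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        by_subject: dict[str, str] = {}
        for s in self.samples:
            key = (s.subject_id, s.scan_id)
            if key in seen:
                raise ValueError(f"duplicate (subject_id, scan_id) {key}")
            seen.add(key)
            prev = by_subject.setdefault(s.subject_id, s.label)
            if prev != s.label:
                raise ValueError(f"subject {s.subject_id} carries labels {prev} and {s.label}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def subjects(self) -> dict[str, str]:
        """subject_id -> label map."""
        return {s.subject_id: s.label for s in self.samples}

    def subset(self, subject_ids) -> "Dataset":
        ids = set(subject_ids)
        return Dataset([s for s in self.samples if s.subject_id in ids])

    def restrict_labels(self, labels) -> "Dataset":
        keep = set(labels)
        return Dataset([s for s in self.samples if s.label in keep])


def read_volume(path) -> Volume:
    """Read a single-volume NIfTI-1 file.

    The grid is returned in stored axis order; voxel spacing comes from the
    header.  4-D / multi-frame files are rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise IOError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path} is not a single 3-D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    return Volume(data, voxel_size=tuple(float(z) for z in zooms),
                  meta={"path": str(path)})


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1; voxel spacing goes into the affine diagonal."""
    path = Path(path)
    vox = v.voxel_size or (1.0, 1.0, 1.0)
    affine = np.diag([*vox, 1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))


def center_crop(v: Volume, target: tuple[int, int, int]) -> Volume:
    """Centered crop to ``target``; odd remainders drop the high-index voxel.

    The low-side offset on each axis is floor((size - target) / 2), so for
    an odd remainder the extra voxel is discarded from the high-index end.
    """
    target = tuple(int(t) for t in target)
    if len(target) != 3:
        raise ValueError("target must have 3 axes")
    for ax, (s, t) in enumerate(zip(v.shape, target)):
        if t > s:
            raise ValueError(f"target {t} exceeds input size {s} on axis {ax}")
        if t < 1:
            raise ValueError("target axes must be positive")
    off = [(s - t) // 2 for s, t in zip(v.shape, target)]
    sl = tuple(slice(o, o + t) for o, t in zip(off, target))
    return Volume(v.data[sl].copy(), voxel_size=v.voxel_size,
                  meta={**v.meta, "crop_offset": tuple(off)})


def standardize_intensity(v: Volume, mask: np.ndarray | None = None) -> Volume:
    """Z-score the volume (optionally within a mask; outside set to 0)."""
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != v.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {v.shape}")
        if mask.sum() < 2:
            raise ValueError("mask must select at least 2 voxels")
        vals = v.data[mask]
    else:
        vals = v.data.ravel()
    mu, sd = vals.mean(), vals.std()
    out = np.zeros_like(v.data)
    if sd <= 1e-12 * max(1.0, abs(mu)):  # constant up to roundoff
        warnings.warn("constant volume: standardization returns all zeros")
    else:
        region = mask if mask is not None else slice(None)
        out[region] = (v.data[region] - mu) / sd
    return Volume(out, voxel_size=v.voxel_size, meta=dict(v.meta))


def read_manifest(manifest_path) -> Dataset:
    """Load a dataset from a CSV manifest (path, subject_id, scan_id, label).

    Relative volume paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str)
    required = {"path", "subject_id", "scan_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(df.columns))}")
    samples = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        samples.append(Sample(read_volume(p), row.subject_id, row.scan_id, row.label))
    return Dataset(samples)


def write_manifest(d: Dataset, out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write every volume as NIfTI plus the CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in d:
        fname = f"{s.subject_id}_{s.scan_id}.nii.gz"
        write_volume(s.volume, out_dir / fname)
        rows.append({"path": fname, "subject_id": s.subject_id,
                     "scan_id": s.scan_id, "label": s.label})
    mpath = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath
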