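"""Synthetic FDG-PET phantom cohorts.

Real FDG-PET of Alzheimer's disease shows regional hypometabolism that
deepens along the clinical spectrum NC -> MCI -> AD.  The phantoms emulate
only that class structure: a smooth ellipsoidal "brain" template, a fixed
region of interest (ROI) standing in for AD-affected cortex where the mean
signal is reduced by a class-dependent effect plus a per-subject random
offset, and additive Gaussian voxel noise.  Multiple scans per subject
share the subject's offset so that grouped train/test splitting is
exercised the way multi-scan clinical cohorts require.

Randomness is hierarchical: one seed per cohort spawns independent streams
per (class, subject index) and per scan, so enlarging the cohort never
perturbs the draws of earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .volumes_io import LABELS, Dataset, Sample, Volume

DESK_SHAPE = (32, 40, 30)
FULL_SHAPE = (80, 100, 76)


def default_roi(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal ROI in the anterior half of the grid (boolean mask)."""
    d, h, w = shape
    center = (d * 0.5, h * 0.25, w * 0.5)
    radii = (d * 0.22, h * 0.15, w * 0.22)
    zz, yy, xx = np.ogrid[:d, :h, :w]
    r2 = (((zz - center[0]) / radii[0]) ** 2
          + ((yy - center[1]) / radii[1]) ** 2
          + ((xx - center[2]) / radii[2]) ** 2)
    return r2 <= 1.0


def _brain_template(shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth ellipsoidal intensity blob: 1 at the center, fading to 0 outside."""
    d, h, w = shape
    zz, yy, xx = np.ogrid[:d, :h, :w]
    r2 = (((zz - (d - 1) / 2) / (d * 0.45)) ** 2
          + ((yy - (h - 1) / 2) / (h * 0.45)) ** 2
          + ((xx - (w - 1) / 2) / (w * 0.45)) ** 2)
    return np.clip(1.0 - r2, 0.0, None) ** 0.5


@dataclass
class PhantomConfig:
    """Study conditions for a phantom cohort.

    ``effect`` maps class -> mean regional signal reduction inside the ROI,
    ordered effect(NC)=0 <= effect(MCI) <= effect(AD).  ``subject_sd`` is the
    between-subject random-effect SD added to the class effect;
    ``noise_sd`` is the per-voxel Gaussian noise SD.
    """

    shape: tuple[int, int, int] = DESK_SHAPE
    effect: dict = field(default_factory=lambda: {"NC": 0.0, "MCI": 1.0, "AD": 2.0})
    subject_sd: float = 0.2
    noise_sd: float = 0.25
    scans_per_subject: int = 2
    roi: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 1 for s in self.shape):
            raise ValueError("shape axes must be positive")
        missing = set(LABELS) - set(self.effect)
        if missing:
            raise ValueError(f"effect missing classes {sorted(missing)}")
        if not (self.effect["NC"] <= self.effect["MCI"] <= self.effect["AD"]):
            raise ValueError("effects must be ordered NC <= MCI <= AD")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.scans_per_subject < 1:
            raise ValueError("scans_per_subject must be >= 1")
        if self.roi is None:
            self.roi = default_roi(self.shape)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.roi.shape != self.shape:
            raise ValueError("roi shape must match grid shape")
        if not self.roi.any():
            raise ValueError("roi must be non-empty")

    def to_yaml(self, path) -> None:
        doc = {
            "shape": list(self.shape),
            "effect": {k: float(v) for k, v in self.effect.items()},
            "subject_sd": float(self.subject_sd),
            "noise_sd": float(self.noise_sd),
            "scans_per_subject": int(self.scans_per_subject),
            "seed": int(self.seed),
            "roi": "default_ellipsoid" if self.roi is None else "custom",
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


def generate_phantom(cfg: PhantomConfig, label: str, subject_offset: float,
                     seed: int) -> Volume:
    """One phantom scan: template - (effect(label)+offset) inside ROI + noise.

    Deterministic given (cfg, label, subject_offset, seed); the seed drives
    only the voxel noise.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)
    data = _brain_template(cfg.shape).copy()
    data[cfg.roi] -= cfg.effect[label] + subject_offset
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    return Volume(data, voxel_size=(2.0, 2.0, 2.0),
                  meta={"label": label, "synthetic": True})


def generate_cohort(cfg: PhantomConfig, n_subjects_per_class: int) -> Dataset:
    """Balanced cohort: 3 * n subjects, ``scans_per_subject`` scans each.

    Each subject draws one offset ~ N(0, subject_sd^2) shared by all of its
    scans; scan noise streams are spawned per scan.
    """
    if n_subjects_per_class < 1:
        raise ValueError("n_subjects_per_class must be >= 1")
    root = np.random.SeedSequence(cfg.seed)
    samples = []
    for ci, label in enumerate(LABELS):
        for si in range(n_subjects_per_class):
            subj_ss = np.random.SeedSequence(entropy=root.entropy,
                                             spawn_key=(ci, si))
            streams = subj_ss.spawn(cfg.scans_per_subject + 1)
            offset = float(np.random.default_rng(streams[0]).normal(0.0, cfg.subject_sd))
            subject_id = f"{label}{si:03d}"
            for k in range(cfg.scans_per_subject):
                scan_seed = int(streams[k + 1].generate_state(1)[0] % (2**31))
                vol = generate_phantom(cfg, label, offset, scan_seed)
                samples.append(Sample(vol, subject_id, f"s{k}", label))
    return Dataset(samples)


def roi_mean(v: Volume, roi: np.ndarray) -> float:
    """Mean intensity inside the ROI — the 1-D summary the classes separate on."""
    return float(v.data[np.asarray(roi, dtype=bool)].mean())
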