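"""Multi-modal volume I/O, Gaussian smoothing and min-max normalization.

Volumes are plain ``numpy`` arrays indexed ``(x, y, z)``.  A subject is a
:class:`ModalityStack` of four co-registered MR sequences (Flair, T1, T1c,
T2) plus, optionally, a :class:`LabelVolume` of integer tissue classes 0-4.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

from ._mha import read_mha, write_mha

#: Canonical modality order used everywhere (feature names, registries, tables).
MODALITIES: tuple[str, ...] = ("flair", "t1", "t1c", "t2")

#: Valid tissue classes: 0 background/normal, 1 necrotic core, 2 edema,
#: 3 non-enhancing core, 4 enhancing core.
VALID_LABELS = frozenset({0, 1, 2, 3, 4})


class ShapeMismatchError(ValueError):
    """Raised when companion volumes do not share one voxel grid."""


@dataclass(frozen=True)
class ModalityStack:
    """Four co-registered scalar 3D volumes, one per MR sequence."""

    flair: np.ndarray
    t1: np.ndarray
    t1c: np.ndarray
    t2: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        shapes = {m: self.get(m).shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise ShapeMismatchError(f"modality shapes differ: {shapes}")
        for m in MODALITIES:
            vol = self.get(m)
            if vol.ndim != 3:
                raise ValueError(f"modality {m!r} is not 3D: shape {vol.shape}")
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"modality {m!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flair.shape

    def get(self, modality: str) -> np.ndarray:
        if modality not in MODALITIES:
            raise KeyError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
        return getattr(self, modality)

    def map(self, func: Callable[[np.ndarray], np.ndarray]) -> "ModalityStack":
        """Apply ``func`` to every modality volume, returning a new stack."""
        return replace(self, **{m: func(self.get(m)) for m in MODALITIES})


@dataclass(frozen=True)
class LabelVolume:
    """Integer 3D grid of tissue classes 0-4."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError(f"label volume is not 3D: shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label volume must be integer, got dtype {self.labels.dtype}")
        present = set(np.unique(self.labels).tolist())
        unexpected = present - VALID_LABELS
        if unexpected:
            raise ValueError(
                f"unexpected tissue classes {sorted(unexpected)}; valid classes are 0-4"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | os.PathLike) -> np.ndarray:
    """Load one 3D volume from NIfTI (.nii/.nii.gz) or MetaImage (.mha)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix == ".mha":
        return read_mha(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data


def save_volume(path: str | os.PathLike, volume: np.ndarray) -> None:
    """Save one 3D volume as NIfTI or MetaImage, chosen by extension."""
    path = Path(path)
    if path.suffix == ".mha":
        write_mha(path, volume)
    else:
        nib.save(nib.Nifti1Image(np.asarray(volume), affine=np.eye(4)), str(path))


def load_subject(
    modality_paths: Mapping[str, str | os.PathLike],
    label_path: str | os.PathLike | None = None,
    subject_id: str = "subject",
) -> tuple[ModalityStack, LabelVolume | None]:
    """Load a subject's four modality volumes plus, optionally, its labels.

    Raises on missing files, on modality grids of differing shape, and on
    label values outside classes 0-4.
    """
    missing = [m for m in MODALITIES if m not in modality_paths]
    if missing:
        raise KeyError(f"modality paths missing for {missing}")
    volumes = {m: load_volume(modality_paths[m]) for m in MODALITIES}
    stack = ModalityStack(subject_id=subject_id, **volumes)
    labels: LabelVolume | None = None
    if label_path is not None:
        raw = load_volume(label_path)
        labels = LabelVolume(np.rint(raw).astype(np.int64))
        if labels.shape != stack.shape:
            raise ShapeMismatchError(
                f"label shape {labels.shape} != modality shape {stack.shape}"
            )
    return stack, labels


def save_subject(
    directory: str | os.PathLike,
    stack: ModalityStack,
    labels: LabelVolume | None = None,
    fmt: str = "nii.gz",
) -> dict:
    """Write a subject's volumes to ``directory``; return its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entry: dict = {"subject_id": stack.subject_id, "modalities": {}}
    for m in MODALITIES:
        path = directory / f"{stack.subject_id}_{m}.{fmt}"
        save_volume(path, stack.get(m))
        entry["modalities"][m] = str(path)
    if labels is not None:
        path = directory / f"{stack.subject_id}_seg.{fmt}"
        save_volume(path, labels.labels.astype(np.int16))
        entry["labels"] = str(path)
    return entry


def load_manifest(path: str | os.PathLike) -> list[dict]:
    """Read a JSON subject manifest (list of entries as written by save_manifest)."""
    with open(path) as fh:
        manifest = json.load(fh)
    if not isinstance(manifest, list):
        raise ValueError(f"{path}: manifest must be a JSON list of subject entries")
    return manifest


def save_manifest(path: str | os.PathLike, entries: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def gaussian_smooth(volume: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-filter a volume (reflect boundary); ``sigma`` in voxels, >= 0."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    volume = np.asarray(volume, dtype=np.float64)
    if sigma == 0:
        return volume.copy()
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="reflect")


def minmax_normalize(volume: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Rescale to [0, 1] via (X - X_min) / (X_max - X_min).

    Statistics are taken over the whole volume by default, or over ``mask``
    when given (e.g. brain-only voxels).  A constant volume is a degenerate
    input and raises ``ValueError``.
    """
    volume = np.asarray(volume, dtype=np.float64)
    sample = volume if mask is None else volume[mask]
    x_min = float(sample.min())
    x_max = float(sample.max())
    if x_max <= x_min:
        raise ValueError("cannot min-max normalize a constant volume (X_max == X_min)")
    return (volume - x_min) / (x_max - x_min)


def preprocess_stack(
    stack: ModalityStack, sigma: float = 0.5, brain_only: bool = False
) -> ModalityStack:
    """Smooth then min-max normalize every modality (the fixed pipeline order)."""

    def _one(volume: np.ndarray) -> np.ndarray:
        smoothed = gaussian_smooth(volume, sigma)
        mask = np.asarray(volume) != 0 if brain_only else None
        return minmax_normalize(smoothed, mask=mask)

    return stack.map(_one)
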