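"""Synthetic multi-modal phantoms with nested 5-class tumor anatomy.

A phantom is built from nested ellipsoids: brain > edema > core >
enhancing rim > necrotic center.  Labels follow the shell structure
(0 normal tissue, 2 edema, 3 non-enhancing core, 4 enhancing rim,
1 necrotic center); intensities are a per-class, per-modality mean plus
Gaussian noise, clipped to [0, 1].  LGG-like phantoms omit the enhancing
rim entirely (no class-4 voxels).

The default contrast table encodes the radiological structure the feature
bank exploits: edema is brightest on Flair, the enhancing rim on T1c, and
every class has a distinct (Flair, T1) signature so in-plane context
features carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess_io import (
    MODALITIES,
    LabelVolume,
    ModalityStack,
    save_manifest,
    save_subject,
)

#: Per-class, per-modality mean intensity (class -> modality -> mean in [0,1]).
DEFAULT_MEANS: dict[int, dict[str, float]] = {
    0: {"flair": 0.30, "t1": 0.35, "t1c": 0.35, "t2": 0.30},
    1: {"flair": 0.20, "t1": 0.15, "t1c": 0.10, "t2": 0.65},
    2: {"flair": 0.85, "t1": 0.30, "t1c": 0.30, "t2": 0.75},
    3: {"flair": 0.55, "t1": 0.50, "t1c": 0.45, "t2": 0.50},
    4: {"flair": 0.45, "t1": 0.60, "t1c": 0.90, "t2": 0.40},
}

#: Default compartment radii for a 48^3 grid, outermost first.
DEFAULT_RADII: dict[str, tuple[float, float, float]] = {
    "brain": (21.0, 21.0, 21.0),
    "edema": (15.0, 15.0, 14.0),
    "core": (11.0, 11.0, 10.5),
    "enhancing": (8.0, 8.0, 7.5),
    "necrosis": (4.5, 4.5, 4.5),
}

_COMPARTMENTS = ("brain", "edema", "core", "enhancing", "necrosis")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic subject."""

    shape: tuple[int, int, int] = (48, 48, 48)
    seed: int = 0
    subject_id: str = "phantom"
    cohort: str = "HGG"  # "HGG" (all classes) or "LGG" (no enhancing rim)
    center: tuple[float, float, float] | None = None
    radii: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_RADII.items()}
    )
    means: dict[int, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_MEANS.items()}
    )
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.noise_sd}")
        if self.cohort not in ("HGG", "LGG"):
            raise ValueError(f"cohort must be HGG or LGG, got {self.cohort!r}")
        order = [c for c in _COMPARTMENTS if self.cohort == "HGG" or c != "enhancing"]
        for outer, inner in zip(order, order[1:]):
            ro, ri = self.radii[outer], self.radii[inner]
            if not all(a > b for a, b in zip(ro, ri)):
                raise ValueError(f"non-nested radii: {outer} {ro} must enclose {inner} {ri}")
        for c, table in self.means.items():
            for m, v in table.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"mean intensity out of [0,1]: class {c}, {m} = {v}")

    @property
    def effective_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple((n - 1) / 2.0 for n in self.shape)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ModalityStack, LabelVolume]:
    """Render one phantom deterministically from its spec."""
    center = spec.effective_center
    masks = {name: _ellipsoid_mask(spec.shape, center, spec.radii[name]) for name in _COMPARTMENTS}
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[masks["edema"]] = 2
    labels[masks["core"]] = 3
    if spec.cohort == "HGG":
        labels[masks["enhancing"]] = 4
    labels[masks["necrosis"]] = 1

    rng = np.random.default_rng(spec.seed)
    volumes: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        mean_of_class = np.array([spec.means[c][m] for c in range(5)])
        vol = mean_of_class[labels]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        volumes[m] = np.clip(vol, 0.0, 1.0)
    return ModalityStack(subject_id=spec.subject_id, **volumes), LabelVolume(labels)


@dataclass(frozen=True)
class PhantomSubject:
    """One generated cohort member, held in memory."""

    subject_id: str
    cohort: str
    stack: ModalityStack
    labels: LabelVolume
    spec: PhantomSpec


def cohort_specs(
    n_subjects: int,
    seed: int = 0,
    hgg_fraction: float = 0.8,
    shape: tuple[int, int, int] = (48, 48, 48),
    jitter: float = 0.10,
    noise_sd: float = 0.05,
) -> list[PhantomSpec]:
    """Specs for a jittered cohort: centers/radii perturbed uniformly within
    +/- ``jitter`` per subject; the first round(n * hgg_fraction) subjects
    are HGG-like, the rest LGG-like.
    """
    if n_subjects < 1:
        raise ValueError(f"need n_subjects >= 1, got {n_subjects}")
    n_hgg = int(round(n_subjects * hgg_fraction))
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        cohort = "HGG" if i < n_hgg else "LGG"
        base_center = tuple((n - 1) / 2.0 for n in shape)
        center = tuple(
            c * (1.0 + rng.uniform(-jitter, jitter)) for c in base_center
        )
        radii = {
            name: tuple(r * (1.0 + rng.uniform(-jitter, jitter)) for r in rs)
            for name, rs in DEFAULT_RADII.items()
        }
        specs.append(
            PhantomSpec(
                shape=shape,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"phantom_{i:03d}",
                cohort=cohort,
                center=center,
                radii=radii,
                noise_sd=noise_sd,
            )
        )
    return specs


def generate_cohort(
    n_subjects: int,
    seed: int = 0,
    hgg_fraction: float = 0.8,
    shape: tuple[int, int, int] = (48, 48, 48),
    jitter: float = 0.10,
    noise_sd: float = 0.05,
) -> list[PhantomSubject]:
    """Generate an in-memory cohort of jittered phantoms."""
    subjects = []
    for spec in cohort_specs(n_subjects, seed, hgg_fraction, shape, jitter, noise_sd):
        stack, labels = generate_phantom(spec)
        subjects.append(
            PhantomSubject(
                subject_id=spec.subject_id,
                cohort=spec.cohort,
                stack=stack,
                labels=labels,
                spec=spec,
            )
        )
    return subjects


def write_cohort(
    subjects: list[PhantomSubject], directory: str | Path, fmt: str = "nii.gz"
) -> Path:
    """Write a cohort to disk plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for subj in subjects:
        entry = save_subject(directory, subj.stack, subj.labels, fmt=fmt)
        entry["cohort"] = subj.cohort
        entries.append(entry)
    manifest_path = directory / "manifest.json"
    save_manifest(manifest_path, entries)
    return manifest_path
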