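"""Ray-based context features on axial (in-plane) slices of T1 and Flair.

Every voxel probes its surroundings along straight in-plane rays.  A ray is
parameterised by an angle and a radius; its value is the mean intensity of
the voxels sampled at unit steps from the voxel outward, rescaled by robust
histogram bounds (H_min, H_max) of the source modality and clipped to
[0, 1].

Two feature groups are derived:

* the original context-sensitive features — 4 fixed rays (angles 0, pi/2,
  pi, 2*pi/3) at radii 10 and 20, averaged over angles, per modality;
* the circular context-sensitive (CCS) features — rays swept over a full
  circle of directions and a range of radii, pooled into equal-width radius
  bands, per modality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocess_io import ModalityStack

#: Modalities context features are computed on (in-plane, canonical order).
CONTEXT_MODALITIES: tuple[str, ...] = ("flair", "t1")

ORIGINAL_CS_ANGLES: tuple[float, ...] = (0.0, math.pi / 2, math.pi, 2 * math.pi / 3)
ORIGINAL_CS_RADII: tuple[float, ...] = (10.0, 20.0)


@dataclass(frozen=True)
class RayConfig:
    """Geometry of the circular ray sweep.

    Angles are ``beta0 + n * beta_step`` for n = 0..n_beta-1 with
    ``beta_step = 2*pi/n_beta``; radii are ``r0 + n * r_step`` for
    n = 1..n_r with ``r_step = (r_max - r_min) / n_r``.

    The default (8 directions, radii the even integers 10..20, i.e. 6
    circles) matches the fixed geometry used throughout the package.
    """

    beta0: float = 0.0
    n_beta: int = 8
    r0: float = 8.0
    r_min: float = 8.0
    r_max: float = 20.0
    n_r: int = 6

    def __post_init__(self) -> None:
        if self.n_beta < 1:
            raise ValueError(f"n_beta must be >= 1, got {self.n_beta}")
        if self.n_r < 1:
            raise ValueError(f"n_r must be >= 1, got {self.n_r}")
        if not (self.r_max > self.r_min >= 0):
            raise ValueError(f"need r_max > r_min >= 0, got [{self.r_min}, {self.r_max}]")

    @property
    def beta_step(self) -> float:
        return 2 * math.pi / self.n_beta

    @property
    def r_step(self) -> float:
        return (self.r_max - self.r_min) / self.n_r

    def angles(self) -> tuple[float, ...]:
        return tuple((self.beta0 + n * self.beta_step) % (2 * math.pi) for n in range(self.n_beta))

    def radii(self) -> tuple[float, ...]:
        # n runs over the positive naturals (n >= 1).
        return tuple(self.r0 + n * self.r_step for n in range(1, self.n_r + 1))


DEFAULT_RAY_CONFIG = RayConfig()


def generate_rays(config: RayConfig) -> list[tuple[float, float]]:
    """All (angle, radius) pairs, radius-major then angle; n_beta * n_r total."""
    return [(ang, r) for r in config.radii() for ang in config.angles()]


@dataclass(frozen=True)
class HistogramBounds:
    """Robust intensity bounds (H_min, H_max) for ray normalization."""

    h_min: float
    h_max: float
    n_bins: int = 64
    source_modality: str = ""

    def __post_init__(self) -> None:
        if not self.h_max > self.h_min:
            raise ValueError(f"need h_max > h_min, got [{self.h_min}, {self.h_max}]")


def histogram_bounds(
    volume: np.ndarray,
    n_bins: int = 64,
    percentiles: tuple[float, float] = (1.0, 99.0),
    mask: np.ndarray | None = None,
    source_modality: str = "",
) -> HistogramBounds:
    """H_min/H_max as robust percentiles of brain-voxel intensities.

    Brain voxels are ``mask`` when given, else all nonzero-intensity voxels
    (falling back to the whole volume if it has no zeros to exclude).
    """
    volume = np.asarray(volume, dtype=np.float64)
    sample = volume[mask] if mask is not None else volume[volume != 0]
    if sample.size == 0:
        sample = volume.ravel()
    if np.unique(sample).size < 2:
        raise ValueError("cannot derive histogram bounds from a constant volume")
    h_min, h_max = np.percentile(sample, percentiles)
    return HistogramBounds(
        h_min=float(h_min), h_max=float(h_max), n_bins=n_bins, source_modality=source_modality
    )


def _ray_offsets(angle: float, radius: float) -> list[tuple[int, int]]:
    """Nearest-voxel in-plane offsets at unit steps t = 1..round(radius)."""
    n = int(round(radius))
    c, s = math.cos(angle), math.sin(angle)
    return [(int(round(t * c)), int(round(t * s))) for t in range(1, n + 1)]


def ray_mean(
    volume: np.ndarray,
    center: tuple[int, int, int],
    angle: float,
    radius: float,
    bounds: HistogramBounds,
) -> float:
    """Normalized mean intensity along one in-plane ray from ``center``.

    Out-of-bounds samples are dropped; a ray with no in-bounds sample
    returns the background value 0.  The raw mean m is mapped to
    ``clip((m - h_min) / (h_max - h_min), 0, 1)``.
    """
    volume = np.asarray(volume)
    nx, ny, _ = volume.shape
    x0, y0, z0 = center
    samples = []
    for dx, dy in _ray_offsets(angle, radius):
        x, y = x0 + dx, y0 + dy
        if 0 <= x < nx and 0 <= y < ny:
            samples.append(float(volume[x, y, z0]))
    if not samples:
        return 0.0
    m = float(np.mean(samples))
    return float(np.clip((m - bounds.h_min) / (bounds.h_max - bounds.h_min), 0.0, 1.0))


def _shifted_sum_counts(volume: np.ndarray, offsets: Sequence[tuple[int, int]]):
    """Running (sum, count) volumes over in-plane shifts, yielded per prefix.

    ``yield`` after each offset so callers can snapshot the cumulative mean
    at any prefix length (prefixes correspond to rays of growing radius
    along a fixed direction).
    """
    nx, ny, _ = volume.shape
    total = np.zeros(volume.shape, dtype=np.float64)
    count = np.zeros(volume.shape, dtype=np.float64)
    for dx, dy in offsets:
        xs_lo, xs_hi = max(0, -dx), min(nx, nx - dx)
        ys_lo, ys_hi = max(0, -dy), min(ny, ny - dy)
        if xs_lo < xs_hi and ys_lo < ys_hi:
            dst = (slice(xs_lo, xs_hi), slice(ys_lo, ys_hi), slice(None))
            src = (slice(xs_lo + dx, xs_hi + dx), slice(ys_lo + dy, ys_hi + dy), slice(None))
            total[dst] += volume[src]
            count[dst] += 1.0
        yield total, count


def ray_mean_map(
    volume: np.ndarray, rays: Sequence[tuple[float, float]], bounds: HistogramBounds
) -> list[np.ndarray]:
    """Vectorized :func:`ray_mean` over every voxel, one 3D map per ray.

    Rays sharing a direction reuse prefix sums of the shifted volumes, so
    the cost is O(directions * max-radius) volume additions.
    """
    volume = np.asarray(volume, dtype=np.float64)
    by_angle: dict[float, list[int]] = {}
    for i, (ang, _) in enumerate(rays):
        by_angle.setdefault(ang, []).append(i)
    out: list[np.ndarray | None] = [None] * len(rays)
    scale = bounds.h_max - bounds.h_min
    for ang, indices in by_angle.items():
        max_r = max(int(round(rays[i][1])) for i in indices)
        offsets = _ray_offsets(ang, max_r)
        want = {int(round(rays[i][1])): [] for i in indices}
        for i in indices:
            want[int(round(rays[i][1]))].append(i)
        for t, (total, count) in enumerate(_shifted_sum_counts(volume, offsets), start=1):
            if t in want:
                with np.errstate(invalid="ignore", divide="ignore"):
                    mean = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
                value = np.clip((mean - bounds.h_min) / scale, 0.0, 1.0)
                value[count == 0] = 0.0
                for i in want[t]:
                    out[i] = value if len(want[t]) == 1 else value.copy()
    return [m for m in out]  # type: ignore[list-item]


def ccs_features(
    stack: ModalityStack,
    config: RayConfig = DEFAULT_RAY_CONFIG,
    bounds: Mapping[str, HistogramBounds] | None = None,
    n_bands: int = 6,
) -> dict[str, np.ndarray]:
    """Circular context-sensitive features: per modality (T1, Flair) the ray
    means are averaged within ``n_bands`` equal-width radius bands over
    (r_min, r_max], giving 2 * n_bands maps (12 by default).
    """
    radii = config.radii()
    if len(set(int(round(r)) for r in radii)) < n_bands:
        raise ValueError(
            f"ray config yields {len(set(radii))} distinct radii; need >= {n_bands} bands"
        )
    if bounds is None:
        bounds = {m: histogram_bounds(stack.get(m), source_modality=m) for m in CONTEXT_MODALITIES}
    width = (config.r_max - config.r_min) / n_bands
    rays = generate_rays(config)
    band_of_ray = [
        min(n_bands - 1, max(0, math.ceil((r - config.r_min) / width) - 1)) for _, r in rays
    ]
    maps: dict[str, np.ndarray] = {}
    for m in CONTEXT_MODALITIES:
        per_ray = ray_mean_map(stack.get(m), rays, bounds[m])
        for b in range(n_bands):
            members = [per_ray[i] for i in range(len(rays)) if band_of_ray[i] == b]
            if not members:
                raise ValueError(f"radius band {b + 1} contains no rays")
            maps[f"ccs_{m}_b{b + 1}"] = np.mean(members, axis=0)
    return maps


def original_cs_features(
    stack: ModalityStack,
    bounds: Mapping[str, HistogramBounds] | None = None,
    radii: Sequence[float] = ORIGINAL_CS_RADII,
    angles: Sequence[float] = ORIGINAL_CS_ANGLES,
) -> dict[str, np.ndarray]:
    """Original context-sensitive features: per modality and radius, the mean
    ray value over the four fixed angles — 4 maps by default.
    """
    if bounds is None:
        bounds = {m: histogram_bounds(stack.get(m), source_modality=m) for m in CONTEXT_MODALITIES}
    maps: dict[str, np.ndarray] = {}
    for m in CONTEXT_MODALITIES:
        for r in radii:
            rays = [(ang, float(r)) for ang in angles]
            per_ray = ray_mean_map(stack.get(m), rays, bounds[m])
            maps[f"cs_{m}_{int(r)}"] = np.mean(per_ray, axis=0)
    return maps
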