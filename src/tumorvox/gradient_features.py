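"""Gradient feature bank: in-plane (Gradient2D) and volumetric (Gradient3D).

The Gradient3D group decomposes into five subsets: per-modality gradient
magnitude (GM), cube-neighborhood mean/variance of GM per modality
(rMean/rVar at sizes 3, 5, 7), and the same statistics pooled across all
four modalities (seqMean/seqVar).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .preprocess_io import MODALITIES, ModalityStack

_AXIS_BY_NAME = {"x": 0, "y": 1, "z": 2}
#: Coordinate planes and their member axes, in canonical order.
PLANES: tuple[tuple[str, tuple[str, str]], ...] = (
    ("xy", ("x", "y")),
    ("xz", ("x", "z")),
    ("yz", ("y", "z")),
)
CUBE_SIZES: tuple[int, ...] = (3, 5, 7)

GROUP_GRADIENT2D = "Gradient2D"
GROUP_GRADIENT3D = "Gradient3D"
GROUP_CONTEXT = "ContextSensitive"
GROUP_CCS = "CCS"


def central_difference(
    volume: np.ndarray, axis: str | int, boundary: str = "one_sided"
) -> np.ndarray:
    """Central-difference derivative (I(p+1) - I(p-1)) / 2 along one axis.

    Boundary planes use first-order one-sided differences by default, or
    zeros with ``boundary="zero"``.
    """
    volume = np.asarray(volume, dtype=np.float64)
    ax = _AXIS_BY_NAME[axis] if isinstance(axis, str) else int(axis)
    if volume.shape[ax] < 3:
        raise ValueError(f"axis {axis!r} has length {volume.shape[ax]} < 3")
    out = np.empty_like(volume)

    def sl(start, stop):
        idx = [slice(None)] * volume.ndim
        idx[ax] = slice(start, stop)
        return tuple(idx)

    out[sl(1, -1)] = (volume[sl(2, None)] - volume[sl(None, -2)]) / 2.0
    if boundary == "one_sided":
        out[sl(0, 1)] = volume[sl(1, 2)] - volume[sl(0, 1)]
        out[sl(-1, None)] = volume[sl(-1, None)] - volume[sl(-2, -1)]
    elif boundary == "zero":
        out[sl(0, 1)] = 0.0
        out[sl(-1, None)] = 0.0
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    return out


def gradient_magnitude_3d(volume: np.ndarray, boundary: str = "one_sided") -> np.ndarray:
    """sqrt(G_x^2 + G_y^2 + G_z^2) with central-difference directional gradients."""
    gx = central_difference(volume, "x", boundary)
    gy = central_difference(volume, "y", boundary)
    gz = central_difference(volume, "z", boundary)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def gradient2d_features(
    stack: ModalityStack, boundary: str = "one_sided"
) -> dict[str, np.ndarray]:
    """In-plane 2D gradient magnitude per modality and coordinate plane.

    For each of the 4 modalities and each plane (xy, xz, yz) the feature is
    the magnitude of the two in-plane central-difference components, giving
    12 maps.
    """
    maps: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        volume = stack.get(m)
        derivs = {a: central_difference(volume, a, boundary) for a in ("x", "y", "z")}
        for plane, (a1, a2) in PLANES:
            maps[f"g2d_{m}_{plane}"] = np.hypot(derivs[a1], derivs[a2])
    return maps


def _cube_mean(values: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(values, size=size, mode="reflect")


def cube_stats(values: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mean and population variance over a size^3 cube (reflect edges)."""
    if size not in CUBE_SIZES:
        raise ValueError(f"cube size must be one of {CUBE_SIZES}, got {size}")
    values = np.asarray(values, dtype=np.float64)
    mean = _cube_mean(values, size)
    sq_mean = _cube_mean(values * values, size)
    var = np.maximum(sq_mean - mean * mean, 0.0)
    return mean, var


def seq_stats(
    gm_maps: Sequence[np.ndarray], size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/population variance pooled over all modalities' cube neighborhoods.

    Statistics are over the 4 * size^3 values gathered from the same cube in
    each of the four GM maps.
    """
    if size not in CUBE_SIZES:
        raise ValueError(f"cube size must be one of {CUBE_SIZES}, got {size}")
    shapes = {m.shape for m in gm_maps}
    if len(shapes) != 1:
        raise ValueError(f"GM maps must share one shape, got {shapes}")
    maps = [np.asarray(m, dtype=np.float64) for m in gm_maps]
    mean = np.mean([_cube_mean(m, size) for m in maps], axis=0)
    sq_mean = np.mean([_cube_mean(m * m, size) for m in maps], axis=0)
    var = np.maximum(sq_mean - mean * mean, 0.0)
    return mean, var


def gradient3d_features(
    stack: ModalityStack,
    sizes: Iterable[int] = CUBE_SIZES,
    boundary: str = "one_sided",
) -> dict[str, np.ndarray]:
    """The 34 Gradient3D maps: 4 GM + 12 rMean + 12 rVar + 3 seqMean + 3 seqVar."""
    sizes = tuple(sizes)
    gm = {m: gradient_magnitude_3d(stack.get(m), boundary) for m in MODALITIES}
    maps: dict[str, np.ndarray] = {f"GM_{m}": gm[m] for m in MODALITIES}
    r_mean: dict[str, np.ndarray] = {}
    r_var: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        for s in sizes:
            mean, var = cube_stats(gm[m], s)
            r_mean[f"rMean_{m}_{s}"] = mean
            r_var[f"rVar_{m}_{s}"] = var
    maps.update(r_mean)
    maps.update(r_var)
    seq_mean: dict[str, np.ndarray] = {}
    seq_var: dict[str, np.ndarray] = {}
    for s in sizes:
        mean, var = seq_stats([gm[m] for m in MODALITIES], s)
        seq_mean[f"seqMean_{s}"] = mean
        seq_var[f"seqVar_{s}"] = var
    maps.update(seq_mean)
    maps.update(seq_var)
    return maps


@dataclass(frozen=True)
class FeatureRegistry:
    """Canonical, deterministic ordering of the full 62-feature bank."""

    names: tuple[str, ...]
    groups: dict[str, str]

    @classmethod
    def default(
        cls,
        sizes: Iterable[int] = CUBE_SIZES,
        cs_radii: Iterable[float] = (10, 20),
        n_bands: int = 6,
        context_modalities: Iterable[str] = ("flair", "t1"),
    ) -> "FeatureRegistry":
        sizes = tuple(sizes)
        ctx_mods = tuple(context_modalities)
        names: list[str] = []
        groups: dict[str, str] = {}

        def add(group: str, new: list[str]) -> None:
            for n in new:
                names.append(n)
                groups[n] = group

        add(GROUP_GRADIENT2D, [f"g2d_{m}_{p}" for m in MODALITIES for p, _ in PLANES])
        add(GROUP_GRADIENT3D, [f"GM_{m}" for m in MODALITIES])
        add(GROUP_GRADIENT3D, [f"rMean_{m}_{s}" for m in MODALITIES for s in sizes])
        add(GROUP_GRADIENT3D, [f"rVar_{m}_{s}" for m in MODALITIES for s in sizes])
        add(GROUP_GRADIENT3D, [f"seqMean_{s}" for s in sizes])
        add(GROUP_GRADIENT3D, [f"seqVar_{s}" for s in sizes])
        add(GROUP_CONTEXT, [f"cs_{m}_{int(r)}" for m in ctx_mods for r in cs_radii])
        add(GROUP_CCS, [f"ccs_{m}_b{b}" for m in ctx_mods for b in range(1, n_bands + 1)])
        return cls(names=tuple(names), groups=groups)

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.names:
            counts[self.groups[name]] = counts.get(self.groups[name], 0) + 1
        return counts

    def group_names(self, group: str) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.groups[n] == group)

    def __len__(self) -> int:
        return len(self.names)
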