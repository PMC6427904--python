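"""End-to-end voxel classification: ROI detection, feature-table assembly,
class-balanced sampling, random-forest training, subject-level k-fold
cross-validation, dimension sweep, and full-volume prediction.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Hashable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import mrmr_selection
from .context_features import (
    CONTEXT_MODALITIES,
    ORIGINAL_CS_ANGLES,
    ORIGINAL_CS_RADII,
    RayConfig,
    ccs_features,
    histogram_bounds,
    original_cs_features,
)
from .evaluation import COHORTS, METRIC_NAMES, REGIONS, RegionScores, evaluate_segmentation, mean_metric
from .gradient_features import (
    CUBE_SIZES,
    FeatureRegistry,
    gradient2d_features,
    gradient3d_features,
)
from .preprocess_io import LabelVolume, ModalityStack, preprocess_stack

logger = logging.getLogger(__name__)


class Subject(Protocol):
    """Anything with an id, a modality stack, labels and a cohort tag."""

    subject_id: str
    cohort: str
    stack: ModalityStack
    labels: LabelVolume


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, serializable to/from JSON."""

    sigma: float = 0.5  # Gaussian smoothing, voxels
    brain_only_norm: bool = False
    boundary: str = "one_sided"  # central-difference edge handling
    cube_sizes: tuple[int, ...] = CUBE_SIZES
    ray: RayConfig = field(default_factory=RayConfig)
    n_bands: int = 6
    cs_radii: tuple[float, ...] = ORIGINAL_CS_RADII
    cs_angles: tuple[float, ...] = ORIGINAL_CS_ANGLES
    percentiles: tuple[float, float] = (1.0, 99.0)
    n_trees: int = 100
    n_folds: int = 5
    per_class_cap: int | None = None  # optional cap on the balanced per-class count
    f_step: int = 5
    f_n_max: int = 12

    def registry(self) -> FeatureRegistry:
        return FeatureRegistry.default(
            sizes=self.cube_sizes, cs_radii=self.cs_radii, n_bands=self.n_bands
        )

    def f_values(self) -> list[int]:
        return mrmr_selection.sweep_f_values(
            n_features=len(self.registry()), step=self.f_step, n_max=self.f_n_max
        )

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "ray" in data and isinstance(data["ray"], dict):
            data["ray"] = RayConfig(**data["ray"])
        for key in ("cube_sizes", "cs_radii", "cs_angles", "percentiles"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


DEFAULT_CONFIG = PipelineConfig()


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIBox:
    """Half-open per-axis voxel intervals [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.lo, self.hi):
            if not 0 <= lo < hi:
                raise ValueError(f"invalid ROI interval [{lo}, {hi})")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.lo, self.hi))


def detect_roi(labels: LabelVolume | np.ndarray) -> ROIBox:
    """Minimal axis-aligned box containing every nonzero label (plane sweep)."""
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    nz = arr != 0
    if not nz.any():
        raise ValueError("all-zero label volume has no ROI")
    lo, hi = [], []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        profile = nz.any(axis=other)
        lo.append(int(np.argmax(profile)))
        hi.append(int(len(profile) - np.argmax(profile[::-1])))
    return ROIBox(lo=tuple(lo), hi=tuple(hi))


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def compute_feature_maps(
    stack: ModalityStack,
    config: PipelineConfig = DEFAULT_CONFIG,
    preprocess: bool = True,
) -> dict[str, np.ndarray]:
    """All 62 feature maps of a stack, keyed and ordered by the registry."""
    t0 = time.perf_counter()
    if preprocess:
        stack = preprocess_stack(stack, sigma=config.sigma, brain_only=config.brain_only_norm)
    maps: dict[str, np.ndarray] = {}
    maps.update(gradient2d_features(stack, boundary=config.boundary))
    maps.update(gradient3d_features(stack, sizes=config.cube_sizes, boundary=config.boundary))
    bounds = {
        m: histogram_bounds(stack.get(m), percentiles=config.percentiles, source_modality=m)
        for m in CONTEXT_MODALITIES
    }
    maps.update(
        original_cs_features(stack, bounds, radii=config.cs_radii, angles=config.cs_angles)
    )
    maps.update(ccs_features(stack, config.ray, bounds, n_bands=config.n_bands))
    registry = config.registry()
    missing = [n for n in registry.names if n not in maps]
    if missing:
        raise RuntimeError(f"feature maps missing from registry order: {missing}")
    logger.debug(
        "feature maps for %s: %d maps in %.2fs",
        stack.subject_id,
        len(registry),
        time.perf_counter() - t0,
    )
    return {n: maps[n] for n in registry.names}


def feature_table(
    stack: ModalityStack,
    labels: LabelVolume | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    roi: ROIBox | None = None,
    feature_maps: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-voxel feature rows: subject_id, x, y, z, 62 features[, label].

    ``roi`` restricts rows to a box; precomputed ``feature_maps`` may be
    passed to avoid recomputation.
    """
    if feature_maps is None:
        feature_maps = compute_feature_maps(stack, config)
    sl = roi.slices if roi is not None else (slice(None),) * 3
    grids = np.meshgrid(
        *[np.arange(s.start or 0, s.stop if s.stop is not None else n)
          for s, n in zip(sl, stack.shape)],
        indexing="ij",
    )
    data: dict[str, np.ndarray] = {
        "x": grids[0].ravel(),
        "y": grids[1].ravel(),
        "z": grids[2].ravel(),
    }
    for name, vol in feature_maps.items():
        data[name] = vol[sl].ravel().astype(np.float32)
    if labels is not None:
        data["label"] = labels.labels[sl].ravel()
    table = pd.DataFrame(data)
    table.insert(0, "subject_id", stack.subject_id)
    return table


def balanced_sample(
    table: pd.DataFrame,
    seed: int,
    classes: Sequence[int] = (0, 1, 2, 3, 4),
    cap: int | None = None,
) -> pd.DataFrame:
    """Uniform per-class subsample at the minimum class count.

    Every class in ``classes`` must be present; ``cap`` optionally bounds
    the per-class count (still uniform).  Sampling is uniform without
    replacement and deterministic in ``seed``.
    """
    counts = table["label"].value_counts()
    missing = sorted(c for c in classes if counts.get(c, 0) == 0)
    if missing:
        raise ValueError(f"classes absent from the sampling table: {missing}")
    m = int(min(counts[c] for c in classes))
    if cap is not None:
        m = min(m, int(cap))
    rng = np.random.default_rng(seed)
    parts = []
    for c in classes:
        idx = table.index[table["label"] == c].to_numpy()
        chosen = rng.choice(idx, size=m, replace=False)
        parts.append(table.loc[np.sort(chosen)])
    return pd.concat(parts, axis=0, ignore_index=True)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted forest plus the exact feature-name list it was trained on."""

    forest: RandomForestClassifier
    feature_names: list[str]
    seed: int
    classes: list[int]

    def predict_labels(self, table: pd.DataFrame) -> np.ndarray:
        """Per-row argmax class; ties break toward the lower label index."""
        missing = [n for n in self.feature_names if n not in table.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        x = table[self.feature_names].to_numpy()  # aligns by name regardless of order
        proba = self.forest.predict_proba(x)
        classes = np.asarray(self.forest.classes_)
        order = np.argsort(classes)  # argmax picks the first max -> lowest label wins ties
        return classes[order][np.argmax(proba[:, order], axis=1)]


def train_forest(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> TrainedModel:
    """Fit a ``n_trees``-tree random forest on the table's feature columns."""
    y = table["label"].to_numpy()
    classes = sorted(set(int(c) for c in np.unique(y)))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train, got {classes}")
    x = table[list(feature_names)].to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, max_features="sqrt"
    )
    forest.fit(x, y)
    return TrainedModel(
        forest=forest, feature_names=list(feature_names), seed=seed, classes=classes
    )


def predict_volume(
    model: TrainedModel,
    stack: ModalityStack,
    config: PipelineConfig = DEFAULT_CONFIG,
    feature_maps: Mapping[str, np.ndarray] | None = None,
) -> LabelVolume:
    """Classify every voxel of a stack into the 5 tissue classes."""
    table = feature_table(stack, labels=None, config=config, feature_maps=feature_maps)
    pred = model.predict_labels(table)
    return LabelVolume(pred.reshape(stack.shape).astype(np.int64))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class SubjectReport:
    subject_id: str
    cohort: str
    fold: int
    scores: dict[str, RegionScores]


@dataclass
class CVResult:
    """Per-fold and mean region metrics of a subject-level k-fold run."""

    folds: list[list[str]]  # test-subject ids per fold
    subject_reports: list[SubjectReport]
    seed: int

    def _cohort_reports(self, cohort: str) -> list[dict[str, RegionScores]]:
        return [
            r.scores
            for r in self.subject_reports
            if cohort == "HGG&LGG" or r.cohort == cohort
        ]

    def mean_metrics(self) -> dict[str, dict[str, dict[str, float | None]]]:
        """cohort -> region -> metric -> mean over subjects (None if undefined)."""
        out: dict[str, dict[str, dict[str, float | None]]] = {}
        for cohort in COHORTS:
            reports = self._cohort_reports(cohort)
            if not reports:
                continue
            out[cohort] = {
                region: {
                    metric: mean_metric(reports, region, metric)
                    for metric in METRIC_NAMES
                }
                for region in REGIONS
            }
        return out

    def metric_cells(self) -> dict[Hashable, float]:
        """Flat (cohort, region, metric) -> value table for the rank-sum sweep."""
        cells: dict[Hashable, float] = {}
        for cohort, regions in self.mean_metrics().items():
            for region, metric_values in regions.items():
                for metric, value in metric_values.items():
                    if value is not None:
                        cells[(cohort, region, metric)] = value
        return cells


def assign_folds(subject_ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Deterministic shuffle then split into k roughly equal folds."""
    ids = list(subject_ids)
    if len(ids) < k:
        raise ValueError(f"need >= {k} subjects for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return [list(part) for part in np.array_split(shuffled, k)]


def _subject_roi_table(subject: Subject, config: PipelineConfig) -> pd.DataFrame:
    roi = detect_roi(subject.labels)
    maps = compute_feature_maps(subject.stack, config)
    return feature_table(
        subject.stack, subject.labels, config=config, roi=roi, feature_maps=maps
    )


def cross_validate(
    subjects: Sequence[Subject],
    config: PipelineConfig = DEFAULT_CONFIG,
    k: int | None = None,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    tables: Mapping[str, pd.DataFrame] | None = None,
) -> CVResult:
    """Subject-level k-fold cross-validation.

    For each fold, balanced voxel samples pooled over the training
    subjects' ROIs train a forest, which then predicts every ROI voxel of
    each held-out subject; metrics are per-subject over the composite
    regions within that subject's ROI.  Precomputed per-subject ROI tables
    may be supplied via ``tables`` (keyed by subject id).
    """
    k = k if k is not None else config.n_folds
    feature_names = list(feature_names) if feature_names else list(config.registry().names)
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    by_id = {s.subject_id: s for s in subjects}
    folds = assign_folds(ids, k, seed)

    if tables is None:
        tables = {}
        for s in subjects:
            t0 = time.perf_counter()
            tables[s.subject_id] = _subject_roi_table(s, config)
            logger.info(
                "features %s: %d ROI voxels in %.2fs",
                s.subject_id,
                len(tables[s.subject_id]),
                time.perf_counter() - t0,
            )

    reports: list[SubjectReport] = []
    for fold_idx, test_ids in enumerate(folds):
        train_ids = [i for i in ids if i not in set(test_ids)]
        train_table = pd.concat([tables[i] for i in train_ids], axis=0, ignore_index=True)
        balanced = balanced_sample(
            train_table, seed=seed + 1000 * (fold_idx + 1), cap=config.per_class_cap
        )
        t0 = time.perf_counter()
        model = train_forest(
            balanced, feature_names, n_trees=config.n_trees, seed=seed + fold_idx
        )
        logger.info(
            "fold %d: trained on %d rows (%d features) in %.2fs",
            fold_idx,
            len(balanced),
            len(feature_names),
            time.perf_counter() - t0,
        )
        for sid in test_ids:
            subject = by_id[sid]
            table = tables[sid]
            pred = model.predict_labels(table)
            truth = table["label"].to_numpy()
            scores = evaluate_segmentation(pred, truth)
            reports.append(
                SubjectReport(subject_id=sid, cohort=subject.cohort, fold=fold_idx, scores=scores)
            )
    return CVResult(folds=folds, subject_reports=reports, seed=seed)


# ---------------------------------------------------------------------------
# Dimension sweep wiring
# ---------------------------------------------------------------------------

def rank_features(
    subjects: Sequence[Subject],
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> mrmr_selection.MRMRResult:
    """One global mRMR ranking on the pooled balanced sample of all subjects."""
    pooled = pd.concat(
        [_subject_roi_table(s, config) for s in subjects], axis=0, ignore_index=True
    )
    balanced = balanced_sample(pooled, seed=seed, cap=config.per_class_cap)
    names = list(config.registry().names)
    return mrmr_selection.mrmr_rank(
        balanced[names], balanced["label"].to_numpy(), feature_names=names
    )


def run_dimension_sweep(
    subjects: Sequence[Subject],
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
    f_values: Sequence[int] | None = None,
) -> mrmr_selection.SweepResult:
    """Full model-selection harness: global mRMR ranking, then k-fold CV per
    top-f prefix, then rank-sum selection of the best dimension.
    """
    f_values = list(f_values) if f_values is not None else config.f_values()
    tables = {s.subject_id: _subject_roi_table(s, config) for s in subjects}
    pooled = pd.concat(tables.values(), axis=0, ignore_index=True)
    balanced = balanced_sample(pooled, seed=seed, cap=config.per_class_cap)
    names = list(config.registry().names)
    ranking = mrmr_selection.mrmr_rank(
        balanced[names], balanced["label"].to_numpy(), feature_names=names
    ).order

    def evaluate(feature_subset: Sequence[str]) -> dict[Hashable, float]:
        result = cross_validate(
            subjects, config=config, seed=seed, feature_names=feature_subset, tables=tables
        )
        return result.metric_cells()

    return mrmr_selection.dimension_sweep(ranking, f_values, evaluate)
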