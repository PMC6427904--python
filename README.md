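# tumorvox

Voxel-wise multi-modal MRI brain-tumor segmentation. Each voxel of a
co-registered 4-sequence scan (Flair, T1, T1c, T2) is described by a
62-feature bank and classified into five tissue classes (normal tissue,
necrotic core, edema, non-enhancing core, enhancing core) with a random
forest; results are scored over three composite regions (complete tumor,
tumor core, enhancing tumor).

## Pipeline

1. **Preprocessing** (`preprocess_io`) — Gaussian smoothing (default
   sigma 0.5 voxels) then per-volume min–max normalization to [0, 1].
2. **Feature bank** (62 features):
   - `gradient_features` — 12 *Gradient2D* maps (in-plane gradient
     magnitude per modality and coordinate plane) and 34 *Gradient3D*
     maps: per-modality 3D gradient magnitude (GM, 4), cube-neighborhood
     mean/variance of GM at sizes 3/5/7 (rMean/rVar, 12 + 12), and the
     same statistics pooled across all four modalities (seqMean/seqVar,
     3 + 3).
   - `context_features` — on T1 and Flair axial slices: 4 original
     context-sensitive features (fixed rays at radii 10/20, four angles)
     and 12 circular context-sensitive (CCS) features (8 directions ×
     radii 10–20, pooled into 6 radius bands). Ray means are normalized by
     robust per-modality histogram bounds (1st/99th percentiles).
3. **Feature selection** (`mrmr_selection`) — minimal-redundancy
   maximal-relevance greedy ranking (three-level μ±σ discretization,
   plug-in mutual information in bits), plus a dimension sweep over
   f = 62 − 5n (n = 0..12) with rank-sum model selection (ties go to the
   smaller feature set).
4. **Training/CV** (`pipeline`) — ROI cuboid detection from nonzero
   labels, class-balanced voxel sampling at the minimum class count,
   100-tree random forests, subject-level 5-fold cross-validation, and
   full-volume prediction.
5. **Evaluation** (`evaluation`) — Dice, PPV, sensitivity, specificity
   per composite region; zero-denominator metrics are reported as
   undefined (“–”), e.g. enhancing tumor for LGG-like subjects.
6. **Phantoms** (`synthetic_phantom`) — nested-ellipsoid 5-class phantoms
   with modality-specific contrast and noise, so the whole pipeline is
   testable without any external dataset.

Volumes are read/written as NIfTI (`.nii`/`.nii.gz`, via nibabel) or
uncompressed MetaImage (`.mha`, built-in codec); cohorts are described by
a JSON manifest mapping subject ids to per-modality paths.

## CLI

```bash
tumorvox simulate --n 10 --seed 1 --out cohort/            # phantoms + manifest
tumorvox extract-features --manifest cohort/manifest.json \
    --subject phantom_000 --out features.csv
tumorvox select-features --features features.csv --out ranking.json
tumorvox train --features features.csv --out model.joblib
tumorvox cross-validate --manifest cohort/manifest.json --seed 1 --out cv.json
tumorvox predict --manifest cohort/manifest.json --subject phantom_000 \
    --model model.joblib --out pred.nii.gz
tumorvox evaluate --pred pred.nii.gz --truth cohort/phantom_000_seg.nii.gz \
    --out report.json
```

A JSON pipeline config (`PipelineConfig.to_json`) can be passed to most
subcommands via `--config` to change smoothing, ray geometry, tree count,
folds, etc.

## Library use

```python
import tumorvox as tv

subjects = tv.generate_cohort(20, seed=0, hgg_fraction=0.8)
result = tv.cross_validate(subjects, k=5, seed=0)
print(result.mean_metrics()["HGG&LGG"]["complete"]["dice"])

sweep = tv.run_dimension_sweep(subjects[:5], seed=0)   # mRMR + rank-sum selection
print(sweep.selected_dimension)
```
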