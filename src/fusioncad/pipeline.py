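"""End-to-end orchestration: manifest -> features -> selection -> evaluation.

The pipeline composes the library modules into the four-stage CAD chain:

1. **Preprocessing.** Each manifest row is loaded as 8-bit grayscale. If a
   ground-truth mask is provided (the ultrasound convention, mirroring manual
   ROI delineation) it bypasses automatic segmentation; otherwise
   :func:`fusioncad.segmentation.segment_lesion` produces the lesion mask and
   the 25-pixel-padded ROI.
2. **Feature extraction.** Per sample: deep features (default: the seeded
   stub extractor, width 1920), the HOG+LBP texture vector reduced by PCA to
   199 components (fit per modality), and the 4 shape features -- concatenated
   in that fixed order into the 2123-wide hybrid vector.
3. **Feature fusion.** GA and MI selectors run on the hybrid table; their
   selections are concatenated (duplicates retained). With two modalities the
   per-modality tables are first balanced by random undersampling, paired
   within class (seeded random pairing) and column-concatenated (2 x 2123 =
   4246 wide) before selection.
4. **Classification.** Random undersampling, a stratified 80/20 split, one of
   the three classifiers, and the imbalance-aware evaluation report.

Every seed and intermediate artifact is written into the run directory so an
identical manifest + config reproduces an identical evaluation JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classify_eval, deep, segmentation, selection, shape, texture
from .data import FeatureTable
from .segmentation import SegmentationConfig
from .selection import GAConfig

logger = logging.getLogger("fusioncad")


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    descriptor_size: int = texture.DESCRIPTOR_SIZE
    deep_extractor: str = "stub"
    deep_dim: int = deep.DEFAULT_DEEP_DIM
    deep_seed: int = 0
    pca_components: int = texture.N_PCA_COMPONENTS
    ga: GAConfig = field(default_factory=GAConfig)
    mi_k: int = 3
    mi_top_k: int = 26
    rus_seed: int = 0
    split_fraction: float = 0.8
    split_seed: int = 0
    pairing_seed: int = 0
    classifier: str = "xgboost"
    classifier_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


def stratified_split(
    table: FeatureTable, fraction: float, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class proportional train/test split, seeded and exhaustive.

    The test share of each class is ``floor(n_class * (1 - fraction))``; the
    remainder goes to train. 420 balanced samples at fraction 0.8 therefore
    split 336/84 with 42 test samples per class.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in sorted(set(table.labels)):
        idx = np.flatnonzero(table.labels == label)
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        # epsilon guards the floor against float artifacts (0.2*210 = 41.999...)
        n_test = int(np.floor(len(idx) * (1 - fraction) + 1e-9))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    train_idx = rng.permutation(np.concatenate(train_idx))
    test_idx = rng.permutation(np.concatenate(test_idx))
    return table.subset_rows(train_idx), table.subset_rows(test_idx)


def _load_gray(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def extract_sample_features(
    img: np.ndarray,
    mask: np.ndarray | None,
    config: PipelineConfig,
    extractor: deep.DeepExtractor,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(deep vector, raw texture vector, shape vector) for one image."""
    if mask is not None:
        mask = (np.asarray(mask) > 0).astype(np.uint8)
        contours = segmentation.trace_contours(mask)
        contour, lesion_mask = segmentation.largest_lesion(contours, mask)
        box = segmentation.bounding_box(
            contour, config.segmentation.tolerance, img.shape
        )
        roi = box.crop(img)
    else:
        lesion_mask, roi = segmentation.segment_lesion(img, config.segmentation)
        contour, lesion_mask = segmentation.largest_lesion(
            segmentation.trace_contours(lesion_mask), lesion_mask
        )
    sf = shape.shape_features(lesion_mask, contour)
    tex = texture.texture_vector(roi, size=config.descriptor_size)
    dvec = extractor.extract(roi)
    return dvec, tex, sf.as_array()


def build_feature_table(
    manifest: pd.DataFrame, config: PipelineConfig
) -> FeatureTable:
    """Hybrid feature table (deep | PCA texture | shape) for one modality."""
    extractor = deep.get_extractor(config.deep_extractor, config.deep_dim, config.deep_seed)
    deeps, texes, shapes, labels = [], [], [], []
    for _, row in manifest.iterrows():
        img = _load_gray(row["path"])
        mask = None
        if "mask_path" in row and isinstance(row["mask_path"], str) and row["mask_path"]:
            mask = _load_gray(row["mask_path"])
        try:
            dvec, tex, svec = extract_sample_features(img, mask, config, extractor)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for {row['path']}: {exc}"
            ) from exc
        deeps.append(dvec)
        texes.append(tex)
        shapes.append(svec)
        labels.append(row["label"])
    pca = texture.pca_fit(np.vstack(texes), config.pca_components)
    hu = texture.pca_transform(pca, np.vstack(texes))
    values = np.hstack([np.vstack(deeps), hu, np.vstack(shapes)])
    names = (
        [f"deep_{i}" for i in range(config.deep_dim)]
        + [f"hu_{i}" for i in range(hu.shape[1])]
        + shape.SHAPE_FEATURE_NAMES
    )
    return FeatureTable(pd.DataFrame(values, columns=names), np.asarray(labels, dtype=object))


def pair_modalities(
    tables: dict[str, FeatureTable], rus_seed: int, pairing_seed: int
) -> FeatureTable:
    """Balance each modality table, pair rows within class, concatenate columns.

    Each modality is undersampled to the common per-class minimum; rows are
    then paired within class by a seeded random permutation (the pairing rule
    between modalities is an interpretation -- no natural key links an
    ultrasound patient to a mammography one) and column-concatenated with
    modality-prefixed names.
    """
    mods = sorted(tables)
    counts = [tables[m].class_counts() for m in mods]
    labels_all = sorted(set().union(*counts))
    per_class = {lab: min(c.get(lab, 0) for c in counts) for lab in labels_all}
    rng = np.random.default_rng(pairing_seed)
    blocks, labels = [], []
    for li, lab in enumerate(labels_all):
        per_mod_rows = []
        for mi, m in enumerate(mods):
            idx = np.flatnonzero(tables[m].labels == lab)
            sub_rng = np.random.default_rng([rus_seed, mi, li])
            idx = sub_rng.choice(idx, size=per_class[lab], replace=False)
            idx = idx[rng.permutation(per_class[lab])]  # random within-class pairing
            sub = tables[m].values.iloc[idx].reset_index(drop=True)
            sub.columns = [f"{m.lower()}_{c}" for c in sub.columns]
            per_mod_rows.append(sub)
        blocks.append(pd.concat(per_mod_rows, axis=1))
        labels.extend([lab] * per_class[lab])
    fused = pd.concat(blocks, axis=0, ignore_index=True)
    return FeatureTable(fused, np.asarray(labels, dtype=object))


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "runs/run",
) -> Path:
    """Execute the full chain on a manifest; returns the run directory."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        manifest = pd.read_csv(manifest_path, keep_default_na=False)
        logger.info("manifest: %d rows from %s", len(manifest), manifest_path)
        modalities = sorted(manifest["modality"].unique())

        tables: dict[str, FeatureTable] = {}
        for mod in modalities:
            sub = manifest[manifest["modality"] == mod]
            tables[mod] = build_feature_table(sub, config)
            tables[mod].values.assign(label=tables[mod].labels).to_csv(
                out / f"features_{mod}.csv", index=False
            )
            logger.info(
                "modality %s: %d samples x %d features", mod,
                tables[mod].n_samples, tables[mod].n_features,
            )

        if len(modalities) == 1:
            table = tables[modalities[0]]
        else:
            table = pair_modalities(tables, config.rus_seed, config.pairing_seed)
            logger.info(
                "paired modalities: %d samples x %d features",
                table.n_samples, table.n_features,
            )

        ga_mask = selection.ga_select(table, config.ga)
        mi = selection.mi_scores(table, k=config.mi_k, seed=config.ga.seed)
        mi_mask = selection.select_top_k(mi, min(config.mi_top_k, table.n_features))
        for mask, name in ((ga_mask, "ga"), (mi_mask, "mi")):
            with open(out / f"selection_{name}.json", "w") as fh:
                json.dump(
                    {
                        "method": mask.method,
                        "kept_columns": [
                            table.column_names[i] for i in mask.selected_indices()
                        ],
                        "scores": np.asarray(mask.scores, dtype=float).tolist(),
                    },
                    fh,
                )
        fused = selection.fuse_selections(table, ga_mask, mi_mask)
        logger.info(
            "fusion: GA %d + MI %d = %d columns",
            ga_mask.n_selected, mi_mask.n_selected, fused.n_features,
        )

        balanced = selection.random_undersample(fused, seed=config.rus_seed)
        train, test = stratified_split(balanced, config.split_fraction, config.split_seed)
        logger.info(
            "balanced %d -> train %d / test %d",
            balanced.n_samples, train.n_samples, test.n_samples,
        )
        report = classify_eval.train_and_evaluate(
            train, test, classifier=config.classifier, seed=config.classifier_seed
        )
        payload = {
            "report": report.as_dict(),
            "config": {
                "classifier": config.classifier,
                "seeds": {
                    "ga": config.ga.seed,
                    "deep": config.deep_seed,
                    "rus": config.rus_seed,
                    "split": config.split_seed,
                    "pairing": config.pairing_seed,
                    "classifier": config.classifier_seed,
                },
                "split_fraction": config.split_fraction,
                "mi_k": config.mi_k,
                "mi_top_k": config.mi_top_k,
            },
            "n_train": train.n_samples,
            "n_test": test.n_samples,
        }
        with open(out / "evaluation.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        logger.info("accuracy %.4f iba %.4f", report.accuracy, report.iba)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
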