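"""Seeded synthetic lesion images and planted feature tables.

Breast-lesion CAD pipelines are normally developed against ultrasound (US) and
mammography (MG) patches. This module emulates the perceptual properties that
matter to the downstream stages without any dataset download:

* **Geometry.** A lesion is an ellipse whose boundary radius is optionally
  perturbed by a radial sinusoid ("spiculation"). Benign lesions are smooth
  (``spiculation_count = 0``) and therefore round; malignant lesions carry
  five or more spiculations, which lowers their circularity monotonically with
  spiculation depth -- the BI-RADS intuition that irregular margins indicate
  malignancy.
* **Modality corruption.** US patches receive multiplicative speckle,
  ``image * (1 + u)`` with ``u ~ U(-a, a)`` -- the simplest multiplicative
  model that exercises a median filter. MG patches receive a smooth additive
  low-frequency background gradient (amplitude scaled by ``noise_level``) plus
  1-3 bright axis-aligned rectangles away from the lesion, standing in for the
  film labels and markers that segmentation must ignore.

Everything is driven by a single integer seed: equal spec, equal bytes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import BENIGN, CLASSES, MALIGNANT, FeatureTable

US = "US"
MG = "MG"
MODALITIES = (US, MG)

_BACKGROUND = 60  # base background intensity shared by both modalities
_ARTIFACT_INTENSITY = 230
_BORDER_MARGIN = 26  # bounding box tolerance 25 + 1 px of slack


@dataclass(frozen=True)
class LesionSpec:
    """Full description of one synthetic lesion patch."""

    modality: str = MG
    class_label: str = BENIGN
    image_size: int = 128
    center: tuple[int, int] | None = None  # (row, col); None -> image centre
    base_radius: float = 30.0
    spiculation_count: int = 0
    spiculation_depth: float = 0.25
    contrast: float = 100.0
    noise_level: float = 0.0
    seed: int = 0
    aspect: float = 0.85  # minor/major axis ratio of the base ellipse

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}")
        if self.class_label == BENIGN and self.spiculation_count != 0:
            raise ValueError("benign lesions are smooth: spiculation_count must be 0")
        if self.class_label == MALIGNANT and self.spiculation_count < 5:
            raise ValueError("malignant lesions need spiculation_count >= 5")
        if not 0.0 <= self.spiculation_depth < 1.0:
            raise ValueError("spiculation_depth must lie in [0, 1)")
        if not 0.0 <= self.contrast <= 255.0:
            raise ValueError("contrast must lie in [0, 255]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")
        if self.base_radius >= self.image_size / 2 - _BORDER_MARGIN:
            raise ValueError(
                "base_radius must be < image_size/2 - 26 so the padded "
                "bounding box fits inside the image"
            )

    @property
    def centre(self) -> tuple[int, int]:
        if self.center is not None:
            return self.center
        return (self.image_size // 2, self.image_size // 2)


def _rasterize(spec: LesionSpec) -> np.ndarray:
    """Rasterize the lesion boundary model into a binary mask."""
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    r0, c0 = spec.centre
    dr, dc = rr - r0, cc - c0
    # ellipse scaling: minor axis along rows
    rho = np.hypot(dr / spec.aspect, dc)
    theta = np.arctan2(dr, dc)
    radius = spec.base_radius * (
        1.0 + spec.spiculation_depth * np.sin(spec.spiculation_count * theta)
    )
    return (rho <= radius).astype(np.uint8)


def make_lesion_image(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion patch and its exact ground-truth mask.

    Returns
    -------
    (image, mask)
        ``image`` is uint8 ``image_size x image_size``; ``mask`` the uint8
        binary rasterization of the lesion. Identical spec (including seed)
        yields bit-identical output.

    Raises
    ------
    ValueError
        If the rasterized lesion touches the image border.
    """
    mask = _rasterize(spec)
    if mask.sum() == 0:
        raise ValueError("degenerate spec: empty lesion mask")
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    if border.any():
        raise ValueError("lesion touches the image border; shrink base_radius")

    rng = np.random.default_rng(spec.seed)
    img = np.full(mask.shape, float(_BACKGROUND)) + spec.contrast * mask

    if spec.modality == US:
        u = rng.uniform(-spec.noise_level, spec.noise_level, size=img.shape)
        img = img * (1.0 + u)
    else:  # MG: additive low-frequency background + bright label artifacts
        n = spec.image_size
        gr = np.linspace(0.0, 1.0, n)
        direction = rng.uniform(0, 2 * np.pi)
        ramp = np.cos(direction) * gr[None, :] + np.sin(direction) * gr[:, None]
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12)
        img = img + spec.noise_level * ramp
        img = _add_artifacts(img, mask, rng)

    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def _add_artifacts(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Insert 1-3 small bright rectangles that avoid the lesion."""
    img = img.copy()
    n = img.shape[0]
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r_lo, r_hi = rows[0] - 4, rows[-1] + 4
    c_lo, c_hi = cols[0] - 4, cols[-1] + 4
    for _ in range(int(rng.integers(1, 4))):
        for _attempt in range(50):
            h = int(rng.integers(4, 9))
            w = int(rng.integers(6, 13))
            r = int(rng.integers(0, n - h))
            c = int(rng.integers(0, n - w))
            overlaps = not (r + h < r_lo or r > r_hi or c + w < c_lo or c > c_hi)
            if not overlaps:
                img[r : r + h, c : c + w] = _ARTIFACT_INTENSITY
                break
    return img


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Synthetic feature table with a known informative subset planted in it."""

    n_per_class: int = 200
    n_features: int = 10
    informative_indices: tuple[int, ...] = (0, 1)
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        idx = self.informative_indices
        if len(set(idx)) != len(idx):
            raise ValueError("informative_indices must be unique")
        if self.n_features < len(idx):
            raise ValueError("n_features < number of informative indices")
        if idx and (min(idx) < 0 or max(idx) >= self.n_features):
            raise ValueError("informative_indices out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def make_planted_feature_table(spec: PlantedDatasetSpec) -> FeatureTable:
    """Draw a balanced two-class table with planted informative columns.

    Informative columns are unit-variance Gaussians whose class means are
    separated by ``effect_size`` (in noise-SD units); every other column is
    N(0, 1) regardless of class, hence carries no label information.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    x = rng.standard_normal((n, spec.n_features))
    labels = np.array([BENIGN] * spec.n_per_class + [MALIGNANT] * spec.n_per_class)
    shift = spec.effect_size / 2.0
    for j in spec.informative_indices:
        x[labels == BENIGN, j] -= shift
        x[labels == MALIGNANT, j] += shift
    order = rng.permutation(n)
    cols = [f"f{j}" for j in range(spec.n_features)]
    return FeatureTable(pd.DataFrame(x[order], columns=cols), labels[order])


def write_image_dataset(
    out_dir: str | Path,
    n_per_class: int = 30,
    modality: str = MG,
    image_size: int = 128,
    noise_level: float | None = None,
    seed: int = 0,
) -> Path:
    """Write a PNG image/mask dataset plus a CSV manifest; return manifest path.

    The manifest has columns ``path, mask_path, modality, label``. Per-image
    geometry (radius, centre jitter, spiculation depth) is drawn from ``seed``
    so every dataset is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if noise_level is None:
        noise_level = 0.12 if modality == US else 30.0
    rng = np.random.default_rng(seed)
    rows = []
    for label in CLASSES:
        for i in range(n_per_class):
            spec = LesionSpec(
                modality=modality,
                class_label=label,
                image_size=image_size,
                center=(
                    image_size // 2 + int(rng.integers(-6, 7)),
                    image_size // 2 + int(rng.integers(-6, 7)),
                ),
                base_radius=float(rng.uniform(20, image_size / 2 - 30)),
                spiculation_count=0 if label == BENIGN else int(rng.integers(6, 11)),
                spiculation_depth=float(rng.uniform(0.2, 0.35)),
                contrast=100.0,
                noise_level=noise_level,
                seed=int(rng.integers(0, 2**31 - 1)),
                aspect=float(rng.uniform(0.75, 0.95)),
            )
            img, mask = make_lesion_image(spec)
            stem = f"{modality}_{label}_{i:03d}"
            img_path = out / f"{stem}.png"
            mask_path = out / f"{stem}_mask.png"
            Image.fromarray(img).save(img_path)
            Image.fromarray(mask * 255).save(mask_path)
            rows.append(
                {
                    "path": str(img_path),
                    "mask_path": str(mask_path),
                    "modality": modality,
                    "label": label,
                }
            )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "mask_path", "modality", "label"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
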