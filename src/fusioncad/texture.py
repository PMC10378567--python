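"""Texture descriptors (LBP, HOG) and their PCA reduction.

The texture stage turns a lesion ROI into a fixed-length vector:

* **LBP** codes each interior pixel by comparing its 8 ring neighbours
  (radius 1, ordered clockwise from the top-right) against the centre; bit
  ``i`` is set when neighbour ``i`` is >= the centre. The 256-bin code
  histogram, normalized to frequencies, is the texture signature.
* **HOG** computes central-difference gradients, folds orientation to the
  unsigned range [0, 180), accumulates magnitude-weighted votes into 9 bins
  per 8x8-pixel cell (each vote linearly split between the two bins whose
  centres straddle the orientation), and L2-normalizes overlapping 2x2-cell
  blocks (stride one cell) into 36-value segments.
* **PCA** reduces the concatenated HOG+LBP vector to 199 components
  (capped at min(n_samples - 1, n_features) with a warning on small runs).

ROIs are resized to 128 x 128 (bilinear) before description so the
descriptor length is fixed: 15*15 blocks * 36 + 256 = 8356 raw texture
features per ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.decomposition import PCA as _SkPCA

#: (dr, dc) offsets of the 8 ring neighbours, clockwise from top-right;
#: bit i of the LBP code corresponds to offset i.
LBP_OFFSETS = [(-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0)]

HOG_CELL = 8
HOG_BINS = 9
HOG_BLOCK = 2  # cells per block side
HOG_EPS = 1e-5
DESCRIPTOR_SIZE = 128  # ROI is resized to this square before HOG/LBP
N_PCA_COMPONENTS = 199


@dataclass(frozen=True)
class LBPImage:
    codes: np.ndarray  # interior codes, shape (H-2r, W-2r)
    p: int = 8
    r: int = 1


def lbp_code_image(img: np.ndarray, p: int = 8, r: int = 1, literal_sign: bool = False) -> LBPImage:
    """LBP codes for every interior pixel (p=8, r=1 supported).

    ``literal_sign=True`` uses the inverted comparison (bit set when
    neighbour < centre) instead of the standard neighbour >= centre.
    """
    if (p, r) != (8, 1):
        raise ValueError("only p=8, r=1 is supported")
    img = np.asarray(img, dtype=np.int32)
    if img.ndim != 2 or img.shape[0] < 2 * r + 1 or img.shape[1] < 2 * r + 1:
        raise ValueError("image smaller than the LBP window")
    centre = img[1:-1, 1:-1]
    codes = np.zeros_like(centre)
    h, w = img.shape
    for bit, (dr, dc) in enumerate(LBP_OFFSETS):
        neigh = img[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        if literal_sign:
            on = neigh < centre
        else:
            on = neigh >= centre
        codes |= on.astype(np.int32) << bit
    return LBPImage(codes=codes, p=p, r=r)


def lbp_histogram(codes: LBPImage) -> np.ndarray:
    """Counts of each code value; length 2**p (256 for p=8)."""
    return np.bincount(codes.codes.ravel(), minlength=2**codes.p).astype(np.int64)


@dataclass(frozen=True)
class GradientField:
    magnitude: np.ndarray  # >= 0
    orientation: np.ndarray  # degrees in [0, 180)


def hog_gradients(img: np.ndarray) -> GradientField:
    """Central-difference gradients with unsigned orientation.

    ``Gx(r, c) = I(r, c+1) - I(r, c-1)`` and ``Gy(r, c) = I(r+1, c) -
    I(r-1, c)`` with edge replication at the borders; magnitude is the
    Euclidean norm and orientation the quadrant-aware arctangent folded to
    [0, 180) degrees.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be at least 3x3")
    pad = np.pad(img, 1, mode="edge")
    gx = pad[1:-1, 2:] - pad[1:-1, :-2]
    gy = pad[2:, 1:-1] - pad[:-2, 1:-1]
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    return GradientField(magnitude=mag, orientation=ang)


def hog_cell_histograms(
    field: GradientField, cell: int = HOG_CELL, bins: int = HOG_BINS
) -> np.ndarray:
    """Per-cell orientation histograms with linear two-bin vote splitting.

    Each pixel's magnitude is split between the two bins whose centres
    straddle its orientation: with bin width ``w = 180/bins`` and centres
    ``c_j = w*(j + 1/2)``, ``j = floor(theta/w - 1/2)`` (circular), the lower
    bin receives ``mu*(c_{j+1} - theta)/w`` and the upper ``mu*(theta - c_j)/w``.
    Returns an array of shape (rows/cell, cols/cell, bins); total vote mass
    per cell equals the summed magnitudes in that cell.
    """
    mag, ang = field.magnitude, field.orientation
    h, w_px = mag.shape
    if h % cell or w_px % cell:
        raise ValueError("image dimensions must be multiples of the cell size")
    w = 180.0 / bins
    pos = ang / w - 0.5
    j = np.floor(pos).astype(int)
    frac = pos - j  # in [0,1): weight of the upper bin
    j_lo = j % bins
    j_hi = (j + 1) % bins
    v_hi = mag * frac
    v_lo = mag * (1.0 - frac)

    cr = np.arange(h) // cell
    cc = np.arange(w_px) // cell
    cell_r = np.broadcast_to(cr[:, None], mag.shape)
    cell_c = np.broadcast_to(cc[None, :], mag.shape)
    hist = np.zeros((h // cell, w_px // cell, bins))
    np.add.at(hist, (cell_r, cell_c, j_lo), v_lo)
    np.add.at(hist, (cell_r, cell_c, j_hi), v_hi)
    return hist


def hog_descriptor(
    cells: np.ndarray,
    block: int = HOG_BLOCK,
    epsilon: float = HOG_EPS,
) -> np.ndarray:
    """Flattened L2-normalized overlapping-block descriptor.

    Blocks are ``block x block`` cell windows stepped one cell at a time
    (8-pixel stride for 8-pixel cells); each window's ``block**2 * bins``
    values are normalized by ``v / sqrt(||v||^2 + epsilon)``.
    """
    nr, nc, bins = cells.shape
    if nr < block or nc < block:
        raise ValueError("no full block fits the cell grid")
    out = []
    for r in range(nr - block + 1):
        for c in range(nc - block + 1):
            v = cells[r : r + block, c : c + block].ravel()
            out.append(v / np.sqrt(np.sum(v * v) + epsilon))
    return np.concatenate(out)


def texture_vector(img: np.ndarray, size: int = DESCRIPTOR_SIZE) -> np.ndarray:
    """HOG descriptor concatenated with the frequency-normalized LBP histogram.

    The ROI is resized to ``size x size`` (bilinear) first so the output
    length is fixed: for the default 128 px / 8 px cells this is
    15*15*36 + 256 = 8356.
    """
    img = np.asarray(img, dtype=float)
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    hog = hog_descriptor(hog_cell_histograms(hog_gradients(img)))
    codes = lbp_code_image(np.clip(np.round(img), 0, 255).astype(np.uint8))
    hist = lbp_histogram(codes).astype(float)
    hist /= max(hist.sum(), 1.0)
    return np.concatenate([hog, hist])


def texture_feature_names(size: int = DESCRIPTOR_SIZE) -> list[str]:
    n_cells = size // HOG_CELL
    n_blocks = (n_cells - HOG_BLOCK + 1) ** 2
    hog_len = n_blocks * HOG_BLOCK**2 * HOG_BINS
    return [f"hog_{i}" for i in range(hog_len)] + [f"lbp_{i}" for i in range(256)]


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA basis: per-feature mean, orthonormal components (rows),
    eigenvalues in non-increasing order."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance: np.ndarray
    n_components: int


def pca_fit(x: np.ndarray, n_components: int = N_PCA_COMPONENTS) -> PCAModel:
    """Fit PCA with a deterministic sign convention.

    ``n_components`` is capped at ``min(n_samples - 1, n_features)`` with a
    warning when the cap binds (small synthetic runs must not crash). Each
    component's sign is fixed so that its largest-magnitude loading is
    positive.
    """
    x = np.asarray(x, dtype=float)
    n_samples, n_features = x.shape
    cap = min(n_samples - 1, n_features)
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} capped at {cap} "
            f"(n_samples={n_samples}, n_features={n_features})",
            stacklevel=2,
        )
        n_components = cap
    if n_components < 1:
        raise ValueError("need at least 2 samples and 1 feature")
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(x)
    comp = sk.components_.copy()
    for row in comp:  # deterministic sign: largest-|loading| positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return PCAModel(
        mean=sk.mean_.copy(),
        components=comp,
        explained_variance=sk.explained_variance_.copy(),
        n_components=n_components,
    )


def pca_transform(model: PCAModel, x: np.ndarray) -> np.ndarray:
    """Project centred data onto the retained components."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature count {x.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    return (x - model.mean) @ model.components.T


def pca_inverse_transform(model: PCAModel, z: np.ndarray) -> np.ndarray:
    """Map reduced coordinates back to the original feature space."""
    return np.asarray(z, dtype=float) @ model.components + model.mean
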