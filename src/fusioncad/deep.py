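"""Pluggable deep-feature extractor contract.

The pipeline consumes deep features through a minimal contract: a named
extractor mapping an ROI image to a fixed-length real vector,
deterministically. The default implementation is :class:`StubExtractor`, a
seeded random linear projection of the resized ROI followed by a tanh squash
-- it has the contract's shape and determinism and preserves enough image
geometry for end-to-end testing, with no model download. An adapter to a
pretrained DenseNet-201 (global-average-pool features, width 1920) can be
plugged in where a deep-learning runtime is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.transform import resize

#: global-average-pool width of DenseNet-201, hence the default stub width;
#: together with 199 PCA texture components and 4 shape features this gives
#: the 2123-wide hybrid vector.
DEFAULT_DEEP_DIM = 1920
_STUB_GRID = 32  # ROI is resized to this square before projection


@runtime_checkable
class DeepExtractor(Protocol):
    name: str
    output_dim: int

    def extract(self, img: np.ndarray) -> np.ndarray: ...


@dataclass
class StubExtractor:
    """Deterministic stand-in extractor: seeded fixed random projection.

    The ROI is resized to a 32x32 grid, flattened and scaled to [0, 1],
    projected through a fixed N(0, 1/1024) linear map drawn once from
    ``seed``, and squashed with tanh. Same seed => same map across calls and
    processes.
    """

    output_dim: int = DEFAULT_DEEP_DIM
    seed: int = 0
    name: str = "stub"
    _weights: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        rng = np.random.default_rng(self.seed)
        n_in = _STUB_GRID * _STUB_GRID
        self._weights = rng.standard_normal((n_in, self.output_dim)) / np.sqrt(n_in)

    def extract(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise ValueError("expected a 2-D grayscale ROI")
        grid = resize(
            img, (_STUB_GRID, _STUB_GRID), order=1, anti_aliasing=False, preserve_range=True
        )
        return np.tanh((grid.ravel() / 255.0) @ self._weights)


def stub_extract(img: np.ndarray, dim: int = DEFAULT_DEEP_DIM, seed: int = 0) -> np.ndarray:
    """Functional form of :class:`StubExtractor` (one-off use)."""
    return StubExtractor(output_dim=dim, seed=seed).extract(img)


class PretrainedAdapter:
    """Adapter to a pretrained DenseNet-201 feature extractor.

    Requires a deep-learning runtime (torch + torchvision) and downloadable
    weights; grayscale input is replicated to 3 channels, resized to the
    network's input size, and the global-average-pool activations (width
    1920) are returned. Raises a clear error when the runtime is missing.
    """

    name = "densenet201"
    output_dim = DEFAULT_DEEP_DIM

    def __init__(self) -> None:
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "PretrainedAdapter needs torch + torchvision with DenseNet-201 "
                "weights; use the default StubExtractor "
                "(fusioncad.deep.StubExtractor) for a dependency-free, "
                "deterministic extractor with the same contract"
            ) from exc
        import torch
        import torchvision

        weights = torchvision.models.DenseNet201_Weights.IMAGENET1K_V1
        model = torchvision.models.densenet201(weights=weights)
        model.eval()
        self._model = model
        self._torch = torch
        self._preprocess = weights.transforms()

    def extract(self, img: np.ndarray) -> np.ndarray:
        torch = self._torch
        img = np.asarray(img, dtype=np.float32)
        rgb = np.repeat(img[None, :, :], 3, axis=0) / 255.0
        with torch.no_grad():
            t = self._preprocess(torch.from_numpy(rgb))
            feats = self._model.features(t[None])
            pooled = torch.nn.functional.adaptive_avg_pool2d(
                torch.nn.functional.relu(feats), 1
            )
        return pooled.squeeze().numpy()


def get_extractor(name: str = "stub", dim: int = DEFAULT_DEEP_DIM, seed: int = 0) -> DeepExtractor:
    """Factory for the configured extractor (``stub`` or ``densenet201``)."""
    if name == "stub":
        return StubExtractor(output_dim=dim, seed=seed)
    if name == "densenet201":
        return PretrainedAdapter()
    raise ValueError(f"unknown extractor {name!r}; valid: 'stub', 'densenet201'")
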