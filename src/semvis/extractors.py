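"""Differentiable image-feature extractor protocol.

An extractor maps an H x W x 3 pixel image (floats in [0, 1]) to a vector of
channel-mean activations ("feature values"), one scalar per channel of each
declared layer.  Synthesis needs gradients of scalar functions of those
features with respect to pixels, so every extractor also exposes a
vector-Jacobian product: ``vjp(image, upstream)`` returns
``upstream @ d(features)/d(image)`` reshaped to the image shape.

Extractors must be deterministic: the same image always yields the same
features.
"""

from __future__ import annotations

import abc

import numpy as np

__all__ = ["FeatureExtractor", "LinearExtractor", "extract_channel_features"]


class FeatureExtractor(abc.ABC):
    """Abstract deterministic, differentiable image -> feature-vector map."""

    #: ordered mapping layer id -> channel count
    layer_channels: dict[str, int]
    #: layer used for stimulus synthesis targets
    sampled_layer: str

    @abc.abstractmethod
    def layer_features(self, image: np.ndarray, layer: str) -> np.ndarray:
        """Channel-mean activations of one layer for one image."""

    @abc.abstractmethod
    def layer_vjp(self, image: np.ndarray, layer: str, upstream: np.ndarray) -> np.ndarray:
        """Pixel-space gradient of ``upstream @ layer_features``."""

    def features(self, image: np.ndarray, layers: list[str] | None = None) -> np.ndarray:
        layers = [self.sampled_layer] if layers is None else layers
        return np.concatenate([self.layer_features(image, lay) for lay in layers])

    def vjp(
        self, image: np.ndarray, upstream: np.ndarray, layers: list[str] | None = None
    ) -> np.ndarray:
        layers = [self.sampled_layer] if layers is None else layers
        grad = np.zeros_like(image, dtype=float)
        start = 0
        for lay in layers:
            k = self.layer_channels[lay]
            grad += self.layer_vjp(image, lay, upstream[start : start + k])
            start += k
        if start != upstream.shape[0]:
            raise ValueError(
                f"upstream length {upstream.shape[0]} does not match "
                f"{start} channels across layers {layers}"
            )
        return grad

    @property
    def n_features(self) -> int:
        return self.layer_channels[self.sampled_layer]


class LinearExtractor(FeatureExtractor):
    """Toy extractor: features are fixed linear functionals of the pixels.

    Each channel c has a weight map ``weights[c]`` (same shape as the image);
    its feature value is ``mean(weights[c] * image)``.  Useful for exact
    oracle tests (linearity, zero image -> zero features).
    """

    def __init__(self, weights: np.ndarray, layer: str = "linear"):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 4:  # (channels, H, W, 3)
            raise ValueError("weights must have shape (channels, H, W, 3)")
        self.weights = weights
        self.sampled_layer = layer
        self.layer_channels = {layer: weights.shape[0]}

    def layer_features(self, image: np.ndarray, layer: str) -> np.ndarray:
        self._check(image, layer)
        return np.tensordot(self.weights, image, axes=3) / self.weights[0].size

    def layer_vjp(self, image: np.ndarray, layer: str, upstream: np.ndarray) -> np.ndarray:
        self._check(image, layer)
        return np.tensordot(upstream, self.weights, axes=1) / self.weights[0].size

    def _check(self, image: np.ndarray, layer: str) -> None:
        if layer not in self.layer_channels:
            raise KeyError(f"unknown layer {layer!r}")
        if image.shape != self.weights.shape[1:]:
            raise ValueError(f"image shape {image.shape} != {self.weights.shape[1:]}")


def extract_channel_features(
    image: np.ndarray, extractor: FeatureExtractor, layers: list[str] | None = None
) -> np.ndarray:
    """Channel-mean feature vector of ``image``, layers concatenated in order.

    Raises on unknown layer ids and on non-finite activations.
    """
    layers = [extractor.sampled_layer] if layers is None else layers
    for lay in layers:
        if lay not in extractor.layer_channels:
            raise KeyError(f"unknown layer {lay!r}")
    feats = extractor.features(np.asarray(image, dtype=float), layers)
    if not np.all(np.isfinite(feats)):
        raise ValueError("extractor produced non-finite activations")
    return feats
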