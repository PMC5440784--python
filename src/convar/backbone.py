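"""Convolutional filter bank ("backbone") and response extraction.

The analysis only needs the convolutional stages of an AlexNet-style network:
the fully-connected layers are dropped and the input is rescaled to 512 x 512
pixels while the filter sizes, strides and paddings keep their original
values.  Three weight sources are supported:

``pretrained``
    First-layer (and optionally deeper) filters loaded from an ``.npz`` file
    with arrays ``conv1_weight`` (k x kh x kw x 3), ``conv2_weight``, ... and
    an optional per-channel ``mean``.
``builtin_random``
    Seeded zero-mean random filters; useful for structural tests.
``builtin_gabor``
    An analytic bank of 96 filters — oriented Gabor patches for luminance
    edges plus opponent-color blob/edge/surround profiles — qualitatively
    mimicking the learned first-layer filters of object-recognition networks.

Everything is plain numpy: patches are gathered with stride tricks and the
convolution is a single matrix product, which is fast enough for 512 x 512
inputs on one CPU.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import GeometryError, ParameterError
from .images import ImageRGB

WeightSource = Literal["pretrained", "builtin_random", "builtin_gabor"]

#: AlexNet convolutional geometry: (kernel, stride, padding, filter count).
ALEXNET_CONV_LAYERS: tuple[tuple[int, int, int, int], ...] = (
    (11, 4, 0, 96),
    (5, 1, 2, 256),
    (3, 1, 1, 384),
    (3, 1, 1, 384),
    (3, 1, 1, 256),
)


def conv_output_size(in_size: int, kernel: int, stride: int, padding: int = 0) -> int:
    """Spatial output size of a valid convolution.

    ``floor((in_size + 2*padding - kernel) / stride) + 1``; e.g. a 227-pixel
    input with an 11-pixel kernel at stride 4 yields 55.
    """
    if stride < 1:
        raise ParameterError(f"stride must be >= 1, got {stride}")
    if in_size + 2 * padding < kernel:
        raise GeometryError(
            f"kernel {kernel} larger than padded input {in_size + 2 * padding}"
        )
    return (in_size + 2 * padding - kernel) // stride + 1


@dataclass(frozen=True)
class ConvLayerSpec:
    kernel: int
    stride: int
    padding: int
    filters: int


@dataclass(frozen=True)
class BackboneConfig:
    """Configuration of the conv-only backbone.

    ``apply_pool_between_layers`` interposes AlexNet-style 3x3/stride-2 max
    pooling between conv layers; it only matters when analysing layers >= 2.
    Preprocessing: per-channel mean subtraction — the image's own mean for the
    builtin banks, the stored training mean (if present) for pretrained
    weights.
    """

    input_size: int = 512
    layers: tuple[ConvLayerSpec, ...] = tuple(
        ConvLayerSpec(*spec) for spec in ALEXNET_CONV_LAYERS[:1]
    )
    weight_source: WeightSource = "builtin_gabor"
    apply_relu: bool = True
    apply_pool_between_layers: bool = False
    seed: int = 0
    weights_path: str | None = None
    pool_kernel: int = 3
    pool_stride: int = 2

    def __post_init__(self) -> None:
        if not self.layers:
            raise ParameterError("backbone needs at least one conv layer")
        if self.input_size < max(l.kernel for l in self.layers):
            raise GeometryError("input_size smaller than the largest kernel")

    @property
    def config_hash(self) -> str:
        digest = hashlib.sha1(repr(self).encode()).hexdigest()
        return digest[:10]


def alexnet_backbone(
    weight_source: WeightSource = "builtin_gabor",
    n_layers: int = 1,
    input_size: int = 512,
    seed: int = 0,
    weights_path: str | None = None,
    **kwargs,
) -> BackboneConfig:
    """AlexNet conv geometry truncated to the first ``n_layers`` conv layers."""
    layers = tuple(ConvLayerSpec(*spec) for spec in ALEXNET_CONV_LAYERS[:n_layers])
    return BackboneConfig(
        input_size=input_size,
        layers=layers,
        weight_source=weight_source,
        seed=seed,
        weights_path=weights_path,
        apply_pool_between_layers=n_layers > 1,
        **kwargs,
    )


@dataclass
class ResponseStack:
    """Per-layer filter responses for one image: ``k x H_l x W_l``."""

    layer_id: int
    responses: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.responses)
        if r.ndim != 3:
            raise ParameterError("responses must be k x H x W")
        if not np.isfinite(r).all():
            raise ParameterError("responses contain non-finite values")
        self.responses = r

    @property
    def n_filters(self) -> int:
        return self.responses.shape[0]

    @property
    def geometry(self) -> tuple[int, int]:
        return self.responses.shape[1], self.responses.shape[2]


# ---------------------------------------------------------------- filter banks

def builtin_random_bank(
    layer: ConvLayerSpec, in_channels: int, seed: int, layer_index: int = 1
) -> np.ndarray:
    """Seeded random filters, zero-mean and unit-norm per filter."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, layer_index]))
    w = rng.standard_normal((layer.filters, layer.kernel, layer.kernel, in_channels))
    w -= w.mean(axis=(1, 2, 3), keepdims=True)
    w /= np.linalg.norm(w.reshape(layer.filters, -1), axis=1)[:, None, None, None]
    return w


def _gabor(kernel: int, theta: float, wavelength: float, phase: float) -> np.ndarray:
    half = (kernel - 1) / 2.0
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    sigma = 0.5 * wavelength
    env = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
    g = env * np.cos(2.0 * np.pi * xr / wavelength + phase)
    g -= g.mean()  # zero DC: silent on uniform luminance
    return g


def builtin_gabor_bank(kernel: int = 11, in_channels: int = 3) -> np.ndarray:
    """Analytic 96-filter bank: 64 luminance Gabors + 32 opponent-color filters.

    The luminance filters are zero-mean Gabor patches (8 orientations x 4
    wavelengths x 2 phases) applied identically to R, G and B.  The color
    filters combine spatial profiles (Gaussian blobs, odd-symmetric edges, a
    center-surround difference and a uniform patch) with the two classical
    opponent axes R-G and B-Y at both polarities; their per-pixel channel sum
    is zero, so they ignore luminance but respond to color structure — the
    blob/uniform profiles also to uniformly colored areas, as the learned
    filters of Figure-1-style banks do.
    """
    if in_channels != 3:
        raise ParameterError("the Gabor bank is defined for 3-channel input")
    filters: list[np.ndarray] = []
    thetas = np.arange(8) * np.pi / 8.0
    wavelengths = (3.0, 5.0, 7.5, 11.0)
    for theta, wl, phase in product(thetas, wavelengths, (0.0, np.pi / 2.0)):
        g = _gabor(kernel, theta, wl, phase)
        filters.append(np.repeat(g[:, :, None], 3, axis=2) / 3.0)

    half = (kernel - 1) / 2.0
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    rr2 = xx**2 + yy**2
    profiles = [
        np.exp(-rr2 / (2.0 * 2.0**2)),                       # small blob
        np.exp(-rr2 / (2.0 * 4.5**2)),                       # large blob
        np.tanh(xx / 2.0) * np.exp(-rr2 / (2.0 * 3.5**2)),   # vertical edge
        np.tanh(yy / 2.0) * np.exp(-rr2 / (2.0 * 3.5**2)),   # horizontal edge
        np.tanh((xx + yy) / 2.8) * np.exp(-rr2 / (2.0 * 3.5**2)),
        np.tanh((xx - yy) / 2.8) * np.exp(-rr2 / (2.0 * 3.5**2)),
        np.exp(-rr2 / (2.0 * 1.5**2)) - 0.25 * np.exp(-rr2 / (2.0 * 3.0**2)),
        np.ones_like(xx),                                     # uniform patch
    ]
    rg = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    by = np.array([-0.5, -0.5, 1.0]) / np.linalg.norm([-0.5, -0.5, 1.0])
    for axis, prof, sign in product((rg, by), profiles, (1.0, -1.0)):
        filters.append(sign * prof[:, :, None] * axis[None, None, :])

    w = np.stack(filters, axis=0)
    w /= np.linalg.norm(w.reshape(w.shape[0], -1), axis=1)[:, None, None, None]
    return w


def _load_pretrained(cfg: BackboneConfig, layer_index: int, in_channels: int) -> np.ndarray:
    if cfg.weights_path is None:
        raise ParameterError(
            "weight_source='pretrained' requires weights_path pointing to an "
            ".npz file with conv<N>_weight arrays; for an offline run use "
            "weight_source='builtin_random' or 'builtin_gabor' instead"
        )
    try:
        archive = np.load(cfg.weights_path)
    except Exception as exc:
        raise ParameterError(
            f"cannot read pretrained weights from {cfg.weights_path!r}: {exc}; "
            "use weight_source='builtin_random' or 'builtin_gabor' instead"
        ) from exc
    key = f"conv{layer_index}_weight"
    if key not in archive:
        raise ParameterError(
            f"{cfg.weights_path!r} has no array {key!r}; available: "
            f"{sorted(archive.files)}"
        )
    w = np.asarray(archive[key], dtype=np.float64)
    spec = cfg.layers[layer_index - 1]
    expected = (spec.filters, spec.kernel, spec.kernel, in_channels)
    if w.shape != expected:
        raise ParameterError(f"{key} has shape {w.shape}, expected {expected}")
    if layer_index == 1 and spec.filters != 96:
        raise ParameterError("pretrained conv1 must declare 96 filters")
    return w


def bank_for_layer(cfg: BackboneConfig, layer_index: int, in_channels: int) -> np.ndarray:
    spec = cfg.layers[layer_index - 1]
    if cfg.weight_source == "pretrained":
        return _load_pretrained(cfg, layer_index, in_channels)
    if cfg.weight_source == "builtin_gabor" and layer_index == 1:
        if spec.filters != 96:
            raise ParameterError("the builtin Gabor bank has exactly 96 filters")
        return builtin_gabor_bank(spec.kernel, in_channels)
    # deeper layers of the gabor configuration fall back to seeded random
    return builtin_random_bank(spec, in_channels, cfg.seed, layer_index)


# ----------------------------------------------------------------- convolution

def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    """Valid convolution of ``H x W x C`` input with ``k x kh x kw x C`` bank."""
    k, kh, kw, c = w.shape
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    if x.shape[0] < kh or x.shape[1] < kw:
        raise GeometryError("input smaller than kernel after padding")
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    out_h, out_w = win.shape[:2]
    patches = np.moveaxis(win, 2, 4).reshape(out_h * out_w, kh * kw * c)
    out = patches.astype(np.float32) @ w.reshape(k, -1).T.astype(np.float32)
    return out.reshape(out_h, out_w, k)


def _max_pool2d(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (kernel, kernel), axis=(0, 1))[::stride, ::stride]
    return win.max(axis=(-2, -1))


def extract_responses(img: ImageRGB, cfg: BackboneConfig, layer: int = 1) -> ResponseStack:
    """Run ``img`` through the backbone and return layer ``layer`` responses.

    Deterministic given (image, config): the builtin banks are seeded and the
    convolution is a fixed-order float32 matrix product.
    """
    if not 1 <= layer <= len(cfg.layers):
        raise ParameterError(
            f"layer {layer} out of range 1..{len(cfg.layers)}"
        )
    x = img.pixels
    if x.shape[0] != cfg.input_size or x.shape[1] != cfg.input_size:
        from .images import resize_bilinear

        x = np.clip(resize_bilinear(x, cfg.input_size, cfg.input_size), 0.0, 1.0)
    x = x - x.mean(axis=(0, 1), keepdims=True)
    if cfg.weight_source == "pretrained" and cfg.weights_path is not None:
        try:
            archive = np.load(cfg.weights_path)
            if "mean" in archive:
                x = img.pixels - np.asarray(archive["mean"], dtype=np.float64)
        except OSError:
            pass  # _load_pretrained will raise with a clear message
    x = x.astype(np.float32)
    for idx in range(1, layer + 1):
        spec = cfg.layers[idx - 1]
        w = bank_for_layer(cfg, idx, x.shape[2])
        x = _conv2d(x, w, spec.stride, spec.padding)
        if cfg.apply_relu:
            np.maximum(x, 0.0, out=x)
        if cfg.apply_pool_between_layers and idx < layer:
            x = _max_pool2d(x, cfg.pool_kernel, cfg.pool_stride)
    return ResponseStack(layer_id=layer, responses=np.moveaxis(x, 2, 0).astype(np.float64))
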