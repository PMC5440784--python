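"""Image loading and preprocessing.

Images are represented as ``H x W x 3`` float arrays with values in ``[0, 1]``.
Inputs of any bit depth are rescaled by the maximum value of their storage
type; grayscale images are replicated across the three channels; alpha
channels are dropped with a logged warning.  For analysis the image is
anisotropically resized (bilinear, no cropping) to a square of the backbone's
input size, so the full picture surface enters the filter bank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .errors import ImageDecodeError, ParameterError

log = logging.getLogger(__name__)

MIN_SIDE = 32


@dataclass
class ImageRGB:
    """An RGB raster image in ``[0, 1]``.

    Attributes
    ----------
    pixels:
        ``H x W x 3`` float array, every value finite and inside ``[0, 1]``.
    source_path:
        Where the image came from ("<synthetic>" for generated fixtures).
    """

    pixels: np.ndarray
    source_path: str = field(default="<array>")

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ParameterError(
                f"ImageRGB requires an H x W x 3 array, got shape {p.shape}"
            )
        if p.shape[0] < MIN_SIDE or p.shape[1] < MIN_SIDE:
            raise ParameterError(
                f"image must be at least {MIN_SIDE} x {MIN_SIDE}, got "
                f"{p.shape[0]} x {p.shape[1]}"
            )
        if not np.isfinite(p).all():
            raise ParameterError("image contains non-finite values")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ParameterError("image values must lie in [0, 1]")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _decode(path: str) -> np.ndarray:
    """Decode ``path`` to an ``H x W x C`` float array in [0, 1] (C in 1,3,4)."""
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("I;16", "I;16L", "I;16B", "I"):
                arr = np.asarray(im, dtype=np.float64)
                scale = 65535.0 if mode.startswith("I;16") else float(max(arr.max(), 1))
                arr = arr / scale
            elif mode == "F":
                arr = np.asarray(im, dtype=np.float64)
                arr = np.clip(arr, 0.0, 1.0)
            else:
                if mode not in ("RGB", "RGBA", "L", "LA"):
                    im = im.convert("RGBA" if "A" in mode or "P" in mode else "RGB")
                arr = np.asarray(im, dtype=np.float64) / 255.0
    except ImageDecodeError:
        raise
    except Exception as exc:  # decode errors come in many flavours
        raise ImageDecodeError(f"cannot decode image file {path!r}: {exc}") from exc
    return arr


def load_and_preprocess(path: str, input_size: int = 512) -> ImageRGB:
    """Load an image file and resize it to ``input_size`` square RGB.

    Non-square images are resized anisotropically (no crop); grayscale inputs
    are replicated across channels; an alpha channel is dropped with a warning.
    """
    arr = _decode(path)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[2] in (2, 4):  # LA / RGBA
        log.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, :-1]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] != 3:
        raise ImageDecodeError(
            f"{path!r}: unsupported channel count {arr.shape[2]}"
        )
    arr = resize_bilinear(arr, input_size, input_size)
    return ImageRGB(np.clip(arr, 0.0, 1.0), source_path=str(path))


def resize_bilinear(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear per-channel resize of a float ``H x W x C`` array."""
    if arr.shape[0] == out_h and arr.shape[1] == out_w:
        return arr
    channels = [
        np.asarray(
            Image.fromarray(arr[:, :, c].astype(np.float32), mode="F").resize(
                (out_w, out_h), Image.BILINEAR
            ),
            dtype=np.float64,
        )
        for c in range(arr.shape[2])
    ]
    return np.stack(channels, axis=2)
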