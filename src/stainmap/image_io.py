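"""Reading and writing micrographs and label maps.

Micrographs are 8-bit RGB PNG or TIFF. Label maps are written as indexed
(palette) PNG whose pixel values are the class codes themselves, so the
file doubles as a human-viewable overlay and a lossless code image.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .classes import CLASS_CODES, DEFAULT_PALETTE, StainClass
from .errors import InputError

logger = logging.getLogger(__name__)

_RGB_MODES = {"RGB"}
_FLATTENABLE = {"RGBA", "RGB;16", "I;16"}


def load_rgb_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image as an (H, W, 3) uint8 array.

    RGBA images are flattened onto white and 16-bit images rescaled to
    8 bits, each with a logged warning; other modes (grayscale, palette)
    raise :class:`InputError` naming the file.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "RGB":
                arr = np.asarray(im)
            elif mode == "RGBA":
                logger.warning("%s: RGBA input flattened onto white background", path)
                bg = Image.new("RGB", im.size, (255, 255, 255))
                bg.paste(im, mask=im.getchannel("A"))
                arr = np.asarray(bg)
            elif mode in ("I;16", "I"):
                logger.warning("%s: 16-bit input rescaled to 8-bit and replicated to RGB", path)
                raw = np.asarray(im, dtype=np.float64)
                scaled = np.clip(raw / 257.0, 0, 255).astype(np.uint8)
                arr = np.stack([scaled] * 3, axis=-1)
            else:
                raise InputError(f"{path}: unsupported image mode {mode!r}; 8-bit RGB required")
    except FileNotFoundError:
        raise InputError(f"{path}: file not found") from None
    except InputError:
        raise
    except Exception as exc:  # decoding failure
        raise InputError(f"{path}: cannot decode image ({exc})") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path}: expected 3 channels, got shape {arr.shape}")
    return np.ascontiguousarray(arr, dtype=np.uint8)


def save_rgb_image(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 array as PNG/TIFF (format from suffix)."""
    image = np.asarray(image, dtype=np.uint8)
    Image.fromarray(image, mode="RGB").save(Path(path))


def save_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as an indexed PNG with the default palette.

    Pixel values in the file equal the class codes (1..3).
    """
    labels = np.asarray(labels)
    invalid = ~np.isin(labels, CLASS_CODES)
    if invalid.any():
        raise InputError(f"label map contains codes outside {CLASS_CODES}")
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for cls, rgb in DEFAULT_PALETTE.items():
        palette[3 * int(cls) : 3 * int(cls) + 3] = list(rgb)
    im.putpalette(palette)
    im.save(Path(path))


def load_label_map(path: str | Path) -> np.ndarray:
    """Load a label map saved by :func:`save_label_map` (or any single-
    channel image whose values are the class codes)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("P", "L", "I"):
                raise InputError(f"{path}: expected an indexed or grayscale label image, got {im.mode!r}")
            arr = np.asarray(im).astype(np.int64)
    except FileNotFoundError:
        raise InputError(f"{path}: file not found") from None
    if not np.isin(arr, CLASS_CODES).all():
        raise InputError(f"{path}: pixel values are not valid class codes {CLASS_CODES}")
    return arr


def validate_rgb_image(image: np.ndarray) -> np.ndarray:
    """Check an in-memory array is a valid (H, W, 3) image in [0, 255]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] < 1 or image.shape[1] < 1:
        raise InputError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    if image.min() < 0 or image.max() > 255:
        raise InputError("channel values must lie in [0, 255]")
    return image


__all__ = [
    "load_rgb_image",
    "save_rgb_image",
    "save_label_map",
    "load_label_map",
    "validate_rgb_image",
]
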