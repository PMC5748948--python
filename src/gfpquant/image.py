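"""Image loading and the common intensity scale.

All downstream thresholds are defined on a fixed 0-255 intensity scale, so the
loader's only jobs are to pull the GFP (green) channel out of whatever the
microscope exported and to map 16-bit data linearly onto that scale.  No
contrast stretching is ever applied: a percentile stretch would silently move
the absolute thresholds the analysis depends on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError

__all__ = [
    "IntensityImage",
    "EmbryoImageRecord",
    "load_gfp_image",
    "crop_roi",
    "TIMEPOINTS",
]

TIMEPOINTS = ("0hpi", "72hpi")


@dataclass(frozen=True)
class IntensityImage:
    """A 2-D non-negative pixel grid on the 0-255 scale.

    Parameters
    ----------
    pixels : ndarray of float64, shape (height, width)
        Intensities in [0, 255].
    source_depth : {8, 16}
        Bit depth of the file the pixels came from (8 for synthetic images).
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.source_depth not in (8, 16):
            raise ValueError(f"source_depth must be 8 or 16, got {self.source_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


@dataclass(frozen=True)
class EmbryoImageRecord:
    """One micrograph of one embryo at one timepoint."""

    embryo_id: str
    timepoint: Literal["0hpi", "72hpi"]
    image: IntensityImage
    group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )


def load_gfp_image(path: str | os.PathLike) -> IntensityImage:
    """Load a TIFF/PNG micrograph and return its GFP signal on the 0-255 scale.

    RGB(A) inputs yield the green channel only; grayscale inputs pass through.
    16-bit data are rescaled linearly by 255/65535.

    Raises
    ------
    IOError
        If the file is missing or unreadable.
    ImageFormatError
        For channel layouts other than grayscale, RGB or RGBA.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    if raw.ndim == 3:
        if raw.shape[2] in (3, 4):
            raw = raw[:, :, 1]  # green channel; alpha ignored
        else:
            raise ImageFormatError(
                f"{path}: unsupported channel layout with {raw.shape[2]} channels"
            )
    elif raw.ndim != 2:
        raise ImageFormatError(f"{path}: expected a 2-D image, got ndim={raw.ndim}")

    if raw.dtype == np.uint8:
        depth = 8
        pixels = raw.astype(np.float64)
    elif raw.dtype == np.uint16:
        depth = 16
        pixels = raw.astype(np.float64) * (255.0 / 65535.0)
    else:
        raise ImageFormatError(f"{path}: unsupported pixel dtype {raw.dtype}")

    return IntensityImage(pixels=pixels, source_depth=depth)


def crop_roi(image: IntensityImage, rect: tuple[int, int, int, int]) -> IntensityImage:
    """Crop ``rect = (row0, col0, height, width)`` out of the image.

    Coordinates are 0-based and half-open; the rect must lie fully inside the
    image.  Returns a copy.
    """
    row0, col0, height, width = (int(v) for v in rect)
    if height < 1 or width < 1:
        raise ValueError(f"crop extent must be positive, got {height}x{width}")
    if row0 < 0 or col0 < 0 or row0 + height > image.height or col0 + width > image.width:
        raise ValueError(
            f"rect {rect} extends outside the {image.height}x{image.width} image"
        )
    return IntensityImage(
        pixels=image.pixels[row0 : row0 + height, col0 : col0 + width].copy(),
        source_depth=image.source_depth,
    )
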