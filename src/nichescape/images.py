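"""Calibrated multichannel images.

The common currency of all imaging operations is :class:`ImageStack`: a
``channel x row x col`` array of non-negative intensities together with
channel names and a physical pixel size in micrometres.  All downstream
measurements (distances, areas) are reported in physical units, so an image
without a resolvable pixel size cannot enter the pipeline.

Conventions: 0-based indices, origin at the top-left image corner, x runs
along columns and y along rows; pixel (r, c) has its centre at
``((c + 0.5) * s, (r + 0.5) * s)`` in µm, where ``s`` is the pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_image", "write_image"]


@dataclass
class ImageStack:
    """A calibrated multichannel 2D fluorescence image.

    Parameters
    ----------
    pixels:
        ``(n_channels, n_rows, n_cols)`` array of non-negative intensities.
    channel_names:
        One name per channel (e.g. ``["CD31", "Hoechst"]``).
    pixel_size_um:
        Physical edge length of one pixel, in µm; must be positive.
    """

    pixels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, :, :]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (channel, row, col) array")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[0])]
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape as (rows, cols), channels excluded."""
        return self.pixels.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical extent (width_x, height_y) in µm."""
        nr, nc = self.shape
        return nc * self.pixel_size_um, nr * self.pixel_size_um

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 2D array; raises KeyError if absent."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[idx]

    def um_to_pixel(self, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
        """Map physical coordinates to (row, col) indices, clipped to bounds."""
        s = self.pixel_size_um
        col = np.clip(np.floor(np.asarray(x_um) / s).astype(int), 0, self.shape[1] - 1)
        row = np.clip(np.floor(np.asarray(y_um) / s).astype(int), 0, self.shape[0] - 1)
        return row, col


def write_image(path, img: ImageStack) -> None:
    """Write an ImageStack as a multi-page TIFF with calibration metadata.

    Channel names and pixel size are stored in the ImageJ-style metadata
    block plus the TIFF resolution tags, so the file round-trips through
    :func:`read_image` and remains readable by Fiji/ImageJ.
    """
    px = img.pixels
    meta = {
        "axes": "CYX",
        "channel_names": json.dumps(img.channel_names),
        "pixel_size_um": img.pixel_size_um,
    }
    tifffile.imwrite(
        str(path),
        px,
        photometric="minisblack",
        resolution=(1.0 / img.pixel_size_um, 1.0 / img.pixel_size_um),
        metadata=meta,
    )


def read_image(path, pixel_size_um: float | None = None,
               channel_names: list[str] | None = None) -> ImageStack:
    """Read a (multi-page or OME) TIFF as an ImageStack.

    Pixel size is taken from the embedded metadata; ``pixel_size_um``
    overrides it.  Because every downstream quantity is physical, a file
    with no resolvable pixel size and no override is a hard error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if arr.ndim == 2:
            arr = arr[None]
        size = pixel_size_um
        if size is None and "pixel_size_um" in meta:
            size = float(meta["pixel_size_um"])
        if size is None:
            # fall back to the TIFF XResolution tag (pixels per unit);
            # (1, 1) is the writer default placeholder, not a calibration
            page = tf.pages[0]
            tag = page.tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                if num and (num, den) != (1, 1):
                    size = den / num
        if size is None or size <= 0:
            raise ValueError(
                f"{path}: no pixel size in metadata; pass pixel_size_um "
                "explicitly (distances are physical)"
            )
        names = channel_names
        if names is None and "channel_names" in meta:
            names = json.loads(meta["channel_names"])
    return ImageStack(arr, names or [], size)
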