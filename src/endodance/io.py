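"""Calibrated image containers and file round-trips.

Movies are held as :class:`ImageStack` (time, row, column) float arrays with
physical calibration attached, and written as multi-page TIFF with the
calibration embedded as JSON metadata (readable back with tifffile alone).
Tables (spots, tracks, events, ground truth) travel as plain CSV through
pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Time-ordered 2D frames with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Pixel values (photons or arbitrary units). A single 2D frame is
        promoted to a one-frame stack.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    frame_interval : float
        Time between consecutive frames in seconds.
    meta : dict
        Free-form provenance (render report, modality, ...).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, H, W) data, got shape {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, i: int) -> np.ndarray:
        return self.data[i]

    def max_project(self) -> np.ndarray:
        """Maximum-intensity projection over time."""
        return self.data.max(axis=0)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF with calibration in JSON metadata."""
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",  # 3-frame stacks must not be guessed RGB
        metadata={
            "axes": "TYX",
            "pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
        },
    )


def read_stack(path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (or any plain TIFF).

    Calibration is taken from the embedded metadata; explicit arguments
    override it and are required for foreign files that carry none.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            f"{path}: no calibration metadata found; pass pixel_size and frame_interval"
        )
    return ImageStack(np.asarray(data, dtype=float), float(px), float(dt))
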