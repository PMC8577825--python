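"""In-memory raster containers used throughout the pipelines.

All images carry an isotropic pixel size in micrometres per pixel.
Conventions (declared once, tested in round-trips):

* array axes are ``[y, x]`` (row-major), stacks are ``[z, c, y, x]``;
* pixel indices are 0-based, coordinates in μm refer to pixel centres with
  the origin at the centre of the top-left pixel;
* boolean masks share shape and pixel size with their source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ShapeMismatchError


@dataclass
class Image2D:
    """Single-channel 2-D image with physical pixel size."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeMismatchError(f"Image2D expects 2-D data, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("Image2D values must be finite")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """Boolean mask sharing geometry with its source image."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ShapeMismatchError(f"BinaryMask expects 2-D data, got shape {self.values.shape}")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def area_um2(self) -> float:
        return float(self.values.sum()) * self.pixel_size_um**2

    @classmethod
    def empty_like(cls, other: "BinaryMask | Image2D") -> "BinaryMask":
        return cls(np.zeros(other.shape, dtype=bool), other.pixel_size_um)


@dataclass
class LabelMap:
    """Connected-region labelling with a per-component measurement table.

    ``values`` holds non-negative integer labels (0 = background), labels
    contiguous ``1..K``.  ``table`` has one row per label with columns
    ``label, area_px, area_um2, centroid_y_px, centroid_x_px, centroid_y_um,
    centroid_x_um, bbox_y0, bbox_x0, bbox_y1, bbox_x1`` (half-open bounds).
    """

    values: np.ndarray
    pixel_size_um: float
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ConfigError("LabelMap values must be integers")

    @property
    def n_labels(self) -> int:
        return len(self.table)

    def mask_for(self, label: int) -> np.ndarray:
        return self.values == label


@dataclass
class ImageStack:
    """Multi-channel, multi-z fluorescence stack: axes ``[z, c, y, x]``."""

    values: np.ndarray
    channel_roles: tuple[str, ...]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ShapeMismatchError(
                f"ImageStack expects (z, c, y, x) data, got shape {self.values.shape}"
            )
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.values.shape[1]:
            raise ConfigError(
                f"{len(self.channel_roles)} channel roles for {self.values.shape[1]} channels"
            )
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")

    @property
    def n_z(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise ConfigError(
                f"unknown channel role {role!r}; available: {list(self.channel_roles)}"
            ) from None

    def channel(self, role: str) -> np.ndarray:
        """All z-slices of one channel, shape (z, y, x)."""
        return self.values[:, self.channel_index(role)]

    def plane(self, role: str, z: int) -> Image2D:
        return Image2D(self.values[z, self.channel_index(role)].copy(), self.pixel_size_um)


def check_same_geometry(a, b) -> None:
    """Raise unless the two rasters share shape and pixel size."""
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_size_um, b.pixel_size_um):
        raise ShapeMismatchError(
            f"pixel size mismatch: {a.pixel_size_um} vs {b.pixel_size_um} μm/px"
        )
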