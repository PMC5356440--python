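"""Calibrated 2D intensity rasters and TIFF I/O.

The :class:`ImageGrid` is the unit every detector and profiler consumes: a
non-negative float raster with a pixel size in µm/px and an optional
exposure-group label.  Images acquired for one comparison must share an
exposure group, which downstream code uses to enforce that detection and
baselining parameters are applied identically across the group.

Pixel (row, col) covers the square [col*p, (col+1)*p) x [row*p, (row+1)*p)
in µm, so the pixel *centre* sits at ((col+0.5)*p, (row+0.5)*p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import InvalidParameterError


@dataclass
class ImageGrid:
    values: np.ndarray
    pixel_size: float
    exposure_group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidParameterError("ImageGrid values must be a 2D array")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if np.any(v < 0):
            raise InvalidParameterError("intensities must be non-negative")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def field_size(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        h, w = self.values.shape
        return (w * self.pixel_size, h * self.pixel_size)

    def um_to_index(self, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
        """Continuous (row, col) pixel indices of µm positions."""
        col = np.asarray(x_um, dtype=float) / self.pixel_size - 0.5
        row = np.asarray(y_um, dtype=float) / self.pixel_size - 0.5
        return row, col

    def contains_um(self, x_um, y_um) -> np.ndarray:
        w, h = self.field_size
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        return (x >= 0) & (x <= w) & (y >= 0) & (y <= h)

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-centre x and y coordinates in µm."""
        h, w = self.values.shape
        x = (np.arange(w) + 0.5) * self.pixel_size
        y = (np.arange(h) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


def save_image(path: str | Path, image: ImageGrid) -> None:
    """Write a grayscale TIFF plus a JSON sidecar holding the calibration."""
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    sidecar = {
        "pixel_size_um": image.pixel_size,
        "exposure_group": image.exposure_group,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_image(path: str | Path, pixel_size: float | None = None,
               exposure_group: str | None = None) -> ImageGrid:
    """Read a grayscale TIFF; calibration comes from the sidecar unless given."""
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = pixel_size or sidecar.get("pixel_size_um")
        exposure_group = exposure_group or sidecar.get("exposure_group")
    if pixel_size is None:
        raise InvalidParameterError(
            f"no pixel size for {path}: pass pixel_size= or provide a sidecar"
        )
    return ImageGrid(np.clip(values, 0.0, None), pixel_size, exposure_group)
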