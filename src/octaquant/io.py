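"""Image and table I/O, and the enface image container.

Coordinates are 0-based (row, col), row-major; distances are measured
between pixel centers. Images are square enface angiograms covering a
metric field of view (default 3 x 3 mm), so the pixel pitch in micrometres
is ``field_width_mm * 1000 / n_cols``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger("octaquant")

PLEXUSES = ("SCP", "DCP")


@dataclass(frozen=True)
class EnfaceImage:
    """A 2D decorrelation-intensity grid with physical pixel size.

    ``pixels`` holds intensities normalized to [0, 1]; ``plexus`` is either
    ``"SCP"`` (superficial) or ``"DCP"`` (deep capillary plexus).
    """

    pixels: np.ndarray
    field_width_mm: float = 3.0
    plexus: str = "SCP"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D grid, got shape {px.shape}")
        if px.shape[0] != px.shape[1] or px.shape[0] == 0:
            raise ValueError(f"enface image must be square and non-empty, got {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("intensities must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        if self.plexus not in PLEXUSES:
            raise ValueError(f"plexus must be one of {PLEXUSES}, got {self.plexus!r}")
        if self.field_width_mm <= 0:
            raise ValueError("field_width_mm must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_size_um(self) -> float:
        return self.field_width_mm * 1000.0 / self.n_cols

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "EnfaceImage":
        return EnfaceImage(pixels, self.field_width_mm, self.plexus)


def as_mask(arr, shape=None) -> np.ndarray:
    """Validate a boolean mask grid, optionally against a parent shape."""
    m = np.asarray(arr)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {m.shape}")
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match parent {tuple(shape)}")
    return m


def read_enface(path, field_width_mm: float = 3.0, plexus: str = "SCP") -> EnfaceImage:
    """Read an 8- or 16-bit single-channel PNG/TIFF as an EnfaceImage.

    Intensities are linearly rescaled to [0, 1] by the bit-depth maximum.
    """
    raw = iio.imread(path)
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {raw.shape}")
    if raw.shape[0] != raw.shape[1]:
        raise ValueError(f"{path}: expected a square image, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"{path}: unsupported dtype {raw.dtype}; need uint8 or uint16")
    logger.info("io read_enface path=%s shape=%s plexus=%s", path, raw.shape, plexus)
    return EnfaceImage(raw.astype(float) / scale, field_width_mm, plexus)


def write_enface(image: EnfaceImage, path) -> None:
    """Write an EnfaceImage as an 8-bit grayscale PNG (rounded quantization)."""
    iio.imwrite(Path(path), np.round(image.pixels * 255).astype(np.uint8))


def read_mask(path, shape=None) -> np.ndarray:
    """Read a mask image; any nonzero pixel is True."""
    raw = iio.imread(path)
    if raw.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel, got shape {raw.shape}")
    return as_mask(raw > 0, shape)


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), np.where(as_mask(mask), 255, 0).astype(np.uint8))


def write_deficit_overlay(image: EnfaceImage, deficit: np.ndarray, path) -> None:
    """Write a red-on-grayscale overlay PNG of a deficit mask for audit."""
    gray = np.round(image.pixels * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[as_mask(deficit, image.pixels.shape)] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)


# ---------------------------------------------------------------------------
# cohort tables

#: clinical covariate columns, one row per eye
CLINICAL_COLUMNS = ["patient_id", "laterality", "dme", "dr_stage", "cst_um", "bcva_logmar"]

#: per-plexus metric fields, mirrored as scp_<f> / dcp_<f> CSV columns
METRIC_FIELDS = ["vd", "vld", "vdi", "fd", "vti", "vci", "cnp_pct", "gpd_pct", "faz_area_mm2"]


def metric_columns() -> list[str]:
    return [f"{plexus.lower()}_{f}" for plexus in PLEXUSES for f in METRIC_FIELDS]


def write_metrics_table(table: pd.DataFrame, path) -> None:
    """Write a per-eye metrics table as CSV.

    Missing values are written as empty cells (never zeros) so that a
    round-trip read reproduces the table, NaNs included.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty cohort table")
    cols = [c for c in CLINICAL_COLUMNS + metric_columns() if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)
    logger.info("io write_metrics_table path=%s rows=%d", path, len(table))


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
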