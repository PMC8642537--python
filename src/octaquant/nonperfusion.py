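"""Capillary nonperfusion (CNP) and geometric perfusion deficit (GPD).

Both measures threshold a Euclidean distance map: a pixel belongs to a
deficit when its distance to the nearest perfused reference pixel exceeds
the normal inter-capillary bound (default 30 um). CNP references the
binary vessel map and applies a morphological cleanup chain (attribute
filter, then erosion); GPD references the skeleton and applies none. The
foveal avascular zone is physiologically avascular and is removed from the
deficit (numerator) last.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .config import AnalysisConfig
from .io import as_mask

logger = logging.getLogger("octaquant")


@dataclass(frozen=True)
class DistanceMap:
    """Per-pixel Euclidean distance (um) to the nearest reference pixel."""

    distances_um: np.ndarray
    reference: str  # "BINARY" or "SKELETON"
    pixel_size_um: float


@dataclass(frozen=True)
class NonperfusionResult:
    mask: np.ndarray
    percent: float
    method: str  # "CNP" or "GPD"
    threshold_um: float


def distance_map(reference: np.ndarray, pixel_size_um: float,
                 reference_kind: str = "BINARY") -> DistanceMap:
    """Exact Euclidean distance transform of the background, scaled to um."""
    ref = as_mask(reference)
    if not ref.any():
        raise ValueError("reference mask is empty; all distances would be infinite")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    d = ndimage.distance_transform_edt(~ref) * pixel_size_um
    return DistanceMap(d, reference_kind, pixel_size_um)


def _area_filter(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Binary attribute (area) opening: drop components smaller than min_area_px."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def _percent(mask: np.ndarray, faz: np.ndarray, exclude_faz_from_area: bool) -> float:
    denom = mask.size - int(faz.sum()) if exclude_faz_from_area else mask.size
    return 100.0 * int(mask.sum()) / denom


def cnp_quantify(binary: np.ndarray, faz: np.ndarray,
                 config: AnalysisConfig | None = None,
                 pixel_size_um: float = 3000.0 / 304) -> NonperfusionResult:
    """Capillary nonperfusion from the vessel distance map.

    Chain: threshold the distance map at the normal inter-capillary bound,
    attribute-filter connected deficit regions below the minimum area,
    erode by the configured radius, then exclude the FAZ.
    """
    config = config or AnalysisConfig()
    b = as_mask(binary)
    faz = as_mask(faz, b.shape)
    thr = config.cnp_distance_threshold_um
    d = distance_map(b, pixel_size_um, "BINARY")
    deficit = d.distances_um > thr
    if config.attr_min_area_px > 0:
        deficit = _area_filter(deficit, config.attr_min_area_px)
    if config.erosion_radius_px > 0:
        deficit = ndimage.binary_erosion(
            deficit, structure=morphology.disk(config.erosion_radius_px))
    deficit &= ~faz
    pct = _percent(deficit, faz, config.nonperfusion_exclude_faz_from_area)
    logger.info("nonperfusion cnp percent=%.3f threshold_um=%.1f", pct, thr)
    return NonperfusionResult(deficit, pct, "CNP", thr)


def gpd_quantify(skeleton: np.ndarray, faz: np.ndarray,
                 config: AnalysisConfig | None = None,
                 pixel_size_um: float = 3000.0 / 304) -> NonperfusionResult:
    """Geometric perfusion deficit from the skeleton distance map.

    Same thresholding as CNP but referenced to the centerlines and with no
    morphological post-filtering.
    """
    config = config or AnalysisConfig()
    sk = as_mask(skeleton)
    faz = as_mask(faz, sk.shape)
    thr = config.gpd_distance_threshold_um
    d = distance_map(sk, pixel_size_um, "SKELETON")
    deficit = (d.distances_um > thr) & ~faz
    pct = _percent(deficit, faz, config.nonperfusion_exclude_faz_from_area)
    logger.info("nonperfusion gpd percent=%.3f threshold_um=%.1f", pct, thr)
    return NonperfusionResult(deficit, pct, "GPD", thr)


def faz_fallback(binary: np.ndarray, pixel_size_um: float,
                 closing_radius_px: int = 1) -> np.ndarray:
    """Classical fallback FAZ detector (used when no mask file is supplied).

    Closes small gaps in the vessel map, then returns the connected
    non-vessel component containing the image center. Requires an
    avascular neighborhood at the center; fails loudly otherwise.
    """
    b = as_mask(binary)
    closed = ndimage.binary_closing(
        b, structure=morphology.disk(closing_radius_px), border_value=0)
    background = ~closed
    center = (b.shape[0] // 2, b.shape[1] // 2)
    if not background[center]:
        raise ValueError(
            "image center is a vessel pixel; cannot auto-detect the FAZ - "
            "supply a FAZ mask file")
    labels, _ = ndimage.label(background)
    mask = labels == labels[center]
    logger.info("nonperfusion faz_fallback area_px=%d", int(mask.sum()))
    return mask
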