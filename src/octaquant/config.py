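"""Analysis configuration shared by all pipeline stages.

All physical distances are configured in micrometres and converted to pixels
per image via its pixel pitch; all purely digital parameters (Frangi scales,
box sizes, morphology radii) are in pixels.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Tunable parameters of the quantification pipeline.

    Parameters
    ----------
    threshold_multiplier : float
        ``k`` in the FAZ-referenced binarization threshold
        ``mean(FAZ) + k * SD(FAZ)``. Default 1.2.
    faz_sd_population : bool
        Use the population SD (divide by n) in the threshold. Default True.
    binarize_source : str
        Which signal the FAZ threshold rule is applied to:
        ``"gated"`` (default) — foreground where BOTH the raw intensity and
        the rescaled vesselness exceed their own FAZ-referenced thresholds;
        ``"enhanced"`` — threshold the rescaled vesselness only;
        ``"raw"`` — threshold the raw intensity only.
    frangi_scales : tuple of float
        Vesselness filter scales in pixels; capillaries are 1-2 px at the
        default 9.87 um pitch.
    cnp_distance_threshold_um, gpd_distance_threshold_um : float
        Normal inter-capillary distance bounds for the two deficit measures.
    attr_min_area_px : int
        Minimum connected deficit-region area kept by the attribute filter
        (CNP chain only).
    erosion_radius_px : int
        Radius of the disk erosion applied to the CNP deficit mask
        (0 disables).
    nonperfusion_exclude_faz_from_area : bool
        If True the percent denominator excludes FAZ pixels; default False
        (FAZ removed from the numerator only).
    fd_box_sizes : tuple of int
        Box-counting sizes (px), strictly increasing.
    vdi_inverted : bool
        If True, VDI is the literal VLD/VD quotient instead of VD/VLD.
    vci_mode : str
        ``"component"`` (default) — isoperimetric quotient per connected
        component, area-weighted mean; ``"pooled"`` — single quotient from
        pooled counts.
    vci_pixel_counts : bool
        If True use raw perimeter-pixel counts in VCI instead of the
        calibrated perimeter-length estimate.
    vti_arc_estimator : str
        ``"polygon"`` (default) or ``"chain"``.
    vti_polygon_spacing_px : int
        Vertex spacing of the polygonal arc-length estimate.
    vti_min_segment_px : int
        Segments shorter than this many pixels are excluded from VTI.
    vti_weighted : bool
        Arc-length-weighted (default) vs unweighted VTI aggregation.
    faz_closing_radius_px : int
        Gap-closing radius used by the fallback FAZ detector.
    bonferroni_m : int or None
        Bonferroni family size; None means the number of metrics in the run.
    seed : int
        Default seed for stochastic generators.
    """

    threshold_multiplier: float = 1.2
    faz_sd_population: bool = True
    binarize_source: str = "gated"
    frangi_scales: tuple = (1.0, 1.5, 2.0)
    cnp_distance_threshold_um: float = 30.0
    gpd_distance_threshold_um: float = 30.0
    attr_min_area_px: int = 500
    erosion_radius_px: int = 1
    nonperfusion_exclude_faz_from_area: bool = False
    fd_box_sizes: tuple = (2, 4, 8, 16, 32, 64)
    vdi_inverted: bool = False
    vci_mode: str = "component"
    vci_pixel_counts: bool = False
    vti_arc_estimator: str = "polygon"
    vti_polygon_spacing_px: int = 4
    vti_min_segment_px: int = 3
    vti_weighted: bool = True
    faz_closing_radius_px: int = 1
    bonferroni_m: int | None = None
    seed: int = 20211203

    def __post_init__(self):
        if self.threshold_multiplier < 0:
            raise ValueError("threshold_multiplier must be >= 0")
        if self.cnp_distance_threshold_um <= 0 or self.gpd_distance_threshold_um <= 0:
            raise ValueError("distance thresholds must be > 0")
        sizes = tuple(self.fd_box_sizes)
        if len(sizes) < 2 or any(b >= a for a, b in zip(sizes[1:], sizes[:-1])):
            raise ValueError("fd_box_sizes must be >= 2 strictly increasing values")
        if self.binarize_source not in ("gated", "enhanced", "raw"):
            raise ValueError(f"unknown binarize_source {self.binarize_source!r}")
        if self.vci_mode not in ("component", "pooled"):
            raise ValueError(f"unknown vci_mode {self.vci_mode!r}")
        if self.vti_arc_estimator not in ("polygon", "chain"):
            raise ValueError(f"unknown vti_arc_estimator {self.vti_arc_estimator!r}")
        if not self.frangi_scales or any(s <= 0 for s in self.frangi_scales):
            raise ValueError("frangi_scales must be non-empty and positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("frangi_scales", "fd_box_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
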