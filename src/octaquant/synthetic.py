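"""Synthetic test data: analytic shapes, vascular networks, and cohorts.

Three layers of ground truth:

* :func:`make_shape` - noise-free rasterized shapes whose metric values are
  known in closed form (disk, square, bar, line, arc, annulus, grid);
* :func:`make_network` - a sine-perturbed capillary lattice with coarser
  trunk vessels, a central avascular FAZ bounded by a capillary ring,
  circular dropout lesions of known area, and multiplicative speckle;
* :func:`make_cohort` - a two-group clustered cohort (fellow eyes within
  patients) with a controllable DME effect on perfusion metrics.

Every generator is a pure function of its parameters and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .io import EnfaceImage, as_mask

DEFAULT_IMAGE_SIZE = 304  # standard export resolution of 3x3 mm enface scans


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact ground-truth masks and the parameters that generated them."""

    vessel_mask: np.ndarray
    faz_mask: np.ndarray
    dropout_mask: np.ndarray
    params: dict

    def __post_init__(self):
        v = as_mask(self.vessel_mask)
        f = as_mask(self.faz_mask, v.shape)
        d = as_mask(self.dropout_mask, v.shape)
        if (d & v).any():
            raise ValueError("dropout and vessel truth masks must be disjoint")
        object.__setattr__(self, "vessel_mask", v)
        object.__setattr__(self, "faz_mask", f)
        object.__setattr__(self, "dropout_mask", d)


def _empty_truth(mask: np.ndarray, **params) -> SyntheticTruth:
    z = np.zeros_like(mask, dtype=bool)
    return SyntheticTruth(mask, z, z, params)


def _to_image(mask: np.ndarray, field_width_mm: float, plexus: str) -> EnfaceImage:
    return EnfaceImage(mask.astype(float), field_width_mm, plexus)


def make_shape(kind: str, params: dict | None = None, image_size: int = 201,
               field_width_mm: float = 3.0) -> tuple[EnfaceImage, SyntheticTruth]:
    """Noise-free binary-valued image of an analytic shape plus exact truth.

    Supported kinds and parameters (all lengths in pixels):

    * ``disk``: center (default image center), ``radius``
    * ``square``: ``side`` (axis-aligned, centered)
    * ``bar``: ``width`` x ``length`` horizontal bar, centered
    * ``line``: 1-px full-width horizontal line at ``row`` (default center)
    * ``arc``: circular arc of ``radius`` from ``theta0`` to ``theta1``
      radians (1-px wide, 8-connected)
    * ``annulus``: ``r_inner`` .. ``r_outer`` filled ring
    * ``grid``: horizontal+vertical lines of ``width`` every ``spacing``
    """
    params = dict(params or {})
    n = image_size
    mask = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[:n, :n]
    cy = params.get("center_row", n // 2)
    cx = params.get("center_col", n // 2)

    if kind == "disk":
        r = params["radius"]
        if cy - r < 0 or cy + r >= n or cx - r < 0 or cx + r >= n:
            raise ValueError("disk does not fit in the image")
        mask[np.hypot(yy - cy, xx - cx) <= r] = True
    elif kind == "square":
        s = params["side"]
        r0, c0 = cy - s // 2, cx - s // 2
        if r0 < 0 or c0 < 0 or r0 + s > n or c0 + s > n:
            raise ValueError("square does not fit in the image")
        mask[r0:r0 + s, c0:c0 + s] = True
    elif kind == "bar":
        w, length = params["width"], params["length"]
        r0, c0 = cy - w // 2, cx - length // 2
        if r0 < 0 or c0 < 0 or r0 + w > n or c0 + length > n:
            raise ValueError("bar does not fit in the image")
        mask[r0:r0 + w, c0:c0 + length] = True
    elif kind == "line":
        mask[params.get("row", cy), :] = True
    elif kind == "arc":
        r = params["radius"]
        t0, t1 = params.get("theta0", 0.0), params.get("theta1", math.pi)
        ts = np.linspace(t0, t1, max(16, int(8 * r * abs(t1 - t0))))
        rows = np.round(cy - r * np.sin(ts)).astype(int)
        cols = np.round(cx + r * np.cos(ts)).astype(int)
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= n or cols.max() >= n:
            raise ValueError("arc does not fit in the image")
        mask[rows, cols] = True
    elif kind == "annulus":
        ri, ro = params["r_inner"], params["r_outer"]
        if cy + ro >= n or cy - ro < 0 or cx + ro >= n or cx - ro < 0:
            raise ValueError("annulus does not fit in the image")
        rr = np.hypot(yy - cy, xx - cx)
        mask[(rr >= ri) & (rr <= ro)] = True
    elif kind == "grid":
        spacing, w = params["spacing"], params.get("width", 1)
        for start in range(0, n, spacing):
            mask[start:start + w, :] = True
            mask[:, start:start + w] = True
    else:
        raise ValueError(f"unknown shape kind {kind!r}")

    truth = _empty_truth(mask, kind=kind, **params)
    return _to_image(mask, field_width_mm, "SCP"), truth


def _draw_sine_lines(mask, axis, spacing, amp, rng, width, wavelengths=(40.0, 80.0)):
    n = mask.shape[0]
    x = np.arange(n)
    for pos in np.arange(rng.uniform(0, spacing), n, spacing):
        lam = rng.uniform(*wavelengths)
        phase = rng.uniform(0, 2 * math.pi)
        track = np.round(pos + amp * np.sin(2 * math.pi * x / lam + phase)).astype(int)
        for w in range(width):
            t = track + w
            ok = (t >= 0) & (t < n)
            if axis == 0:
                mask[t[ok], x[ok]] = True
            else:
                mask[x[ok], t[ok]] = True


def make_network(density_target: float = 33.0, tortuosity_amp: float = 1.5,
                 faz_radius_um: float = 380.0, dropout_fraction: float = 0.0,
                 noise_sd: float = 0.15, seed: int = 0,
                 image_size: int = DEFAULT_IMAGE_SIZE, field_width_mm: float = 3.0,
                 vessel_width_px: int = 1, n_trunks: int = 4,
                 plexus: str = "SCP") -> tuple[EnfaceImage, SyntheticTruth]:
    """Synthetic capillary network with exact ground truth.

    The capillary bed is a sine-perturbed square lattice whose spacing is
    set from ``density_target`` (percent vessel area); a few wider trunk
    vessels emulate the superficial arcades. The central FAZ disk is
    avascular and bounded by a capillary ring. Dropout lesions are circular,
    placed in the perifoveal annulus (border clipping allowed), and carved
    out of the vessel mask; their union is the exact dropout truth.
    """
    if not 0 < density_target < 80:
        raise ValueError("density_target must be in (0, 80) percent")
    if not 0 <= dropout_fraction < 50:
        raise ValueError("dropout_fraction must be in [0, 50) percent")
    rng = np.random.default_rng(seed)
    n = image_size
    px_um = field_width_mm * 1000.0 / n
    mask = np.zeros((n, n), dtype=bool)

    # lattice spacing from the two-family coverage 1 - (1 - w/s)^2
    w = vessel_width_px
    frac = density_target / 100.0
    spacing = w / (1.0 - math.sqrt(1.0 - frac))
    _draw_sine_lines(mask, 0, spacing, tortuosity_amp, rng, w)
    _draw_sine_lines(mask, 1, spacing, tortuosity_amp, rng, w)

    # coarser trunks
    x = np.arange(n)
    for _ in range(n_trunks):
        axis = rng.integers(0, 2)
        pos = rng.uniform(0.1 * n, 0.9 * n)
        lam = rng.uniform(150, 300)
        phase = rng.uniform(0, 2 * math.pi)
        track = np.round(pos + 4.0 * np.sin(2 * math.pi * x / lam + phase)).astype(int)
        for off in range(-1, 2):
            t = track + off
            ok = (t >= 0) & (t < n)
            if axis == 0:
                mask[t[ok], x[ok]] = True
            else:
                mask[x[ok], t[ok]] = True

    yy, xx = np.mgrid[:n, :n]
    r_center = np.hypot(yy - n / 2.0, xx - n / 2.0)
    faz_r = faz_radius_um / px_um
    faz = r_center <= faz_r
    mask[faz] = False
    mask |= (r_center > faz_r) & (r_center <= faz_r + max(w, 1))  # parafoveal ring

    dropout = np.zeros((n, n), dtype=bool)
    if dropout_fraction > 0:
        target = dropout_fraction / 100.0 * n * n
        guard = 0
        while dropout.sum() < target - 0.002 * n * n:
            guard += 1
            if guard > 200:
                raise ValueError(
                    "cannot place the requested dropout fraction with this FAZ/field")
            rem = target - dropout.sum()
            rl = math.sqrt(rem / math.pi)
            placed = False
            for _ in range(60):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(faz_r + min(rl, 30) + 10, n / 2.0)
                ly = n / 2.0 + rad * math.sin(ang)
                lx = n / 2.0 + rad * math.cos(ang)
                lesion = np.hypot(yy - ly, xx - lx) <= rl
                area = lesion.sum()
                if area == 0 or (lesion & (faz | dropout)).any():
                    continue
                if area > 1.1 * rem:
                    continue
                dropout |= lesion
                placed = True
                break
            if not placed:
                rl *= 0.8  # retry smaller on a crowded field
                if rl < 3:
                    raise ValueError(
                        "cannot place the requested dropout fraction with this FAZ/field")
        mask[dropout] = False

    base = np.where(mask, 0.75, 0.06)
    img = base * (1.0 + noise_sd * rng.standard_normal((n, n))) if noise_sd > 0 else base
    img = np.clip(img, 0.0, 1.0)
    truth = SyntheticTruth(mask, faz, dropout, dict(
        density_target=density_target, tortuosity_amp=tortuosity_amp,
        faz_radius_um=faz_radius_um, dropout_fraction=dropout_fraction,
        noise_sd=noise_sd, seed=seed, image_size=image_size,
        field_width_mm=field_width_mm, vessel_width_px=vessel_width_px))
    return EnfaceImage(img, field_width_mm, plexus), truth


def classify_dme(cst_um: float, central_cysts: bool) -> bool:
    """Diabetic macular edema label: CST strictly above 350 um or central
    cystoid changes."""
    if cst_um <= 0:
        raise ValueError("cst_um must be > 0")
    return cst_um > 350.0 or bool(central_cysts)


@dataclass(frozen=True)
class CohortSpec:
    """Shape and effect sizes of a simulated two-group clustered cohort.

    Defaults mirror the study cohort this package emulates: 92 patients,
    46 bilateral (138 eyes), 59 DME eyes, 44 PDR eyes; DME adds about +3
    percentage points of geometric perfusion deficit and removes about 2.5
    points of vessel density, with fellow-eye correlation 0.6.
    """

    n_patients: int = 92
    bilateral_fraction: float = 46.0 / 92.0
    p_dme: float = 59.0 / 138.0
    p_pdr: float = 44.0 / 138.0
    dme_effect_gpd: float = 3.0
    dme_effect_cnp: float = 3.0
    dme_effect_vd: float = -2.5
    pdr_effect_gpd: float = 1.5
    pdr_effect_vd: float = -1.5
    inter_eye_correlation: float = 0.6
    gpd_sd: float = 4.5
    cnp_sd: float = 4.0
    vd_sd: float = 3.75
    seed: int = 20211203

    def __post_init__(self):
        for name in ("bilateral_fraction", "p_dme", "p_pdr", "inter_eye_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")


# no-DME marginal means/SDs per metric (scp, dcp); perfusion metrics get the
# configured group effects; the remaining indices stay null by default
_BASELINES = {
    "vd": ((28.86, None), (31.54, None)),
    "vti": ((1.138, 0.013), (1.141, 0.013)),
    "fd": ((1.944, 0.012), (1.965, 0.004)),
    "cnp_pct": ((4.99, None), (1.09, 1.27)),
    "gpd_pct": ((7.01, None), (2.17, 1.61)),
    "vdi": ((2.31, 0.08), (2.24, 0.07)),
    "vci": ((1.09, 0.08), (1.20, 0.05)),
    "faz_area_mm2": ((0.46, 0.16), (0.46, 0.16)),
}


def _draw_metric(base, sd, rho, u_patient, rng, effect=0.0, floor=None):
    e = rng.standard_normal()
    val = base + effect + sd * (math.sqrt(rho) * u_patient + math.sqrt(1 - rho) * e)
    if floor is not None:
        val = max(val, floor)
    return val


def make_cohort(spec: CohortSpec | None = None, with_images: bool = False,
                config: AnalysisConfig | None = None,
                image_size: int = DEFAULT_IMAGE_SIZE) -> list:
    """Simulate a clustered two-group cohort of eyes.

    Fellow eyes share a Gaussian patient effect producing inter-eye
    correlation ``rho`` on every metric. DME and PDR labels are drawn
    independently per eye (the emulated cohort shows no DME-stage
    association); DME shifts GPD/CNP up and VD down by the configured effects,
    PDR stage carries its own smaller shifts so the stage adjustment in the
    comparison stage is meaningful. CST is drawn so each eye satisfies the
    DME classification rule (CST > 350 um or central cysts).

    With ``with_images=True`` the DME/PDR/patient effects act on the image
    generator parameters (dropout fraction, lattice density) instead, and
    every metric is measured by running the full pipeline on the generated
    angiograms.
    """
    from .metrics import MetricSet, compute_metric_set
    from .preprocess import make_vessel_maps
    from .stats import EyeRecord

    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rho = spec.inter_eye_correlation
    records: list[EyeRecord] = []
    n_bilateral = int(round(spec.bilateral_fraction * spec.n_patients))

    for pid in range(spec.n_patients):
        u = rng.standard_normal()  # shared patient effect
        n_eyes = 2 if pid < n_bilateral else 1
        lateralities = ["OD", "OS"][:n_eyes]
        for lat in lateralities:
            dme = bool(rng.random() < spec.p_dme)
            pdr = bool(rng.random() < spec.p_pdr)
            if dme:
                cst = float(rng.normal(420.1, 115.4))
                cysts = cst <= 350.0
                if cst <= 0:
                    cst, cysts = 360.0, False
            else:
                cst = float(np.clip(rng.normal(254.1, 29.9), 150.0, 350.0))
                cysts = False
            assert classify_dme(cst, cysts) == dme
            bcva = float(max(rng.normal(0.46 if dme else 0.19, 0.30 if dme else 0.19), 0.0))

            if with_images:
                metrics = {}
                for plexus in ("SCP", "DCP"):
                    density = (33.0 + spec.dme_effect_vd * dme + spec.pdr_effect_vd * pdr
                               + 2.0 * (math.sqrt(rho) * u
                                        + math.sqrt(1 - rho) * rng.standard_normal()))
                    dropout = max(0.0, 2.0 + spec.dme_effect_gpd * dme
                                  + spec.pdr_effect_gpd * pdr
                                  + 1.0 * (math.sqrt(rho) * u
                                           + math.sqrt(1 - rho) * rng.standard_normal()))
                    img, truth = make_network(
                        density_target=float(np.clip(density, 15.0, 50.0)),
                        dropout_fraction=float(min(dropout, 25.0)),
                        seed=int(rng.integers(0, 2**31 - 1)),
                        image_size=image_size, plexus=plexus)
                    maps = make_vessel_maps(img, truth.faz_mask, config)
                    metrics[plexus] = compute_metric_set(maps, truth.faz_mask, config)
                ms_scp, ms_dcp = metrics["SCP"], metrics["DCP"]
            else:
                sets = []
                for ip in range(2):
                    vals = {}
                    for name, per_plexus in _BASELINES.items():
                        base, sd = per_plexus[ip]
                        if name == "vd":
                            sd = spec.vd_sd
                            eff = spec.dme_effect_vd * dme + spec.pdr_effect_vd * pdr
                        elif name == "gpd_pct":
                            sd = spec.gpd_sd if ip == 0 else per_plexus[ip][1]
                            eff = (spec.dme_effect_gpd * dme + spec.pdr_effect_gpd * pdr
                                   ) * (1.0 if ip == 0 else 0.45)
                        elif name == "cnp_pct":
                            sd = spec.cnp_sd if ip == 0 else per_plexus[ip][1]
                            eff = spec.dme_effect_cnp * dme * (1.0 if ip == 0 else 0.5)
                        else:
                            eff = 0.0
                        floor = 0.0 if name in ("cnp_pct", "gpd_pct", "faz_area_mm2") else None
                        if name in ("vti",):
                            floor = 1.0
                        vals[name] = _draw_metric(base, sd, rho, u, rng, eff, floor)
                    vals["vld"] = vals["vd"] / vals["vdi"]
                    sets.append(MetricSet(**vals))
                ms_scp, ms_dcp = sets

            records.append(EyeRecord(
                patient_id=f"P{pid:03d}", laterality=lat, dme=dme,
                dr_stage="PDR" if pdr else "NPDR", cst_um=cst, bcva_logmar=bcva,
                metrics_scp=ms_scp, metrics_dcp=ms_dcp))
    return records
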