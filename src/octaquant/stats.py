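"""Clustered two-group comparison of OCTA metrics.

Fellow eyes of one patient are correlated, so group contrasts are
estimated with generalized estimating equations (GEE): a Gaussian marginal
model with identity link, patients as clusters, an exchangeable working
correlation, and a cluster-robust sandwich covariance. The DME contrast is
adjusted for diabetic-retinopathy stage (NPDR vs PDR), and p-values across
the metric family are Bonferroni-corrected.

Small-sample inference: with fewer than ~100 clusters the plain sandwich
is liberal, so the default covariance is the Mancl-DeRouen bias-reduced
sandwich and p-values use a t reference with (clusters - parameters)
degrees of freedom.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.families import Gaussian

from .io import CLINICAL_COLUMNS, METRIC_FIELDS, metric_columns

logger = logging.getLogger("octaquant")

#: the default metric family of one comparison run (15 tests)
DEFAULT_METRICS = [
    "scp_faz_area_mm2", "scp_vti", "scp_fd", "dcp_fd", "scp_cnp_pct",
    "scp_gpd_pct", "scp_vd", "dcp_vti", "dcp_cnp_pct", "dcp_gpd_pct",
    "dcp_vd", "scp_vdi", "dcp_vdi", "scp_vci", "dcp_vci",
]


@dataclass(frozen=True)
class EyeRecord:
    """Clinical covariates plus per-plexus metric sets for one eye."""

    patient_id: str
    laterality: str
    dme: bool
    dr_stage: str  # "NPDR" | "PDR"
    cst_um: float
    bcva_logmar: float
    metrics_scp: object = None  # MetricSet
    metrics_dcp: object = None

    def __post_init__(self):
        if self.dr_stage not in ("NPDR", "PDR"):
            raise ValueError(f"dr_stage must be NPDR or PDR, got {self.dr_stage!r}")
        if self.cst_um <= 0:
            raise ValueError("cst_um must be > 0")


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    estimate: float
    robust_se: float
    p_raw: float
    p_bonferroni: float
    n_eyes: int
    n_clusters: int

    @property
    def ci95(self) -> tuple[float, float]:
        """95% confidence interval on the t reference used for the p-value."""
        crit = sps.t.ppf(0.975, max(self.n_clusters - 3, 1))
        return (self.estimate - crit * self.robust_se,
                self.estimate + crit * self.robust_se)


def records_to_table(records) -> pd.DataFrame:
    """Flatten EyeRecords into one row per eye (CSV-ready)."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "laterality": r.laterality,
               "dme": int(r.dme), "dr_stage": r.dr_stage,
               "cst_um": r.cst_um, "bcva_logmar": r.bcva_logmar}
        for plexus, ms in (("scp", r.metrics_scp), ("dcp", r.metrics_dcp)):
            for f in METRIC_FIELDS:
                row[f"{plexus}_{f}"] = getattr(ms, f) if ms is not None else math.nan
        rows.append(row)
    counts = pd.Series([r.patient_id for r in records]).value_counts()
    if (counts > 2).any():
        raise ValueError("a patient may contribute at most 2 eyes")
    return pd.DataFrame(rows)


def _as_table(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return records_to_table(table)


def _gee_fit(df: pd.DataFrame, metric: str, predictor: str,
             adjust_stage: bool, cov_struct, cov_type: str):
    cols = [predictor] + (["_pdr"] if adjust_stage else [])
    work = df.dropna(subset=[metric, predictor]).copy()
    y = work[metric].astype(float)
    X = sm.add_constant(work[cols].astype(float))
    n_clusters = work["patient_id"].nunique()
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError(f"singular design for metric {metric!r}")
    model = sm.GEE(y, X, groups=work["patient_id"],
                   cov_struct=cov_struct, family=Gaussian())
    res = model.fit(maxiter=200, cov_type=cov_type)
    est = float(res.params[predictor])
    se = float(res.bse[predictor])
    df_t = max(n_clusters - X.shape[1], 1)
    p = float(2 * sps.t.sf(abs(est / se), df_t))
    return est, se, p, len(work), n_clusters


def compare_groups(table, metric: str, cov_struct=None,
                   cov_type: str = "bias_reduced",
                   bonferroni_m: int = 1) -> ComparisonResult:
    """DME-group contrast for one metric, adjusted for DR stage.

    ``table`` is a list of EyeRecords or a flat per-eye DataFrame. Returns
    the DME coefficient of ``metric ~ DME + stage`` with its cluster-robust
    standard error and two-sided p (raw and Bonferroni-scaled).
    """
    df = _as_table(table).copy()
    if metric not in df.columns:
        raise ValueError(f"metric {metric!r} not present")
    groups = df.dropna(subset=[metric]).groupby("dme")["patient_id"]
    if groups.ngroups < 2:
        raise ValueError("both DME groups must be present")
    if (groups.nunique() < 2).any():
        raise ValueError("need >= 2 clusters per group")
    df["_pdr"] = (df["dr_stage"] == "PDR").astype(float)
    df["dme"] = df["dme"].astype(float)
    est, se, p, n_eyes, n_clusters = _gee_fit(
        df, metric, "dme", True, cov_struct or Exchangeable(), cov_type)
    result = ComparisonResult(metric, est, se, p, min(p * bonferroni_m, 1.0),
                              n_eyes, n_clusters)
    logger.info("stats compare_groups metric=%s estimate=%.4f se=%.4f p=%.4g",
                metric, est, se, p)
    return result


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by the family size (default: the list length), cap at 1."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must be in [0, 1]")
    m = len(ps) if m is None else m
    return [min(p * m, 1.0) for p in ps]


def comparison_table(table, metrics=None, cov_type: str = "bias_reduced",
                     bonferroni_m: int | None = None) -> pd.DataFrame:
    """Run compare_groups over a metric family and Bonferroni-correct."""
    df = _as_table(table)
    metrics = list(metrics or [m for m in DEFAULT_METRICS if m in df.columns])
    m = bonferroni_m if bonferroni_m is not None else len(metrics)
    results = [compare_groups(df, metric, cov_type=cov_type, bonferroni_m=m)
               for metric in metrics]
    return pd.DataFrame([{
        "metric": r.metric, "estimate": r.estimate, "robust_se": r.robust_se,
        "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
        "n_eyes": r.n_eyes, "n_clusters": r.n_clusters} for r in results])


def plexus_ratios(record: EyeRecord) -> tuple[float, float, float]:
    """Per-eye SCP/DCP quotients for CNP, GPD and VD (NaN when DCP is 0)."""
    out = []
    for f in ("cnp_pct", "gpd_pct", "vd"):
        scp = getattr(record.metrics_scp, f)
        dcp = getattr(record.metrics_dcp, f)
        out.append(math.nan if (dcp == 0 or math.isnan(dcp)) else scp / dcp)
    return tuple(out)


def cst_association(table, subgroup: str, metric: str,
                    cov_type: str = "bias_reduced",
                    bonferroni_m: int = 1) -> ComparisonResult:
    """Within-subgroup clustered association of a metric with CST.

    ``subgroup`` is ``"DME"`` or ``"noDME"``; the model is
    ``metric ~ CST + stage`` with the same clustering and covariance as
    :func:`compare_groups`.
    """
    df = _as_table(table).copy()
    if subgroup not in ("DME", "noDME"):
        raise ValueError("subgroup must be 'DME' or 'noDME'")
    df = df[df["dme"].astype(bool) == (subgroup == "DME")]
    if df.empty or df["patient_id"].nunique() < 2:
        raise ValueError("subgroup needs >= 2 clusters")
    df["_pdr"] = (df["dr_stage"] == "PDR").astype(float)
    est, se, p, n_eyes, n_clusters = _gee_fit(
        df, metric, "cst_um", True, Exchangeable(), cov_type)
    return ComparisonResult(f"{metric}~cst|{subgroup}", est, se, p,
                            min(p * bonferroni_m, 1.0), n_eyes, n_clusters)


# ---------------------------------------------------------------------------
# demographic convenience comparisons (t test / chi-square)

def ttest_groups(table, column: str) -> tuple[float, float]:
    df = _as_table(table)
    a = df.loc[df["dme"].astype(bool), column].dropna()
    b = df.loc[~df["dme"].astype(bool), column].dropna()
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def chisq_groups(table, column: str = "dr_stage") -> tuple[float, float]:
    df = _as_table(table)
    ct = pd.crosstab(df["dme"].astype(bool), df[column])
    chi2, p, _, _ = sps.chi2_contingency(ct)
    return float(chi2), float(p)


def independence_structure():
    """Working-independence covariance structure (for sensitivity checks)."""
    return Independence()
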