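"""Agreement statistics for method comparison of quantitative maps.

The battery compares per-subject regional means between imaging methods
(fast scan, deep-learning reconstruction, routine scan): paired t-tests,
TOST equivalence against +-5%-of-reference margins with a 90% CI,
ordinary least-squares regression, Bland-Altman analysis on pair-mean
percent differences, intra-/inter-group coefficients of variation, and
a lesion-ROI comparison table.

Conventions: the Bland-Altman percent denominator is the pair mean (the
standard ratio form); the intergroup CV is the sample SD of the method
means over their grand mean (with two methods this is the literal
two-number CV); equivalence holds iff the 90% CI of the mean paired
difference lies strictly inside (-epsilon, +epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "TOSTConfig", "PairedTResult", "TOSTResult", "extract_mean",
    "paired_ttest", "tost_equivalence", "linear_regression",
    "bland_altman_percent", "cv_intragroup", "cv_intergroup",
    "lesion_table_compare", "AgreementReport", "build_agreement_report",
]

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class TOSTConfig:
    margin_fraction: float = 0.05
    ci_level: float = 0.90

    def __post_init__(self):
        if not (0 < self.margin_fraction < 1):
            raise ValueError("margin_fraction must be in (0, 1)")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")

    def margin(self, reference_mean: float) -> float:
        return self.margin_fraction * reference_mean


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class TOSTResult:
    epsilon: float
    ci_low: float
    ci_high: float
    equivalent: bool
    mean_diff: float


def extract_mean(qmap, mask: np.ndarray) -> float:
    """Arithmetic mean of the map's physical values under a boolean mask."""
    values = qmap.values if hasattr(qmap, "values") else np.asarray(qmap)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("mask and map must share the grid")
    if not mask.any():
        raise ValueError("empty mask")
    return float(values[mask].mean())


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need equal-length 1-D paired vectors")
    if x.size < 2:
        raise ValueError("need n >= 2 pairs")
    return x, y


def paired_ttest(x, y) -> PairedTResult:
    """Two-sided paired t-test on per-subject differences (df = n - 1).

    Zero-variance differences are flagged degenerate instead of
    producing a p-value.
    """
    x, y = _paired(x, y)
    d = x - y
    if np.var(d, ddof=1) < _VAR_EPS:
        return PairedTResult(t=float("nan"), df=d.size - 1, p=float("nan"),
                             degenerate=True)
    t, p = sp_stats.ttest_rel(x, y)
    return PairedTResult(t=float(t), df=d.size - 1, p=float(p))


def tost_equivalence(x, y, config: TOSTConfig, reference_mean: float
                     ) -> TOSTResult:
    """Two one-sided tests via the CI-inclusion criterion.

    epsilon = margin_fraction x reference mean; the two methods are
    declared equivalent iff the ``ci_level`` (default 90%) two-sided CI
    of the mean paired difference lies inside (-epsilon, +epsilon) —
    equivalent to both one-sided tests rejecting at alpha = (1 - level)/2.
    """
    x, y = _paired(x, y)
    d = x - y
    eps = config.margin(reference_mean)
    n = d.size
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    tcrit = float(sp_stats.t.ppf(0.5 + config.ci_level / 2.0, n - 1))
    lo, hi = mean - tcrit * se, mean + tcrit * se
    return TOSTResult(epsilon=float(eps), ci_low=lo, ci_high=hi,
                      equivalent=bool(-eps < lo and hi < eps), mean_diff=mean)


def linear_regression(x, y) -> tuple[float, float, float]:
    """OLS of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) < _VAR_EPS:
        raise ValueError("x has no variance")
    res = sp_stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def bland_altman_percent(x, y) -> tuple[float, float, float]:
    """Bland-Altman on percent differences: (bias%, lower LoA%, upper LoA%).

    Per pair: 100 (x - y) / pair-mean; bias is the mean, limits of
    agreement are bias +- 1.96 SD.  ``x`` is the test method, ``y`` the
    reference.
    """
    x, y = _paired(x, y)
    m = (x + y) / 2.0
    if np.any(m <= 0):
        raise ValueError("pair means must be positive for percent differences")
    pct = 100.0 * (x - y) / m
    bias = float(pct.mean())
    sd = float(pct.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def cv_intragroup(values) -> float:
    """Across-subject coefficient of variation within one method:
    100 x sample SD / mean (percent)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * v.std(ddof=1) / mean)


def cv_intergroup(method_means) -> float:
    """CV across the per-method average values:
    100 x sample SD of the method means / grand mean."""
    m = np.asarray(method_means, dtype=float)
    if m.size < 2:
        raise ValueError("need >= 2 method means")
    grand = m.mean()
    if grand <= 0:
        raise ValueError("grand mean must be positive")
    return float(100.0 * m.std(ddof=1) / grand)


def lesion_table_compare(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter paired t-tests across lesion ROIs.

    Expects columns t1_dl, t1_routine, t2_dl, t2_routine, pd_dl,
    pd_routine (one row per ROI).  Returns tidy rows with t, df, p and
    the degenerate flag.
    """
    if len(roi_table) < 2:
        raise ValueError("need at least 2 ROIs")
    rows = []
    for parameter in ("T1", "T2", "PD"):
        key = parameter.lower()
        res = paired_ttest(roi_table[f"{key}_dl"], roi_table[f"{key}_routine"])
        rows.append({"parameter": parameter, "n_rois": len(roi_table),
                     "t": res.t, "df": res.df, "p": res.p,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


@dataclass
class AgreementReport:
    """Statistics battery output for one parameter map comparison."""

    parameter: str
    tissue: pd.DataFrame = None          # per tissue: t/TOST columns
    regions: pd.DataFrame = None         # per region: CVs + paired t
    pooled_regression: dict = field(default_factory=dict)
    bland_altman: dict = field(default_factory=dict)
    lesions: pd.DataFrame = None

    def to_dict(self) -> dict:
        out = {"parameter": self.parameter,
               "pooled_regression": self.pooled_regression,
               "bland_altman": self.bland_altman}
        if self.tissue is not None:
            out["tissue"] = self.tissue.to_dict(orient="records")
        if self.regions is not None:
            out["regions"] = self.regions.to_dict(orient="records")
        if self.lesions is not None:
            out["lesions"] = self.lesions.to_dict(orient="records")
        return out


def build_agreement_report(parameter: str,
                           tissue_means: dict[str, dict[str, np.ndarray]],
                           region_means: dict[str, dict[str, np.ndarray]] | None = None,
                           lesion_table: pd.DataFrame | None = None,
                           config: TOSTConfig = TOSTConfig(),
                           test_method: str = "DL",
                           reference_method: str = "routine") -> AgreementReport:
    """Assemble the full battery for one parameter.

    ``tissue_means[tissue][method]`` and ``region_means[region][method]``
    hold per-subject mean vectors.  Regression and Bland-Altman pool the
    tissues (concatenated per-subject tissue means), mirroring a
    combined GM+WM assessment.
    """
    t_rows = []
    pooled_x, pooled_y = [], []
    for tissue_name in tissue_means:
        methods = tissue_means[tissue_name]
        x = np.asarray(methods[test_method], dtype=float)
        y = np.asarray(methods[reference_method], dtype=float)
        tres = paired_ttest(x, y)
        ref_mean = float(y.mean())
        tost = tost_equivalence(x, y, config, ref_mean)
        t_rows.append({
            "tissue": tissue_name, "n": x.size,
            "mean_test": float(x.mean()), "mean_reference": ref_mean,
            "t": tres.t, "p": tres.p, "degenerate": tres.degenerate,
            "epsilon": tost.epsilon, "ci_low": tost.ci_low,
            "ci_high": tost.ci_high, "equivalent": tost.equivalent})
        pooled_x.append(x)
        pooled_y.append(y)
    px = np.concatenate(pooled_x)
    py = np.concatenate(pooled_y)
    slope, intercept, r2 = linear_regression(py, px)
    bias, lo, hi = bland_altman_percent(px, py)
    report = AgreementReport(
        parameter=parameter, tissue=pd.DataFrame(t_rows),
        pooled_regression={"slope": slope, "intercept": intercept, "r2": r2},
        bland_altman={"bias_percent": bias, "loa_low": lo, "loa_high": hi})
    if region_means:
        r_rows = []
        for region, methods in region_means.items():
            x = np.asarray(methods[test_method], dtype=float)
            y = np.asarray(methods[reference_method], dtype=float)
            tres = paired_ttest(x, y)
            all_means = [np.asarray(v, dtype=float).mean()
                         for v in methods.values()]
            r_rows.append({
                "region": region,
                "cv_intragroup_test": cv_intragroup(x),
                "cv_intragroup_reference": cv_intragroup(y),
                "cv_intergroup": cv_intergroup(all_means),
                "t": tres.t, "p": tres.p, "degenerate": tres.degenerate})
        report.regions = pd.DataFrame(r_rows)
    if lesion_table is not None:
        report.lesions = lesion_table_compare(lesion_table)
    return report
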