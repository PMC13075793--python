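"""Set-enrichment statistics, count normalization/DE, and growth fitness.

The differential-expression routine is an explicit simplified engine:
median-of-ratios size factors, a method-of-moments negative-binomial
dispersion per feature shrunk toward the across-feature median, and a Wald
test on the log fold change, followed by Benjamini-Hochberg adjustment.  It
trades the full shrinkage machinery of the established DE frameworks for
transparency; its operating characteristics (type-I control, power on
planted changes) are what the test suite asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .synthetic import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    k: int                 # overlap
    size_a: int
    size_b: int
    universe: int
    pvalue: float          # upper tail P(X >= k)
    odds_ratio: float
    or_ci: tuple[float, float]


def hypergeom_overlap(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    a, b = k, K - k
    c, d = n - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(oratio * np.exp(-1.96 * se)), float(oratio * np.exp(1.96 * se)))
    return OverlapResult(k, K, n, N, min(p, 1.0), float(oratio), ci)


def fisher_enrichment(table) -> tuple[float, float]:
    """Two-sided exact Fisher test on a 2x2 table -> (odds ratio, p).

    The reported odds ratio is the sample cross-product, with a Haldane 0.5
    correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c)), float(p)


# ---------------------------------------------------------------------------
# Count normalization / DE


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Only features with nonzero counts in every sample enter the reference
    geometric mean, as in the standard median-of-ratios estimator.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has nonzero counts in all samples")
    logx = np.log(x[positive])
    ref = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_like(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size factor + 1): a declared variance-flattening stand-in."""
    return np.log2(counts.div(factors, axis=1) + 1.0)


def de_test(cm: CountMatrix, condition_a: str = "wt", condition_b: str = "mutant",
            dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Per-feature NB Wald test of condition_b vs condition_a.

    Returns a frame with log2FC, dispersion, p-value and BH-adjusted p-value.
    All-zero features are excluded (logged).  log2FC > 0 means higher in
    condition_b.
    """
    cond = cm.conditions
    cols_a = cond.index[cond == condition_a]
    cols_b = cond.index[cond == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition")

    counts = cm.counts
    nonzero = counts.sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("de_test: excluded %d all-zero features", dropped)
    counts = counts.loc[nonzero]

    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    na, nb = len(cols_a), len(cols_b)
    xa = norm[cols_a].to_numpy(dtype=float)
    xb = norm[cols_b].to_numpy(dtype=float)
    ma = xa.mean(axis=1)
    mb = xb.mean(axis=1)

    # method-of-moments NB dispersion from pooled within-condition residuals,
    # shrunk toward the across-feature median (few replicates make the raw
    # per-feature estimate too noisy to test against)
    var_within = (xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    mean_pooled = (ma * na + mb * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_within - mean_pooled) / mean_pooled**2
    disp = np.where(np.isfinite(disp), disp, dispersion_floor)
    disp = np.maximum(disp, dispersion_floor)
    common = max(float(np.median(disp)), dispersion_floor)
    disp = np.exp(0.5 * np.log(disp) + 0.5 * np.log(common))

    # Wald on log means; NB variance of a normalized-count mean
    inv_sa = float((1.0 / sf[cols_a]).mean())
    inv_sb = float((1.0 / sf[cols_b]).mean())
    eps = 0.5  # continuity guard for a condition with an all-zero mean
    ma_s = np.maximum(ma, eps)
    mb_s = np.maximum(mb, eps)
    var_la = (ma_s * inv_sa + disp * ma_s**2) / na / ma_s**2
    var_lb = (mb_s * inv_sb + disp * mb_s**2) / nb / mb_s**2
    z = (np.log(mb_s) - np.log(ma_s)) / np.sqrt(var_la + var_lb)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")

    return pd.DataFrame(
        {
            "baseMean": mean_pooled,
            "log2FoldChange": np.log2(mb_s / ma_s),
            "dispersion": disp,
            "stat": z,
            "pvalue": pvals,
            "padj": padj,
        },
        index=counts.index,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Growth fitness


@dataclass
class GrowthCurve:
    times: np.ndarray       # hours, strictly increasing
    od: np.ndarray          # optical density, >= 0
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size or self.times.size < 3:
            raise ValueError("need >= 3 matched (time, OD) points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD must be >= 0")


def growth_auc(curve: GrowthCurve, method: str = "trapezoid") -> float:
    """Area under the growth curve in OD x hours.

    ``method="logistic"`` fits K / (1 + ((K - N0)/N0) exp(-r t)) and
    integrates the fit analytically over the observed span.
    """
    if method == "trapezoid":
        return float(np.trapezoid(curve.od, curve.times))
    if method != "logistic":
        raise ValueError(f"unknown method {method!r}")
    from scipy.optimize import curve_fit

    def logistic(t, K, N0, r):
        return K / (1 + (K - N0) / N0 * np.exp(-r * t))

    K0 = max(curve.od.max(), 1e-6)
    N00 = max(curve.od[0], 1e-6)
    (K, N0, r), _ = curve_fit(
        logistic, curve.times, curve.od, p0=[K0, N00, 0.5],
        bounds=([1e-9, 1e-9, 1e-6], [np.inf, np.inf, 100.0]), maxfev=10000,
    )
    t0, t1 = curve.times[0], curve.times[-1]
    c = (K - N0) / N0

    def antider(t):
        return K * t + (K / r) * np.log((1 + c * np.exp(-r * t)) / (1 + c))

    return float(antider(t1) - antider(t0))


def log2auc_relative(mutant_auc: float, wt_auc: float) -> float:
    """log2 of the mutant/WT AUC ratio (matched media and condition)."""
    if mutant_auc <= 0 or wt_auc <= 0:
        raise ValueError("AUCs must be positive")
    return float(np.log2(mutant_auc / wt_auc))
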