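"""Statistical primitives: Welch's t, BH adjustment, log-log regression and
slope comparison, TMM normalization, and a simple two-condition DE caller.

The DE caller filters genes at CPM > 1, TMM-normalizes library sizes
(trimmed mean of M-values, Robinson & Oshlack), then tests each gene with a
Welch two-sample t on log2(CPM + 0.5) and adjusts p-values with
Benjamini-Hochberg. This is a deliberately plain pipeline: no moderated
variance or precision weights; its recovery properties are established on
synthetic data rather than on any particular published gene list.

Two fitted log-log regressions (gene-body nascent-transcription density
against mRNA level) are compared with the normal z statistic

    z = (beta1 - beta2) / sqrt(se1**2 + se2**2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class LogLogFit:
    beta: float
    se_beta: float
    intercept: float
    n: int
    n_excluded: int = 0


@dataclass(frozen=True)
class SlopeComparison:
    beta1: float
    se1: float
    beta2: float
    se2: float
    z: float
    p: float
    degenerate: bool = False


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t test with Welch-Satterthwaite degrees of freedom.

    With both sample variances zero: equal means give t=0, p=1; unequal means
    are an error (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least two observations per sample")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0)
        raise ValueError("both samples have zero variance but unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def bh_adjust(pvals: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (or Bonferroni)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=sm_method)[1]


def loglog_fit(x: Sequence[float], y: Sequence[float]) -> LogLogFit:
    """OLS of log(y) on log(x); non-positive pairs are excluded (logged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("loglog_fit: excluded %d non-positive/non-finite points", n_excluded)
    if ok.sum() < 3:
        raise ValueError("loglog_fit needs at least 3 points with x>0 and y>0")
    res = sps.linregress(np.log(x[ok]), np.log(y[ok]))
    return LogLogFit(
        beta=float(res.slope),
        se_beta=float(res.stderr),
        intercept=float(res.intercept),
        n=int(ok.sum()),
        n_excluded=n_excluded,
    )


def slope_z(fit1: LogLogFit, fit2: LogLogFit) -> SlopeComparison:
    """Compare two regression slopes: z = (b1 - b2)/sqrt(se1^2 + se2^2)."""
    se1, se2 = fit1.se_beta, fit2.se_beta
    if se1 < 0 or se2 < 0:
        raise ValueError("slope standard errors must be non-negative")
    denom = float(np.hypot(se1, se2))
    diff = fit1.beta - fit2.beta
    if denom == 0.0:
        if diff == 0.0:
            return SlopeComparison(fit1.beta, se1, fit2.beta, se2, 0.0, 1.0)
        return SlopeComparison(
            fit1.beta, se1, fit2.beta, se2,
            float(np.inf) if diff > 0 else float(-np.inf), 0.0, degenerate=True,
        )
    z = diff / denom
    p = float(2.0 * sps.norm.sf(abs(z)))
    return SlopeComparison(fit1.beta, se1, fit2.beta, se2, float(z), p)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
        w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_column: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    Doubly trimmed (``trim_M`` on log-ratios, ``trim_A`` on absolute
    intensity), inverse-asymptotic-variance weighted mean of M-values against
    the reference sample. When ``ref_column`` is None the sample whose CPM
    upper quartile is closest to the mean upper quartile is the reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with all-zero counts")
    if ref_column is None:
        uq = np.percentile(mat / lib, 75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_column)
    ref = mat[:, ref_idx]
    f = np.array(
        [_tmm_pair(mat[:, j], ref, trim_M, trim_A) for j in range(mat.shape[1])]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts * 1e6 / lib


def de_call(
    counts: pd.DataFrame,
    design: dict[str, str] | pd.Series | None = None,
    cpm_min: float = 1.0,
    *,
    cond_test: str = "kd",
    cond_ref: str = "control",
    pseudocount: float = 0.5,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Two-condition DE table: logFC, Welch p and adjusted p per gene.

    ``design`` maps sample name -> condition; by default the condition is the
    sample-name prefix before the last underscore. Genes must pass
    CPM > ``cpm_min`` in at least half of the samples. logFC is the difference
    of condition means of log2(TMM-normalized CPM + pseudocount), test minus
    reference.
    """
    if design is None:
        design = {c: c.rsplit("_", 1)[0] for c in counts.columns}
    design = pd.Series(design)
    for cond in (cond_test, cond_ref):
        if (design == cond).sum() < 2:
            raise ValueError(f"need >= 2 replicates for condition {cond!r}")

    keep = (cpm(counts) > cpm_min).sum(axis=1) >= counts.shape[1] / 2
    filtered = counts.loc[keep]
    logger.info("de_call: %d of %d genes pass CPM > %g", keep.sum(), len(counts), cpm_min)
    if filtered.empty:
        raise ValueError("no genes pass the CPM filter")

    factors = tmm_factors(filtered)
    eff_lib = filtered.sum(axis=0) * factors
    logcpm = np.log2(cpm(filtered, eff_lib) + pseudocount)

    a = logcpm.loc[:, design[logcpm.columns] == cond_test].to_numpy()
    b = logcpm.loc[:, design[logcpm.columns] == cond_ref].to_numpy()
    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame(
        {
            "gene_id": filtered.index,
            f"mean_log2cpm_{cond_test}": a.mean(axis=1),
            f"mean_log2cpm_{cond_ref}": b.mean(axis=1),
            "logfc": a.mean(axis=1) - b.mean(axis=1),
            "pvalue": pvals,
            "padj": bh_adjust(pvals, method=adjust),
        }
    ).set_index("gene_id", drop=False)
    out.attrs["pseudocount"] = pseudocount
    out.attrs["cpm_min"] = cpm_min
    return out
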