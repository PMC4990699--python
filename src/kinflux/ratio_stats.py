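"""Replicate aggregation, significance testing and local FDR for
phosphopeptide log2 ratios.

A site enters the analysis only when it was detected in at least two of
the replicates of a contrast; singly detected sites are discarded, never
imputed.  Each aggregated ratio is tested against zero with a one-sample
t-test, the t statistics are mapped to signed z scores, and a local
false discovery rate is attached via an empirical-Bayes two-group model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinflux.io_formats import RatioTable

log = logging.getLogger(__name__)

#: |log2 ratio| cutoff for dysregulation calls
DEFAULT_ABS_LOG2_CUTOFF = 0.58
#: local-FDR ceiling for dysregulation calls
DEFAULT_FDR_CUTOFF = 0.1


@dataclass(frozen=True)
class ExperimentStats:
    """Population mean and standard deviation of all aggregated mean
    log2 ratios in one contrast (the reference distribution for the
    KSEA z test).  ``s`` is the population (divide-by-N) form.
    """

    mu: float
    s: float
    n_total: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    zero_variance: bool = False


def aggregate_replicates(table: RatioTable) -> RatioTable:
    """Attach per-contrast observation counts and mean log2 ratios.

    The mean is the arithmetic mean of the observed replicates and is
    defined only for sites observed in >= 2 replicates; sites observed
    once get no mean and drop out of all downstream statistics.
    Returns a new table; the input is not modified.
    """
    df = table.df.copy()
    for contrast in table.contrasts:
        reps = df[table.replicate_cols(contrast)]
        n_obs = reps.notna().sum(axis=1)
        mean = reps.mean(axis=1)
        mean[n_obs < 2] = np.nan
        df[f"{contrast}_n"] = n_obs
        df[f"{contrast}_mean"] = mean
    return RatioTable(df=df, contrasts=table.contrasts, n_replicates=table.n_replicates)


def test_ratio_vs_zero(replicates) -> TTestResult:
    """Two-sided one-sample t-test of H0: mean log2 ratio = 0.

    Requires >= 2 finite replicates.  With zero sample variance and a
    nonzero mean the p-value degenerates to 0; the smallest positive
    float is reported with ``zero_variance`` flagged.
    """
    x = np.asarray([v for v in np.atleast_1d(replicates) if np.isfinite(v)], dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"t-test undefined for {n} replicate(s); need >= 2")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, zero_variance=True)
        t = np.inf if mean > 0 else -np.inf
        return TTestResult(t=t, p=np.nextafter(0.0, 1.0), zero_variance=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(min(p, 1.0)))


def z_from_pvalues(p, sign) -> np.ndarray:
    """Map two-sided p-values and effect signs to signed N(0,1) scores."""
    # floor keeps isf finite for degenerate (zero-variance) p-values
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0)
    return np.sign(sign) * stats.norm.isf(p / 2.0)


def estimate_local_fdr(z) -> np.ndarray:
    """Local false discovery rate for a vector of z scores.

    Empirical-Bayes two-group estimate: the mixture density f(z) is
    estimated with a Gaussian kernel, the null f0 is the theoretical
    standard normal, and pi0 is estimated from the count in the central
    region |z| <= 1.  fdr(z) = pi0 * f0(z) / f(z), capped at 1 and
    monotonized to be non-increasing in |z| within each sign tail.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n < 50:
        warnings.warn(
            f"local FDR estimated from only {n} values; unstable below 50",
            stacklevel=2,
        )
    if n == 0:
        return np.array([])
    if np.ptp(z) == 0.0:
        warnings.warn("all z values identical; local FDR set to 1", stacklevel=2)
        return np.ones(n)

    kde = stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    f0 = stats.norm.pdf(z)
    central = stats.norm.cdf(1) - stats.norm.cdf(-1)
    pi0 = min(1.0, np.mean(np.abs(z) <= 1.0) / central)
    fdr = np.clip(pi0 * f0 / f, 0.0, 1.0)

    # enforce monotone non-increasing fdr in |z|, per tail (PAVA)
    out = fdr.copy()
    for mask in (z >= 0, z < 0):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        order = idx[np.argsort(np.abs(z[idx]), kind="stable")]
        out[order] = _pava_nonincreasing(out[order])
    return out


def _pava_nonincreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-increasing sequence."""
    # fit non-decreasing on the negated series, then negate back
    vals = list(-y)
    weights = [1.0] * len(vals)
    means: list[float] = []
    counts: list[int] = []
    for v, w in zip(vals, weights):
        means.append(v)
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, c2 = means.pop(), counts.pop()
            m1, c1 = means.pop(), counts.pop()
            means.append((m1 * c1 + m2 * c2) / (c1 + c2))
            counts.append(c1 + c2)
    fitted = np.repeat(means, counts)
    return -fitted


def add_site_statistics(table: RatioTable) -> RatioTable:
    """Aggregate, t-test and local-FDR every contrast of a ratio table.

    Adds columns ``<c>_n/_mean/_t/_p/_lfdr``.  Sites without an
    aggregated mean get NaN statistics.
    """
    table = aggregate_replicates(table)
    df = table.df
    for contrast in table.contrasts:
        reps = df[table.replicate_cols(contrast)].to_numpy(dtype=float)
        has_mean = df[f"{contrast}_mean"].notna().to_numpy()
        n_obs = np.sum(~np.isnan(reps), axis=1)
        mean = df[f"{contrast}_mean"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.full(len(df), np.nan)
            sd[has_mean] = np.nanstd(reps[has_mean], axis=1, ddof=1)
            t_vals = mean / (sd / np.sqrt(n_obs))
            p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df=np.maximum(n_obs - 1, 1))
        # degenerate rows: zero variance
        zero_var = has_mean & (sd == 0)
        t_vals[zero_var & (mean == 0)] = 0.0
        p_vals[zero_var & (mean == 0)] = 1.0
        t_vals[zero_var & (mean > 0)] = np.inf
        t_vals[zero_var & (mean < 0)] = -np.inf
        p_vals[zero_var & (mean != 0)] = np.nextafter(0.0, 1.0)
        t_vals[~has_mean] = np.nan
        p_vals[~has_mean] = np.nan
        df[f"{contrast}_t"] = t_vals
        df[f"{contrast}_p"] = p_vals
        lfdr = np.full(len(df), np.nan)
        if has_mean.any():
            z = z_from_pvalues(p_vals[has_mean], np.sign(t_vals[has_mean]))
            lfdr[has_mean] = estimate_local_fdr(z)
        df[f"{contrast}_lfdr"] = lfdr
    return table


def call_dysregulated(
    table: RatioTable,
    contrast: str,
    abs_log2_cutoff: float = DEFAULT_ABS_LOG2_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> pd.DataFrame:
    """Label each aggregated site up / down / unchanged.

    A site is ``up`` when its mean log2 ratio exceeds +cutoff and its
    local FDR is <= the FDR cutoff; ``down`` symmetrically.  Sites
    without an aggregated mean are excluded.  The result is invariant
    to row order and idempotent.
    """
    df = table.df
    mean = df[f"{contrast}_mean"]
    lfdr = df[f"{contrast}_lfdr"]
    keep = mean.notna()
    label = pd.Series("unchanged", index=df.index[keep], dtype=object)
    up = (mean[keep] > abs_log2_cutoff) & (lfdr[keep] <= fdr_cutoff)
    down = (mean[keep] < -abs_log2_cutoff) & (lfdr[keep] <= fdr_cutoff)
    label[up] = "up"
    label[down] = "down"
    out = pd.DataFrame(
        {
            "protein": df.loc[keep, "protein"],
            "position": df.loc[keep, "position"],
            "mean": mean[keep],
            "lfdr": lfdr[keep],
            "label": label,
        }
    ).reset_index(drop=True)
    out.attrs["abs_log2_cutoff"] = abs_log2_cutoff
    out.attrs["fdr_cutoff"] = fdr_cutoff
    return out


def compute_experiment_stats(table: RatioTable, contrast: str) -> ExperimentStats:
    """Population mean/SD of all aggregated mean log2 ratios in a contrast."""
    means = table.df[f"{contrast}_mean"].dropna().to_numpy(dtype=float)
    if len(means) < 2:
        raise ValueError(
            f"need >= 2 aggregated sites to compute experiment statistics, "
            f"got {len(means)}"
        )
    return ExperimentStats(
        mu=float(means.mean()), s=float(means.std(ddof=0)), n_total=len(means)
    )
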