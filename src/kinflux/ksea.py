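"""Kinase-substrate enrichment analysis (KSEA).

Each kinase's detected, aggregated substrates form a substrate group
(default floor: 10 members).  Two complementary statistics are computed
per group:

* the fractional delta-count, fcount = (N_I - N_D) / (N_I + N_D),
  where N_I and N_D count members with positive and negative mean log2
  ratio, with a one-sided hypergeometric test for the significance of
  obtaining N_I (and, symmetrically, N_D) against the background
  composition of all aggregated sites; and
* a z test of the group mean log2 ratio against the experiment-wide
  population mean, z = (x_bar - mu) / (s / sqrt(N)), with
  p = 2 * Phi(-|z|).

Both p-value families are Benjamini-Hochberg corrected, independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from kinflux.io_formats import KinaseSubstrateMap, RatioTable
from kinflux.ratio_stats import ExperimentStats

log = logging.getLogger(__name__)

DEFAULT_MIN_GROUP_SIZE = 10


@dataclass
class SubstrateGroup:
    """A kinase's detected substrates with their aggregated log2 ratios."""

    kinase: str
    members: list[tuple[str, int]]
    ratios: np.ndarray

    @property
    def N(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HypergeomResult:
    """One-sided tail probabilities for the increased and decreased
    counts, and the reported minimum of the two."""

    p_increased: float
    p_decreased: float
    p: float


def build_substrate_groups(
    kmap: KinaseSubstrateMap,
    table: RatioTable,
    contrast: str,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[SubstrateGroup]:
    """Intersect the kinase map with detected, aggregated sites.

    A site may belong to several groups.  Map entries whose residue
    disagrees with the ratio table at the same (protein, position) key
    are logged and dropped.  Groups below ``min_size`` detected members
    are omitted.  Returned sorted by kinase symbol.
    """
    df = table.df
    detected = df[df[f"{contrast}_mean"].notna()]
    site_info = {
        (p, int(pos)): (res, float(m))
        for p, pos, res, m in zip(
            detected["protein"],
            detected["position"],
            detected["residue"],
            detected[f"{contrast}_mean"],
        )
    }
    groups: list[SubstrateGroup] = []
    for kinase, sub in kmap.df.groupby("kinase", sort=True):
        members: list[tuple[str, int]] = []
        ratios: list[float] = []
        for prot, pos, res in zip(sub["protein"], sub["position"], sub["residue"]):
            key = (prot, int(pos))
            if key not in site_info:
                continue
            table_res, mean = site_info[key]
            if res and res != table_res:
                log.warning(
                    "residue mismatch for %s:%s (map %s vs table %s); "
                    "dropping map entry",
                    prot, pos, res, table_res,
                )
                continue
            members.append(key)
            ratios.append(mean)
        if len(members) >= min_size:
            groups.append(
                SubstrateGroup(kinase=kinase, members=members, ratios=np.array(ratios))
            )
    if not groups:
        log.warning("no substrate group met the size floor of %d", min_size)
    return groups


def compute_fcount(ratios) -> float:
    """Fractional delta-count (N_I - N_D)/(N_I + N_D).

    Members with ratio exactly 0 count in neither tally; when no member
    has a nonzero ratio the fcount is undefined and NaN is returned.
    """
    r = np.asarray(ratios, dtype=float)
    n_i = int(np.sum(r > 0))
    n_d = int(np.sum(r < 0))
    if n_i + n_d == 0:
        return float("nan")
    return (n_i - n_d) / (n_i + n_d)


def hypergeom_enrichment(group_ratios, background_ratios) -> HypergeomResult:
    """Hypergeometric significance of the group's sign composition.

    The group's signed members (n = N_I + N_D draws) are compared with
    the background of all aggregated sites (size M, of which K have
    positive and K' negative ratios).  Both one-sided upper tails
    P(X >= N_I) and P(X >= N_D) are computed; the reported p is the
    smaller of the two.
    """
    grp = np.asarray(group_ratios, dtype=float)
    bg = np.asarray(background_ratios, dtype=float)
    if len(grp) > len(bg):
        raise ValueError("substrate group larger than background")
    n_i = int(np.sum(grp > 0))
    n_d = int(np.sum(grp < 0))
    n = n_i + n_d
    M = len(bg)
    K_inc = int(np.sum(bg > 0))
    K_dec = int(np.sum(bg < 0))
    p_inc = float(min(1.0, stats.hypergeom.sf(n_i - 1, M, K_inc, n)))
    p_dec = float(min(1.0, stats.hypergeom.sf(n_d - 1, M, K_dec, n)))
    return HypergeomResult(p_increased=p_inc, p_decreased=p_dec, p=min(p_inc, p_dec))


def ztest_group_mean(
    group_mean: float, exp_stats: ExperimentStats, n: int
) -> tuple[float, float]:
    """z = (x_bar - mu)/(s/sqrt(N)); two-sided p = 2*Phi(-|z|)."""
    if exp_stats.s <= 0:
        raise ValueError("population standard deviation must be positive")
    if n < 1:
        raise ValueError("group must have at least one member")
    z = (group_mean - exp_stats.mu) / (exp_stats.s / np.sqrt(n))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ksea(
    kmap: KinaseSubstrateMap,
    table: RatioTable,
    exp_stats: ExperimentStats,
    contrast: str,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Full KSEA for one contrast.

    Returns one row per qualifying substrate group, ordered by kinase
    symbol, with counts, fcount, the hypergeometric and z-test p-values
    and their (independently) BH-corrected q-values.
    """
    groups = build_substrate_groups(kmap, table, contrast, min_size=min_size)
    background = table.df[f"{contrast}_mean"].dropna().to_numpy(dtype=float)
    return ksea_from_groups(groups, background, exp_stats)


def ksea_from_groups(
    groups: list[SubstrateGroup],
    background: np.ndarray,
    exp_stats: ExperimentStats,
    label: str = "kinase",
) -> pd.DataFrame:
    """KSEA statistics for pre-built groups (kinase or motif)."""
    rows = []
    for g in groups:
        hyper = hypergeom_enrichment(g.ratios, background)
        x_bar = float(np.mean(g.ratios))
        z, p_z = ztest_group_mean(x_bar, exp_stats, g.N)
        rows.append(
            {
                label: g.kinase,
                "N": g.N,
                "N_I": int(np.sum(g.ratios > 0)),
                "N_D": int(np.sum(g.ratios < 0)),
                "fcount": compute_fcount(g.ratios),
                "p_hyper_inc": hyper.p_increased,
                "p_hyper_dec": hyper.p_decreased,
                "p_hyper": hyper.p,
                "group_mean": x_bar,
                "z": z,
                "p_z": p_z,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            label, "N", "N_I", "N_D", "fcount", "p_hyper_inc", "p_hyper_dec",
            "p_hyper", "group_mean", "z", "p_z",
        ],
    )
    if len(result):
        result["q_hyper"] = adjust_bh(result["p_hyper"])
        result["q_z"] = adjust_bh(result["p_z"])
    else:
        result["q_hyper"] = []
        result["q_z"] = []
    return result.sort_values(label, ignore_index=True)
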