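"""Probe-set filtering, fold-change calls, and KS gene-set enrichment.

The expression branch starts from a summarized log2 probe matrix (array
normalization and probe summarization are upstream, out of scope).
Probes are filtered by four exclusion rules, genes are called
dysregulated at fold change > 1.5, a patient cohort is ranked by the
difference in median expression between two groups, and a gene set is
tested for enrichment at one end of the ranking with a classic
unweighted KS running-sum enrichment score; the p-value comes from the
two-sample KS test on in-set vs out-of-set rank distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinflux.io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_EXPR_FLOOR = 5.0
DEFAULT_FC_THRESHOLD = 1.5

FILTER_RULES = (
    "low_expression",      # (i)  mean log2 expression < floor in both groups
    "multiple_genes",      # (ii) probe associated with several gene symbols
    "no_gene",             # (iii) probe with no gene symbol
    "gene_multi_probe",    # (iv) gene symbol mapped by several probe sets
)


@dataclass
class EnrichmentResult:
    """Signed running-sum enrichment outcome for one gene set."""

    ES: float
    p: float
    set_size: int
    ranking_size: int
    leading_edge: list[str]


def filter_probesets(
    matrix: ExpressionMatrix, expr_floor: float = DEFAULT_EXPR_FLOOR
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Apply the four probe exclusion rules; report per-rule counts.

    Rules, applied in order with each excluded probe attributed to the
    first rule it fails: (i) mean log2 expression below the floor in
    both sample groups; (ii) several gene symbols; (iii) no gene
    symbol; (iv) gene symbol shared by several surviving probe sets.
    Rule (iv) multiplicity is assessed among probes passing (i)-(iii).
    Idempotent and invariant to probe order.
    """
    groups = matrix.require_groups()
    labels = sorted(set(groups[matrix.values.columns]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two sample groups, got {labels}")
    cols_a = [s for s in matrix.values.columns if groups[s] == labels[0]]
    cols_b = [s for s in matrix.values.columns if groups[s] == labels[1]]

    counts = {rule: 0 for rule in FILTER_RULES}
    mean_a = matrix.values[cols_a].mean(axis=1)
    mean_b = matrix.values[cols_b].mean(axis=1)
    surviving = []
    for probe in matrix.values.index:
        genes = matrix.probe_genes.get(probe, [])
        if mean_a[probe] < expr_floor and mean_b[probe] < expr_floor:
            counts["low_expression"] += 1
        elif len(set(genes)) > 1:
            counts["multiple_genes"] += 1
        elif len(genes) == 0:
            counts["no_gene"] += 1
        else:
            surviving.append(probe)

    gene_of = {p: matrix.probe_genes[p][0] for p in surviving}
    gene_counts = pd.Series(list(gene_of.values())).value_counts()
    final = [p for p in surviving if gene_counts[gene_of[p]] == 1]
    counts["gene_multi_probe"] = len(surviving) - len(final)

    filtered = ExpressionMatrix(
        values=matrix.values.loc[final],
        probe_genes={p: matrix.probe_genes[p] for p in final},
        groups=matrix.groups,
    )
    log.info(
        "probe filter: %d -> %d survivors (%s)",
        len(matrix.values), len(final), counts,
    )
    return filtered, counts


def call_fold_change(
    log2_ratios: pd.Series | dict, threshold: float = DEFAULT_FC_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Up/down gene sets at linear fold change strictly > threshold.

    Input is log2 ratios; up means log2 ratio > log2(threshold), down
    means log2 ratio < -log2(threshold).  A gene at the threshold
    exactly is unchanged.
    """
    if threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    s = pd.Series(log2_ratios, dtype=float)
    cut = np.log2(threshold)
    up = sorted(s.index[s > cut])
    down = sorted(s.index[s < -cut])
    return up, down


def rank_by_median_diff(
    matrix: ExpressionMatrix, group1: str, group2: str
) -> pd.DataFrame:
    """Rank genes by median(group1) - median(group2), descending.

    Assumes a filtered matrix with a 1:1 probe->gene mapping.  Genes
    with all-missing values in either group are excluded with a
    warning; ties break by gene symbol.  Output columns: gene,
    statistic, rank.
    """
    groups = matrix.require_groups()
    cols1 = [s for s in matrix.values.columns if groups[s] == group1]
    cols2 = [s for s in matrix.values.columns if groups[s] == group2]
    if not cols1 or not cols2:
        raise ValueError("each group needs at least one sample")
    med1 = matrix.values[cols1].median(axis=1)
    med2 = matrix.values[cols2].median(axis=1)
    genes = pd.Series(
        {p: (g[0] if (g := matrix.probe_genes.get(p, [])) else p)
         for p in matrix.values.index}
    )
    valid = med1.notna() & med2.notna()
    for gene in genes[~valid]:
        log.warning("gene %s has no values in one group; excluded", gene)
    ranked = pd.DataFrame(
        {"gene": genes[valid], "statistic": (med1 - med2)[valid]}
    ).sort_values(
        ["statistic", "gene"], ascending=[False, True], ignore_index=True
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked.attrs["direction"] = f"{group1}-high-first"
    return ranked


def gsea_es(
    ranked: pd.DataFrame, gene_set, weighted: bool = False
) -> EnrichmentResult:
    """Classic KS running-sum enrichment of a gene set in a ranking.

    Walking the ranking from the top, the running sum gains
    1/|set ∩ ranking| at each set member and loses 1/(n - |set ∩
    ranking|) at each non-member; ES is the signed maximum deviation.
    The p-value is the two-sample KS test comparing the rank
    distributions of in-set and out-of-set genes.  The leading edge is
    the set members at or before (ES > 0) / at or after (ES < 0) the
    extremum.  ``weighted=True`` weights hit increments by |statistic|
    (offered for comparison only).
    """
    genes = ranked["gene"].to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n = len(genes)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranking; ES undefined")

    if weighted:
        w = np.abs(ranked["statistic"].to_numpy(dtype=float))
        w = np.where(w == 0, np.finfo(float).tiny, w)
        hit_inc = np.where(in_set, w, 0.0)
        hit_inc = hit_inc / hit_inc.sum()
    else:
        hit_inc = np.where(in_set, 1.0 / n_hit, 0.0)
    miss_dec = np.where(~in_set, 1.0 / (n - n_hit), 0.0)
    running = np.cumsum(hit_inc - miss_dec)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])

    ranks = ranked["rank"].to_numpy(dtype=float)
    ks = stats.ks_2samp(ranks[in_set], ranks[~in_set])

    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], in_set[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], in_set[i_ext:]) if h]
    return EnrichmentResult(
        ES=es, p=float(ks.pvalue), set_size=n_hit, ranking_size=n,
        leading_edge=leading,
    )
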