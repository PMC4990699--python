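"""miRNA seed-match rank enrichment in 3'UTRs and candidate selection.

Genes are ranked by log2 fold change in expression after miRNA
induction (most downregulated first).  Each gene's longest 3'UTR is
scanned — sense strand only, as UTRs are mRNA sequence — for exact
occurrences of the 7-mer complementary to the miRNA seed (default
``CTATAGT``, the miR-625-3p target motif).  The rank distributions of
seed-containing and seed-free genes are compared with a two-sample
Kolmogorov-Smirnov test; candidate targets are the most downregulated
seed-containing genes with a target-prediction score above a floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinflux.io_formats import SequenceSet

log = logging.getLogger(__name__)

DEFAULT_SEED_MOTIF = "CTATAGT"
DEFAULT_SCORE_THRESHOLD = 75.0
DEFAULT_TOP_N = 8
NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class UTRRecord:
    gene: str
    utr: str

    @property
    def length(self) -> int:
        return len(self.utr)


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    method: str  # "exact" or "asymptotic"
    n_motif: int
    n_other: int


def select_longest_utr(seqs: SequenceSet) -> list[UTRRecord]:
    """One UTR per gene symbol: the longest isoform.

    The gene symbol is the FASTA id up to the first ``|`` (so isoform
    ids like ``MAP2K6|201`` collapse onto one gene).  U is mapped to T
    first; records still containing non-ACGT characters are dropped
    with a warning.  Length ties keep the lexicographically smaller
    sequence (deterministic, logged).
    """
    best: dict[str, str] = {}
    for rec_id, seq in seqs.items():
        gene = rec_id.split("|", 1)[0]
        seq = seq.upper().replace("U", "T")
        if not set(seq) <= NUCLEOTIDES:
            log.warning("UTR for %s contains non-ACGT characters; dropped", gene)
            continue
        cur = best.get(gene)
        if cur is None or len(seq) > len(cur):
            best[gene] = seq
        elif len(seq) == len(cur) and seq < cur:
            log.info("equal-length UTRs for %s; keeping lexicographically smaller", gene)
            best[gene] = seq
    return [UTRRecord(gene=g, utr=u) for g, u in best.items()]


def scan_seed(utr: str, motif: str = DEFAULT_SEED_MOTIF) -> list[int]:
    """1-based offsets of every (possibly overlapping) exact motif match."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if not set(motif) <= NUCLEOTIDES:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    hits = []
    start = utr.find(motif)
    while start != -1:
        hits.append(start + 1)
        start = utr.find(motif, start + 1)
    return hits


def rank_by_fold_change(ratios: pd.Series | dict) -> pd.DataFrame:
    """Rank genes ascending by log2 ratio: most downregulated first.

    Ties break by gene symbol; duplicate genes are an error.  Output
    columns: gene, statistic, rank (1..n); row order is the ranking.
    """
    s = pd.Series(ratios, dtype=float)
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()].unique()
        raise ValueError(f"duplicate genes in ratio table: {list(dup)[:5]}")
    ordered = s.reset_index()
    ordered.columns = ["gene", "statistic"]
    ordered = ordered.sort_values(
        ["statistic", "gene"], ascending=[True, True], ignore_index=True
    )
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    ordered.attrs["direction"] = "most-downregulated-first"
    return ordered


def flag_seed_genes(
    ranked: pd.DataFrame, utrs: list[UTRRecord], motif: str = DEFAULT_SEED_MOTIF
) -> pd.DataFrame:
    """Attach ``has_motif`` and ``n_matches`` columns to a ranking."""
    counts = {r.gene: len(scan_seed(r.utr, motif)) for r in utrs}
    out = ranked.copy()
    out["n_matches"] = out["gene"].map(counts).fillna(0).astype(int)
    out["has_motif"] = out["n_matches"] > 0
    return out


def seed_rank_ks(ranked: pd.DataFrame, exact_limit: int = 10) -> KSResult:
    """Two-sample KS test on the ranks of motif vs non-motif genes.

    The p-value is exact (conditional distribution of D given the
    class sizes) when the smaller class has <= ``exact_limit`` members
    or n*m <= 1e6, and asymptotic beyond that; the method used is
    recorded in the result.
    """
    motif_ranks = ranked.loc[ranked["has_motif"], "rank"].to_numpy(dtype=float)
    other_ranks = ranked.loc[~ranked["has_motif"], "rank"].to_numpy(dtype=float)
    n, m = len(motif_ranks), len(other_ranks)
    if n == 0 or m == 0:
        raise ValueError("both motif and non-motif classes must be non-empty")
    method = "exact" if (min(n, m) <= exact_limit or n * m <= 1_000_000) else "asymp"
    res = stats.ks_2samp(motif_ranks, other_ranks, method=method)
    return KSResult(
        D=float(res.statistic), p=float(res.pvalue),
        method={"asymp": "asymptotic"}.get(method, method),
        n_motif=n, n_other=m,
    )


def seed_rank_ks_uniform(ranked: pd.DataFrame) -> KSResult:
    """One-sample alternative: motif-gene ranks against uniform on [1, n]."""
    motif_ranks = ranked.loc[ranked["has_motif"], "rank"].to_numpy(dtype=float)
    if len(motif_ranks) == 0:
        raise ValueError("no motif genes in the ranking")
    n_total = len(ranked)
    res = stats.kstest(motif_ranks, stats.uniform(loc=1, scale=n_total - 1).cdf)
    return KSResult(
        D=float(res.statistic), p=float(res.pvalue), method="one-sample",
        n_motif=len(motif_ranks), n_other=n_total - len(motif_ranks),
    )


def select_candidates(
    ranked: pd.DataFrame,
    scores: pd.Series | dict,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    top_n: int = DEFAULT_TOP_N,
) -> pd.DataFrame:
    """The ``top_n`` most downregulated motif genes scoring above the
    prediction-score floor (strict inequality).  Returns fewer rows
    with a warning when fewer qualify."""
    s = pd.Series(scores, dtype=float)
    sub = ranked[ranked["has_motif"]].copy()
    sub["score"] = sub["gene"].map(s)
    qual = sub[sub["score"] > score_threshold].sort_values(
        ["statistic", "gene"], ignore_index=True
    )
    if len(qual) < top_n:
        log.warning(
            "only %d genes pass has_motif & score > %s (requested %d)",
            len(qual), score_threshold, top_n,
        )
    return qual.head(top_n).reset_index(drop=True)
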