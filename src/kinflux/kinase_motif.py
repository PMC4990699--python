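"""Kinase-motif association on NetworKIN-style prediction tables.

High-confidence kinase->substrate mappings (networkin_score strictly
greater than 3 by default) carry an 11-residue phosphorylation window.
For a motif m and kinase k the enrichment score is

    ES_{m,k} = (n_mk / N_m) / (N_k / N)

where n_mk counts mappings of k whose window matches m, N_m all
mappings matching m, N_k all mappings of k and N all mappings; ES = 1
under independence.  Significance is a two-sided Fisher exact test on
the mapping-level 2x2 table, BH-corrected jointly across all
(motif, kinase) pairs; per motif the top kinases by smallest p with
n_mk above a floor are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinflux.ksea import adjust_bh
from kinflux.motifs import MotifPattern, match_motif

log = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 3.0
DEFAULT_MIN_N = 100
DEFAULT_TOP_K = 10


@dataclass
class AssociationResult:
    """Full score table, the per-motif top-k selection, and the number
    of distinct kinases across all selections."""

    scores: pd.DataFrame
    selection: pd.DataFrame
    distinct_kinases: int


def filter_networkin(records: pd.DataFrame, min_score: float = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Keep records with networkin_score strictly greater than the floor."""
    kept = records[records["networkin_score"] > min_score].reset_index(drop=True)
    log.info("networkin filter: kept %d of %d records", len(kept), len(records))
    return kept


def simplify_motif_11(pattern15: MotifPattern) -> MotifPattern | None:
    """Trim a 15-residue (7+1+7) motif to 11 residues (5+1+5).

    Returns the trimmed pattern, or None (with a log line) when a
    residue constraint lies in the trimmed flanks — such motifs need
    more than a 5+1+5 format and are removed from the association
    analysis.
    """
    if len(pattern15) != 15:
        raise ValueError(f"expected a 15-residue pattern, got {len(pattern15)}")
    outside = [i for i in pattern15.literal_positions() if i < 2 or i > 12]
    if outside:
        log.info(
            "motif %r dropped: constrained positions %s fall outside the "
            "central 11 residues", pattern15.text, [i + 1 for i in outside],
        )
        return None
    tokens = pattern15.tokens[2:13]
    text = "".join(
        "." if t is None else (next(iter(t)) if len(t) == 1 else "[" + "".join(sorted(t)) + "]")
        for t in tokens
    )
    return MotifPattern(text=text, tokens=tokens)


def compute_es(n_mk: int, N_m: int, N_k: int, N: int) -> float:
    """ES_{m,k} = (n_mk/N_m) / (N_k/N); equals 1 under independence."""
    if N_m <= 0 or N_k <= 0 or N <= 0:
        raise ValueError("N_m, N_k and N must be positive")
    return (n_mk / N_m) / (N_k / N)


def associate_kinases(
    motifs: list[MotifPattern],
    records: pd.DataFrame,
    top_k: int = DEFAULT_TOP_K,
    min_n: int = DEFAULT_MIN_N,
) -> AssociationResult:
    """Score every (motif, kinase) pair over filtered mapping records.

    Windows in ``records`` must be 11-mers.  Fisher's exact test is
    two-sided on [[n_mk, N_m-n_mk], [N_k-n_mk, N-N_m-N_k+n_mk]];
    q-values are BH over all pairs jointly; the per-motif selection
    takes the ``top_k`` smallest p subject to n_mk >= ``min_n``.
    Motifs matching no mapping are excluded with a warning.
    """
    N = len(records)
    if N == 0:
        empty = pd.DataFrame(
            columns=["motif", "kinase", "n_mk", "N_m", "N_k", "N", "ES", "p", "q"]
        )
        return AssociationResult(scores=empty, selection=empty, distinct_kinases=0)

    windows = records["window11"].to_numpy()
    kinases = records["kinase"].to_numpy()
    kinase_levels = sorted(set(kinases))
    n_k = {k: int(np.sum(kinases == k)) for k in kinase_levels}

    rows = []
    for pat in motifs:
        if len(pat) != 11:
            raise ValueError(f"motif {pat.text!r} is not an 11-mer")
        hits = np.fromiter(
            (match_motif(w, pat) for w in windows), dtype=bool, count=N
        )
        N_m = int(hits.sum())
        if N_m == 0:
            log.warning("motif %r matches no mapping; excluded", pat.text)
            continue
        for k in kinase_levels:
            n_mk = int(np.sum(hits & (kinases == k)))
            N_k = n_k[k]
            table = np.array(
                [[n_mk, N_m - n_mk], [N_k - n_mk, N - N_m - N_k + n_mk]]
            )
            _, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "motif": pat.text, "kinase": k, "n_mk": n_mk, "N_m": N_m,
                    "N_k": N_k, "N": N, "ES": compute_es(n_mk, N_m, N_k, N),
                    "p": float(p),
                }
            )
    scores = pd.DataFrame(rows)
    if len(scores):
        scores["q"] = adjust_bh(scores["p"].clip(lower=np.nextafter(0.0, 1.0)))
    else:
        scores["q"] = []

    selected = []
    for motif, sub in scores.groupby("motif", sort=True):
        ok = sub[sub["n_mk"] >= min_n].nsmallest(top_k, "p", keep="first")
        selected.append(ok)
    selection = (
        pd.concat(selected, ignore_index=True)
        if selected
        else scores.iloc[0:0]
    )
    distinct = selection["kinase"].nunique() if len(selection) else 0
    return AssociationResult(
        scores=scores.reset_index(drop=True),
        selection=selection,
        distinct_kinases=int(distinct),
    )
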