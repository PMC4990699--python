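"""Sequence-context analysis of phosphosites.

Extracts fixed 7+1+7 windows around phosphorylated S/T/Y residues
(sites within seven residues of a protein terminus are flagged and
discarded from motif work), matches positional motif patterns, builds
motif groups for KSEA, and performs the pS/pTQ (ATM/ATR consensus)
analysis: sequence-logo counts and a Fisher exact test on dysregulated
counts.

Pattern syntax: a fixed-width string, one token per position, where a
token is ``.`` (wildcard), a literal residue, or a bracket class such
as ``[ST]``.  The centre position must be S, T or the S/T class.
Ambiguous residues (B, Z, X) in a window match only wildcards.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinflux.io_formats import NEAR_TERMINUS, RatioTable
from kinflux.ksea import SubstrateGroup, ksea_from_groups
from kinflux.ratio_stats import ExperimentStats

log = logging.getLogger(__name__)

DEFAULT_MIN_OCCURRENCE = 50
AMBIGUOUS = frozenset("BZX")

_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|(.)")


@dataclass(frozen=True)
class MotifPattern:
    """Positional phospho-motif over a fixed-length window.

    ``tokens`` holds one frozenset of allowed residues per position,
    with None meaning wildcard.  Length must be odd (15 or 11 in this
    pipeline) and the centre must allow only S and/or T.
    """

    text: str
    tokens: tuple[frozenset | None, ...]

    def __post_init__(self):
        n = len(self.tokens)
        if n % 2 == 0:
            raise ValueError(f"pattern {self.text!r} has even length {n}")
        centre = self.tokens[n // 2]
        if centre is None or not centre <= {"S", "T"}:
            raise ValueError(
                f"pattern {self.text!r} centre must be S, T or [ST]"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def centre_index(self) -> int:
        return len(self.tokens) // 2

    def literal_positions(self) -> list[int]:
        """0-based positions carrying a residue constraint."""
        return [i for i, t in enumerate(self.tokens) if t is not None]


def parse_pattern(text: str) -> MotifPattern:
    """Parse a fixed-width motif string like ``.......SP.....`` or
    ``......[ST]P....K`` into a :class:`MotifPattern`."""
    tokens: list[frozenset | None] = []
    for m in _TOKEN_RE.finditer(text.strip()):
        if m.group(1) is not None:
            tokens.append(frozenset(m.group(1)))
        else:
            ch = m.group(2)
            tokens.append(None if ch == "." else frozenset(ch.upper()))
    return MotifPattern(text=text.strip(), tokens=tuple(tokens))


def read_patterns(path) -> list[MotifPattern]:
    """Read a motif file: one pattern per line, ``#`` comments."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                patterns.append(parse_pattern(line))
    return patterns


def extract_window(sequence: str, position: int, flank: int = 7) -> str:
    """The (2*flank+1)-residue window centred on a 1-based position.

    Sites within ``flank`` residues of either terminus cannot provide a
    full window and return the ``near-terminus`` sentinel; positions
    outside the sequence are an error.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    lo = position - flank
    hi = position + flank
    if lo < 1 or hi > len(sequence):
        return NEAR_TERMINUS
    return sequence[lo - 1 : hi]


def match_motif(window: str, pattern: MotifPattern) -> bool:
    """True iff every constrained pattern position matches the window."""
    if window == NEAR_TERMINUS:
        raise ValueError("cannot match a near-terminus sentinel window")
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}"
        )
    for ch, tok in zip(window, pattern.tokens):
        if tok is None:
            continue
        if ch in AMBIGUOUS or ch not in tok:
            return False
    return True


def build_motif_groups(
    windows: dict[tuple[str, int], str],
    patterns: list[MotifPattern],
    table: RatioTable,
    contrast: str,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
) -> list[SubstrateGroup]:
    """Group detected sites by motif match for motif-level KSEA.

    ``windows`` maps site keys to their 15-residue context (sentinel
    windows are skipped).  A site may match several overlapping motifs.
    Only patterns matched at least ``min_occurrence`` times among
    aggregated sites are kept.
    """
    df = table.df
    detected = df[df[f"{contrast}_mean"].notna()]
    ratios = {
        (p, int(pos)): float(m)
        for p, pos, m in zip(
            detected["protein"], detected["position"], detected[f"{contrast}_mean"]
        )
    }
    groups = []
    for pat in patterns:
        members, vals = [], []
        for key, window in windows.items():
            if key not in ratios or window == NEAR_TERMINUS:
                continue
            if match_motif(window, pat):
                members.append(key)
                vals.append(ratios[key])
        if len(members) >= min_occurrence:
            groups.append(
                SubstrateGroup(kinase=pat.text, members=members, ratios=np.array(vals))
            )
    return groups


def run_motif_ksea(
    windows: dict[tuple[str, int], str],
    patterns: list[MotifPattern],
    table: RatioTable,
    exp_stats: ExperimentStats,
    contrast: str,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
) -> pd.DataFrame:
    """KSEA over motif groups instead of kinase substrate groups."""
    groups = build_motif_groups(
        windows, patterns, table, contrast, min_occurrence=min_occurrence
    )
    background = table.df[f"{contrast}_mean"].dropna().to_numpy(dtype=float)
    return ksea_from_groups(groups, background, exp_stats, label="motif")


def classify_sq(window: str) -> bool:
    """True iff the window is a pS/pTQ site: centre S or T immediately
    followed by glutamine (the ATM/ATR consensus).  Sentinel windows
    are never SQ."""
    if window == NEAR_TERMINUS:
        return False
    if len(window) % 2 == 0:
        raise ValueError("window length must be odd")
    c = len(window) // 2
    return window[c] in "ST" and c + 1 < len(window) and window[c + 1] == "Q"


def fisher_sq_dysregulation(calls: pd.DataFrame, sq_flags) -> tuple[float, float]:
    """Fisher exact test: is upregulation enriched among pS/pTQ sites?

    ``calls`` is the dysregulation table (column ``label``), aligned
    with a boolean SQ flag per site.  Tests the 2x2 table
    (up vs not-up) x (SQ vs non-SQ), two-sided.
    """
    sq = np.asarray(sq_flags, dtype=bool)
    if len(sq) != len(calls):
        raise ValueError("one SQ flag per call required")
    up = (calls["label"] == "up").to_numpy()
    tab = np.array(
        [
            [int(np.sum(up & sq)), int(np.sum(up & ~sq))],
            [int(np.sum(~up & sq)), int(np.sum(~up & ~sq))],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        log.warning("empty margin in SQ dysregulation table; p set to 1")
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(odds), float(p)


def logo_counts(windows: list[str]) -> pd.DataFrame:
    """Position x residue count matrix over equal-length windows.

    Rows are 1-based window positions; columns are residues; an extra
    ``freq_`` frame can be derived by dividing rows by their sums.
    """
    if not windows:
        raise ValueError("no windows supplied")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows have mixed lengths")
    residues = sorted({ch for w in windows for ch in w})
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, length + 1, name="position"), columns=residues
    )
    for w in windows:
        for i, ch in enumerate(w, start=1):
            counts.at[i, ch] += 1
    return counts


def logo_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-position residue frequencies (rows sum to 1)."""
    return counts.div(counts.sum(axis=1), axis=0)
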