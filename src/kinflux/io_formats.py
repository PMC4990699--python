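"""Readers and writers for every external table the pipeline touches.

All formats are plain TSV (tab-separated, UTF-8, one header line, no
quoting) or FASTA.  Missing cells are written as the empty string and
read back as absent values; ``.`` is accepted as missing on input.
Protein positions are 1-based throughout, matching curated
kinase-substrate resources.

A phosphosite is identified by ``(gene symbol, position)``; the residue
and sequence window travel with it but are not part of the key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

MISSING = ["", "."]
VALID_RESIDUES = frozenset("STY")

#: sentinel for phosphosites closer than one flank to a protein terminus
NEAR_TERMINUS = "near-terminus"


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the line."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True)
class PhosphoSite:
    """A phosphorylated residue: protein symbol, 1-based position, residue.

    ``window15`` is the 7+1+7 sequence context centred on the residue,
    or the ``near-terminus`` sentinel when the site lies within seven
    residues of a protein terminus.
    """

    protein: str
    position: int
    residue: str
    window15: str = NEAR_TERMINUS

    def __post_init__(self):
        if self.residue not in VALID_RESIDUES:
            raise ValidationError(
                f"residue {self.residue!r} at {self.protein}:{self.position} "
                f"not one of S/T/Y"
            )
        if self.window15 != NEAR_TERMINUS:
            if len(self.window15) != 15:
                raise ValidationError(
                    f"window for {self.protein}:{self.position} has length "
                    f"{len(self.window15)}, expected 15"
                )
            if self.window15[7] != self.residue:
                raise ValidationError(
                    f"window centre {self.window15[7]!r} does not match residue "
                    f"{self.residue!r} at {self.protein}:{self.position}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein, self.position)


@dataclass
class RatioTable:
    """Per-site replicate log2 ratios for one or more contrasts.

    ``df`` holds one row per site with columns ``protein``, ``position``,
    ``residue``, ``window`` followed by replicate columns
    ``<contrast>_r1 .. _r<k>`` and, after processing, the derived columns
    ``<contrast>_n/_mean/_t/_p/_lfdr``.  The mean is defined only for
    sites observed in at least two replicates.
    """

    df: pd.DataFrame
    contrasts: list[str]
    n_replicates: int = 3

    def replicate_cols(self, contrast: str) -> list[str]:
        return [f"{contrast}_r{i}" for i in range(1, self.n_replicates + 1)]

    def site_keys(self) -> pd.Index:
        return pd.MultiIndex.from_arrays(
            [self.df["protein"], self.df["position"]], names=["protein", "position"]
        )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class KinaseSubstrateMap:
    """Merged kinase -> substrate-site mapping.

    One row per distinct (kinase, protein, position) with the residue and
    a ``;``-joined list of source labels.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["kinase", "protein", "position", "residue", "sources"]
        )
    )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SequenceSet:
    """Ordered id -> sequence mapping read from FASTA; ids unique."""

    records: dict[str, str]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: str) -> str:
        return self.records[key]

    def __iter__(self):
        return iter(self.records)

    def items(self):
        return self.records.items()


@dataclass
class ExpressionMatrix:
    """Summarized log2 expression: probes x samples.

    ``probe_genes`` maps each probe id to its associated gene symbols
    (possibly none or several); ``groups`` maps sample id to group label
    and may be None when no group analysis is requested.
    """

    values: pd.DataFrame
    probe_genes: dict[str, list[str]]
    groups: pd.Series | None = None

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicated probe ids: {list(dups)[:5]}")

    def require_groups(self) -> pd.Series:
        if self.groups is None:
            raise ValidationError("sample group labels required but not provided")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        return self.groups


# ---------------------------------------------------------------------------
# readers / writers


def read_ratio_table(
    path, contrasts: list[str], n_replicates: int = 3
) -> RatioTable:
    """Read a phosphopeptide log2-ratio TSV.

    Expected columns: ``protein``, ``position``, ``residue``, ``window``,
    then ``<contrast>_r1..r<k>`` for each contrast.  Empty and ``.``
    cells become missing values, never zeros.  Raises
    :class:`ParseError` / :class:`ValidationError` naming the offending
    line (1-based, counting the header as line 1).
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    required = ["protein", "position", "residue", "window"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")

    # positions must be integers; report the first bad line
    positions = pd.to_numeric(df["position"], errors="coerce")
    bad = positions.isna() | (positions != positions.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(
            f"{path}: malformed position {df['position'].iloc[line - 2]!r} "
            f"on line {line}"
        )
    df["position"] = positions.astype(int)

    bad_res = ~df["residue"].isin(VALID_RESIDUES)
    if bad_res.any():
        line = int(np.flatnonzero(bad_res.to_numpy())[0]) + 2
        raise ValidationError(
            f"{path}: residue {df['residue'].iloc[line - 2]!r} on line {line} "
            f"not one of S/T/Y"
        )

    key = pd.MultiIndex.from_arrays([df["protein"], df["position"]])
    if key.has_duplicates:
        dup = key[key.duplicated()][0]
        raise ValidationError(f"{path}: duplicated site identifier {dup}")

    rep_cols = [
        f"{c}_r{i}" for c in contrasts for i in range(1, n_replicates + 1)
    ]
    for col in rep_cols:
        if col not in df.columns:
            raise ParseError(f"{path}: missing replicate column {col!r}")
        df[col] = pd.to_numeric(df[col].replace(MISSING, np.nan))

    return RatioTable(df=df, contrasts=list(contrasts), n_replicates=n_replicates)


def write_ratio_table(table: RatioTable, path) -> None:
    """Write a ratio table as TSV; floats round-trip bit-exact."""
    df = table.df.copy()
    float_cols = df.select_dtypes(include=[float]).columns
    for col in float_cols:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> SequenceSet:
    """Read FASTA; ids are the header up to the first whitespace.

    Sequences are uppercased; record order is preserved.  Duplicate ids
    and empty sequences are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for id {rec.id!r}")
        records[rec.id] = seq
    return SequenceSet(records=records)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_kinase_map(
    paths: list, sources: list[str] | None = None
) -> KinaseSubstrateMap:
    """Merge kinase-substrate TSVs (columns kinase/protein/position/residue).

    Emulates merging curated collections (HPRD, PhosphoSitePlus,
    Phospho.ELM): duplicate (kinase, protein, position) pairs are
    collapsed and their source labels concatenated with ``;``.
    """
    if sources is None:
        sources = [str(p) for p in paths]
    if len(sources) != len(paths):
        raise ValueError("one source label per file required")
    frames = []
    for path, source in zip(paths, sources):
        df = pd.read_csv(
            path, sep="\t", dtype={"kinase": str, "protein": str, "residue": str},
            keep_default_na=False, na_values=[],
        )
        for col in ("kinase", "protein", "position", "residue"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing column {col!r}")
        df["position"] = pd.to_numeric(df["position"]).astype(int)
        df["sources"] = source
        frames.append(df[["kinase", "protein", "position", "residue", "sources"]])
    if not frames:
        return KinaseSubstrateMap()
    merged = pd.concat(frames, ignore_index=True)
    collapsed = (
        merged.groupby(["kinase", "protein", "position"], as_index=False)
        .agg(residue=("residue", "first"), sources=("sources", ";".join))
        .sort_values(["kinase", "protein", "position"], ignore_index=True)
    )
    return KinaseSubstrateMap(df=collapsed)


def write_kinase_map(kmap: KinaseSubstrateMap, path) -> None:
    kmap.df.to_csv(path, sep="\t", index=False)


def read_networkin(path) -> pd.DataFrame:
    """Read a NetworKIN-style prediction table.

    Columns: ``kinase``, ``substrate`` (symbol_position), ``window11``
    (11-residue context, phosphoacceptor at centre), ``networkin_score``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for col in ("kinase", "substrate", "window11", "networkin_score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["networkin_score"] = pd.to_numeric(df["networkin_score"])
    bad_len = df["window11"].str.len() != 11
    if bad_len.any():
        line = int(np.flatnonzero(bad_len.to_numpy())[0]) + 2
        raise ValidationError(f"{path}: window11 on line {line} is not 11 residues")
    return df


def read_expression(
    values_path, probe_map_path, groups_path=None
) -> ExpressionMatrix:
    """Read an expression matrix, its probe->gene map, and group labels.

    The probe map has columns ``probe`` and ``gene``; a probe with several
    genes appears on several lines (or with an empty gene field for
    unannotated probes).  Group labels TSV has columns ``sample`` and
    ``group``.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    pmap = pd.read_csv(
        probe_map_path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    probe_genes: dict[str, list[str]] = {p: [] for p in values.index}
    for probe, gene in zip(pmap["probe"], pmap["gene"]):
        if probe not in probe_genes:
            probe_genes[probe] = []
        if gene:
            probe_genes[probe].append(gene)
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(
            groups_path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
        )
        groups = pd.Series(gdf["group"].values, index=gdf["sample"].values)
    return ExpressionMatrix(values=values, probe_genes=probe_genes, groups=groups)
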