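"""Synthetic study generator.

Generates every input the pipeline consumes with the statistical
structure the analysis assumes: a random proteome with phosphosites
placed clear of the termini, kinase-substrate assignments, triplicate
SILAC-style log2 ratio tables with per-replicate dropout and planted
kinase-activity shifts, 3'UTR cohorts with planted seed motifs and
expression effects, and two-group patient expression matrices with a
planted gene set plus probes embodying each filter-failure mode.

All generators are pure functions of the configuration (which carries
the seed): identical configs give identical data.  Every planted truth
is returned alongside the data so downstream tests never reach into
generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from kinflux.io_formats import (
    ExpressionMatrix,
    KinaseSubstrateMap,
    RatioTable,
    SequenceSet,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCS = np.array(list("ACGT"))

# per-generator rng stream tags, so the streams stay independent
_TAG_PROTEOME, _TAG_PHOSPHO, _TAG_UTR, _TAG_EXPR, _TAG_NETWORKIN = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the triplicate SILAC design (three replicates per
    contrast, moderate per-replicate dropout), a kinase panel with a
    handful of activity-shifted kinases at one log2 unit, a gene cohort
    with a planted seed-motif expression effect, and a two-group
    patient cohort (9 vs 17) with a planted up-regulated gene set.
    """

    seed: int = 0
    # proteome / phospho experiment
    n_kinases: int = 20
    substrates_per_kinase: int = 30
    protein_length: int = 60
    flank: int = 7
    perturbed_kinases: dict = field(
        default_factory=lambda: {
            "KIN01": 1.0, "KIN02": -1.0, "KIN03": 1.0, "KIN04": -1.0,
        }
    )
    replicate_sigma: float = 0.5
    n_replicates: int = 3
    dropout: float = 0.1
    motif_kinase: str | None = None  # plant a +1 proline context on this kinase
    # UTR cohort
    n_genes: int = 2000
    utr_length: int = 500
    seed_motif: str = "CTATAGT"
    seed_motif_fraction: float = 0.2
    target_effect: float = -0.5
    gene_ratio_sd: float = 1.0
    # expression cohort
    n_cohort_genes: int = 5000
    planted_set_size: int = 100
    cohort_effect: float = 1.0
    group_sizes: tuple = (9, 17)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    expr_floor: float = 5.0
    n_low_expr: int = 5
    n_multi_gene: int = 5
    n_no_gene: int = 5
    n_dup_gene: int = 5  # genes mapped by two probe sets each

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        if not 0.0 <= self.seed_motif_fraction <= 1.0:
            raise ValueError("seed_motif_fraction must be a probability")
        if self.replicate_sigma <= 0:
            raise ValueError("replicate_sigma must be positive")
        if self.protein_length < 2 * self.flank + 1:
            raise ValueError(
                f"protein_length must be >= {2 * self.flank + 1} to host a full window"
            )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def kinase_names(config: SimConfig) -> list[str]:
    return [f"KIN{i + 1:02d}" for i in range(config.n_kinases)]


def gen_proteome(config: SimConfig) -> tuple[SequenceSet, pd.DataFrame]:
    """Random proteome with one designated phosphosite per protein.

    Each of n_kinases * substrates_per_kinase substrate proteins gets a
    random amino-acid sequence with an S/T/Y site at a uniform position
    at least flank+1 residues from either terminus, so every site's
    full window is extractable.  When ``motif_kinase`` is set, that
    kinase's substrates carry a proline immediately after the
    phosphoacceptor (and the acceptor is S/T), giving the classic
    proline-directed motif.  Returns the sequences and a site catalogue
    (protein, position, residue, window15, kinase).
    """
    rng = _rng(config, _TAG_PROTEOME)
    n_sub = config.n_kinases * config.substrates_per_kinase
    L = config.protein_length
    flank = config.flank
    kinases = np.repeat(kinase_names(config), config.substrates_per_kinase)

    records: dict[str, str] = {}
    rows = []
    for i in range(n_sub):
        protein = f"SUB{i + 1:04d}"
        seq = rng.choice(AMINO_ACIDS, size=L)
        pos = int(rng.integers(flank + 1, L - flank + 1))  # 1-based
        planted = config.motif_kinase is not None and kinases[i] == config.motif_kinase
        if planted:
            residue = "S" if rng.random() < 0.8 else "T"
            seq[pos] = "P"  # position pos is 0-based index of the +1 residue
        else:
            residue = rng.choice(["S", "T", "Y"], p=[0.7, 0.25, 0.05])
        seq[pos - 1] = residue
        seq_str = "".join(seq)
        records[protein] = seq_str
        rows.append(
            {
                "protein": protein,
                "position": pos,
                "residue": residue,
                "window15": seq_str[pos - flank - 1 : pos + flank],
                "kinase": kinases[i],
            }
        )
    return SequenceSet(records=records), pd.DataFrame(rows)


def gen_kinase_map(catalogue: pd.DataFrame) -> KinaseSubstrateMap:
    """Kinase-substrate map from the site catalogue (source 'synthetic')."""
    df = catalogue[["kinase", "protein", "position", "residue"]].copy()
    df["sources"] = "synthetic"
    return KinaseSubstrateMap(
        df=df.sort_values(["kinase", "protein", "position"], ignore_index=True)
    )


def gen_phospho_experiment(
    config: SimConfig,
    kmap: KinaseSubstrateMap,
    catalogue: pd.DataFrame,
    contrast: str = "treat_vs_ctrl",
) -> tuple[RatioTable, pd.DataFrame]:
    """Triplicate log2 ratios with planted kinase-activity shifts.

    Substrates of a perturbed kinase k draw their replicates around
    delta_k, all others around 0, with Gaussian noise replicate_sigma;
    each replicate is independently missing with probability
    ``dropout``.  Returns the ratio table and the per-site truth
    (kinase, delta).
    """
    rng = _rng(config, _TAG_PHOSPHO)
    deltas = catalogue["kinase"].map(
        lambda k: config.perturbed_kinases.get(k, 0.0)
    ).to_numpy(dtype=float)
    n = len(catalogue)
    reps = deltas[:, None] + rng.normal(
        0.0, config.replicate_sigma, size=(n, config.n_replicates)
    )
    drop = rng.random(size=reps.shape) < config.dropout
    reps[drop] = np.nan

    df = catalogue[["protein", "position", "residue"]].copy()
    df["window"] = catalogue["window15"]
    for j in range(config.n_replicates):
        df[f"{contrast}_r{j + 1}"] = reps[:, j]
    table = RatioTable(
        df=df.reset_index(drop=True),
        contrasts=[contrast],
        n_replicates=config.n_replicates,
    )
    truth = catalogue[["protein", "position", "kinase"]].copy()
    truth["delta"] = deltas
    return table, truth


def gen_utr_cohort(config: SimConfig) -> tuple[SequenceSet, pd.Series, pd.DataFrame]:
    """Random 3'UTRs with planted seed motifs and an expression effect.

    A configured fraction of genes receives one planted seed motif at a
    random offset (written over the random background); those genes'
    log2 expression ratios are shifted by ``target_effect``.  Returns
    the UTR sequences, the per-gene log2 ratios, and the truth table
    (gene, seeded, offset).
    """
    rng = _rng(config, _TAG_UTR)
    motif = config.seed_motif
    if len(motif) > config.utr_length:
        raise ValueError("seed motif longer than the UTR length")
    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    seeded = rng.random(config.n_genes) < config.seed_motif_fraction
    records: dict[str, str] = {}
    offsets = np.full(config.n_genes, -1)
    for i, gene in enumerate(genes):
        seq = rng.choice(NUCS, size=config.utr_length)
        if seeded[i]:
            off = int(rng.integers(0, config.utr_length - len(motif) + 1))
            seq[off : off + len(motif)] = list(motif)
            offsets[i] = off + 1  # 1-based
        records[gene] = "".join(seq)
    ratios = pd.Series(
        rng.normal(0.0, config.gene_ratio_sd, size=config.n_genes)
        + np.where(seeded, config.target_effect, 0.0),
        index=genes,
    )
    truth = pd.DataFrame({"gene": genes, "seeded": seeded, "offset": offsets})
    return SequenceSet(records=records), ratios, truth


def gen_expression_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, list[str], dict[str, int]]:
    """Two-group patient expression matrix with a planted gene set.

    Clean probes map 1:1 to genes; the planted set's genes are shifted
    in group 1 (labelled ``g1``) by ``cohort_effect``.  Extra probes
    embody each filter-failure mode in configured numbers.  Returns the
    matrix, the planted gene set, and the expected per-rule exclusion
    counts for the probe filter.
    """
    if min(config.group_sizes) < 2:
        raise ValueError("both cohort groups need >= 2 samples")
    rng = _rng(config, _TAG_EXPR)
    n1, n2 = config.group_sizes
    samples = [f"s{i + 1:02d}" for i in range(n1 + n2)]
    groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=samples)

    genes = [f"CG{i + 1:05d}" for i in range(config.n_cohort_genes)]
    planted = list(rng.choice(genes, size=config.planted_set_size, replace=False))
    planted_mask = np.isin(genes, planted)

    baseline = rng.normal(
        config.baseline_mean, config.baseline_sd, size=config.n_cohort_genes
    )
    # keep clean genes clear of the expression floor so the low-expression
    # exclusion rule fires only on the probes constructed for it
    baseline = np.maximum(baseline, config.expr_floor + 1.5)
    vals = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_cohort_genes, n1 + n2)
    )
    vals[planted_mask, :n1] += config.cohort_effect

    probes = [f"p_{g}" for g in genes]
    probe_genes = {p: [g] for p, g in zip(probes, genes)}
    values = pd.DataFrame(vals, index=probes, columns=samples)

    def _extra(n_probes, prefix, low=False):
        v = rng.normal(
            config.expr_floor - 3.0 if low else config.baseline_mean,
            0.5, size=(n_probes, n1 + n2),
        )
        idx = [f"{prefix}{i + 1:03d}" for i in range(n_probes)]
        return pd.DataFrame(v, index=idx, columns=samples)

    # (i) low expression in both groups, with an otherwise clean mapping
    low = _extra(config.n_low_expr, "plow", low=True)
    for i, p in enumerate(low.index):
        probe_genes[p] = [f"LOWG{i + 1:03d}"]
    # (ii) several gene symbols
    multi = _extra(config.n_multi_gene, "pmulti")
    for i, p in enumerate(multi.index):
        probe_genes[p] = [f"MGA{i + 1:03d}", f"MGB{i + 1:03d}"]
    # (iii) no gene symbol
    nogene = _extra(config.n_no_gene, "pnogene")
    for p in nogene.index:
        probe_genes[p] = []
    # (iv) two probes per gene; both are excluded by the filter
    dup = _extra(2 * config.n_dup_gene, "pdup")
    for i, p in enumerate(dup.index):
        probe_genes[p] = [f"DUPG{i // 2 + 1:03d}"]

    values = pd.concat([values, low, multi, nogene, dup])
    expected_counts = {
        "low_expression": config.n_low_expr,
        "multiple_genes": config.n_multi_gene,
        "no_gene": config.n_no_gene,
        "gene_multi_probe": 2 * config.n_dup_gene,
    }
    matrix = ExpressionMatrix(values=values, probe_genes=probe_genes, groups=groups)
    return matrix, planted, expected_counts


def gen_networkin(
    config: SimConfig,
    n_records: int = 4000,
    planted_kinase: str = "NK_PLANT",
    planted_motif_fraction: float = 0.08,
) -> tuple[pd.DataFrame, str]:
    """NetworKIN-style mapping table with one planted kinase-motif link.

    Background records carry random kinases and random 11-residue
    windows (S/T centre).  A planted fraction of records belong to
    ``planted_kinase`` and always carry a proline at +1 — the motif
    ``.....[ST]P....`` — while background windows have proline at +1
    only by chance.  Scores are uniform on (0, 6) so roughly half pass
    the default confidence floor.  Returns the table and the planted
    11-mer pattern text.
    """
    rng = _rng(config, _TAG_NETWORKIN)
    kin_pool = [f"NK{i + 1:02d}" for i in range(15)]
    rows = []
    for i in range(n_records):
        is_planted = rng.random() < planted_motif_fraction
        kinase = planted_kinase if is_planted else str(rng.choice(kin_pool))
        win = rng.choice(AMINO_ACIDS, size=11)
        win[5] = "S" if rng.random() < 0.75 else "T"
        if is_planted:
            win[6] = "P"
        rows.append(
            {
                "kinase": kinase,
                "substrate": f"SUB{rng.integers(1, 10_000):05d}_{rng.integers(1, 500)}",
                "window11": "".join(win),
                "networkin_score": float(rng.uniform(0.0, 6.0)),
            }
        )
    return pd.DataFrame(rows), ".....[ST]P...."
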