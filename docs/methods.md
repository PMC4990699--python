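# Methods

This note records the statistical models, the defaults, and the design
choices made where the underlying analysis left the details open. All
empirical numbers referenced here are the ones computed by the test
suite or `scripts/acceptance.py`.

## Per-site statistics

Replicate log2 phosphopeptide ratios (triplicate design) are aggregated
as the arithmetic mean of the observed replicates; a site needs at
least two observations, and singly detected sites are discarded rather
than imputed. Each aggregated site is tested against zero with a
two-sided one-sample t test (df = n−1, so df = 2 at full triplicates).
With zero sample variance and a nonzero mean the p-value degenerates;
the smallest positive float is reported with a `zero_variance` flag.

**Local FDR.** The per-site local false discovery rate follows the
empirical-Bayes two-group model: signed z scores are obtained from the
t p-values (`z = sign(t) · Φ⁻¹(1 − p/2)`, with p floored at 1e−300 to
keep z finite for degenerate sites), the mixture density `f(z)` is
estimated with a Gaussian kernel (Scott bandwidth), the null `f0` is
the theoretical standard normal, and `π0` is estimated from the
central-region count `#{|z| ≤ 1} / (n · (Φ(1) − Φ(−1)))`, capped at 1.
`fdr(z) = π0 f0(z) / f(z)`, capped at 1 and monotonized (pool-adjacent-
violators) to be non-increasing in |z| within each sign tail. The two
tails are monotonized separately so an asymmetric alternative is not
flattened. Below 50 values the estimate is flagged as unstable; a
degenerate all-identical input returns fdr = 1 with a warning. Under a
pure N(0,1) null at n = 2000 the median fdr is ≥ 0.99 (acceptance
suite); a 10% component shifted by 4 units gets mean fdr < 0.2.

**Dysregulation calls** use |mean log2| > 0.58 (≈ 1.5-fold) strictly and
local FDR ≤ 0.1. The experiment-wide reference distribution
(`μ`, `s`, population divide-by-N form — fixed and unit-tested, the
sample form would differ negligibly at experiment scale) is computed
over all aggregated sites of a contrast.

## KSEA

Substrate groups intersect the merged kinase→substrate map with the
detected, aggregated sites; site identity is (gene symbol, 1-based
position), a site may serve several kinases, and map entries whose
residue disagrees with the ratio table at the same key are logged and
dropped. The default group floor is 10 detected members.

The hypergeometric framing is one-sided tails against the background
composition: with M aggregated background sites of which K are
increased, drawing n = N_I + N_D signed members, `P(X ≥ N_I)` and
symmetrically `P(X ≥ N_D)` against the decreased count. Both tails are
reported; the headline p is the smaller. Members at exactly zero count
in neither tally (the fcount denominator is N_I + N_D, implying a
strict sign partition). The z test and the hypergeometric family are
BH-corrected independently, since they answer different questions
(magnitude shift vs sign imbalance) and are reported side by side.

## Motif analysis

Patterns are fixed-width strings, one token per position: `.` wildcard,
a literal residue, or a bracket class (`[ST]`) occupying one position —
the unambiguous fixed-width rendering of motifs conventionally printed
as e.g. "pS/pTP". The centre of a valid pattern allows only S and/or T.
Ambiguous residues (B, Z, X) in a window match only wildcards
(conservative). Window extraction returns a `near-terminus` sentinel
for sites within seven residues of either terminus; such sites are
excluded from motif work. Motif *discovery* is out of scope — patterns
are inputs.

The motif occurrence floor defaults to 50, the value appropriate to a
full-scale experiment of several thousand peptides. The synthetic
studies in `analysis/` and the acceptance script run ~600 detected
sites, where the planted proline-directed group lands at 55 ± 5
members; those studies use a proportionally scaled floor of 30 so that
sampling noise in group size does not mask an otherwise decisive signal
(the group's q_z is < 1e−6 in every seeded run).

Simplification to the 11-residue (5+1+5) format keeps the central 11
tokens when no residue constraint lies in the trimmed flanks; a pattern
with a constraint outside positions 3–13 of the 15-mer cannot be
expressed as 5+1+5 and is removed, with each removal logged.

## Kinase–motif association

Mapping records (kinase, substrate, 11-residue window, confidence
score) are filtered to score strictly > 3. `ES_{m,k}` and the Fisher
test share the mapping-level sampling frame: each record is one trial,
the 2×2 table is (matches m vs not) × (kinase k vs not), so
`N` = total mappings, keeping ES and p consistent. BH correction is
applied jointly across all (motif, kinase) pairs before the per-motif
top-10 selection with `n_mk ≥ 100`; the joint family is the
conservative choice where the original family was unstated. The number
of distinct kinases across selections is reported but depends on the
prediction snapshot, so it is not a validated quantity.

## Seed enrichment

UTR scanning is single-stranded (3′UTRs are mRNA sense), exact matching
with overlaps counted, on the longest UTR per gene (the gene symbol is
the FASTA id up to the first `|`; equal-length ties keep the
lexicographically smaller sequence, deterministically). Ranking is
ascending in log2 ratio — most downregulated first — with symbol
tie-breaks; the direction is recorded in the output. The KS test is
two-sample on rank values (seed vs non-seed genes), with the exact
conditional p-value whenever the smaller class has ≤ 10 members or
n·m ≤ 1e6 (cheap and better calibrated than the asymptotic formula at
cohort sizes; the method used is recorded). A one-sample variant
against the uniform rank distribution is exposed as an option. The
7-mer seed is a parameter, defaulting to the miR-625-3p target motif
CTATAGT.

## Expression cohort

Probe filtering applies the four exclusion rules in order — (i) mean
log2 expression below the floor (default 5) in both groups, (ii)
several gene symbols, (iii) no gene symbol, (iv) gene symbol shared by
several probe sets — attributing each excluded probe to the first rule
it fails, with rule (iv) multiplicity assessed among probes surviving
(i)–(iii). The rule order was unstated upstream; this ordering is
deterministic, idempotent, and matches the natural reading that
per-gene uniqueness is evaluated on annotatable probes.

Fold-change calls use strict linear fold change > 1.5 (log2 > 0.585).
The cohort ranking statistic is median(group 1) − median(group 2),
descending. The enrichment score is the classic unweighted KS running
sum (+1/|hits| at set members, −1/|misses| otherwise; ES = signed
maximum deviation), since the source analysis attributes its p-value to
a Kolmogorov–Smirnov test rather than a weighted permutation scheme; a
|statistic|-weighted variant is available behind a flag for comparison.
The p-value is the two-sample KS test on in-set vs out-of-set ranks;
phenotype permutation is deliberately not the default.

## Synthetic data

The generator emulates the study designs the statistics assume:

- **Phospho experiment:** 20 kinases × 30 substrate sites, one site per
  random 60-residue protein placed ≥ 8 residues from the termini (so
  every 15-mer window exists); triplicate log2 ratios Gaussian around
  the kinase's planted activity shift (default: 4 kinases at ±1.0 log2
  units, noise σ = 0.5) with independent 10% per-replicate dropout,
  which puts a realistic share of sites into the discarded
  singly-detected class. Optionally one kinase's substrates carry a +1
  proline (proline-directed motif) for motif-KSEA recovery studies.
- **UTR cohort:** 2000 genes, 500-nt random UTRs, 20% seeded with one
  planted CTATAGT at a random offset; seeded genes' log2 ratios shifted
  by −0.5 against unit-SD background. Chance seed matches in
  unseeded UTRs occur at the theoretical (L−6)·4⁻⁷ rate and are left in
  place — the analysis scans sequences, never the truth table.
- **Expression cohort:** 5000 clean genes (1:1 probes), groups of 9 and
  17 samples, baseline N(7, 1) truncated ≥ 1.5 above the expression
  floor (so rule (i) fires only on purpose-built probes), unit noise; a
  planted 100-gene set shifted +1.0 in group 1; plus configured counts
  of probes embodying each filter-failure mode.
- **NetworKIN table:** 4000 records, 15 background kinases, uniform
  scores on (0, 6) (half pass the >3 floor); a planted kinase whose
  records always match `.....[ST]P....`.

Generators are pure functions of (config, seed) with independent
per-generator streams; every planted truth is returned alongside the
data. What the synthetic data does **not** emulate: peptide-level
effects (missed cleavages, shared peptides, intensity-dependent
missingness), correlated replicates, non-Gaussian ratio noise,
realistic UTR composition bias, or array probe effects — so passing
tests demonstrate the correctness and calibration of the statistics
under their stated assumptions, not robustness to those artefacts.
A heavier-tailed noise option on the phospho generator is the natural
extension point for robustness studies.

## Problem sizes and numerical choices

The seeded studies use 50 runs for kinase recovery, 20 for motif and
seed-enrichment power, 30 for cohort GSEA power, 100–200 for null
calibration, and n = 2000 for local-FDR simulations — sizes at which
every Monte-Carlo check is stable across base seeds while the whole
acceptance script stays under a minute. Exact tests (hypergeometric,
Fisher, small/medium KS) are used wherever feasible and are verified
against brute-force enumeration oracles in the test suite. Ties in
rankings break lexicographically by symbol; all orderings are
deterministic; p-values are capped into (0, 1].

## Known limitations

- The local-FDR estimate assumes the theoretical N(0,1) null; with
  df = 2 t tests the tail mapping is exact only under normal replicate
  noise (which the generator provides). An empirical-null variant is
  not implemented.
- KSEA treats substrates as exchangeable; no weighting by site
  stoichiometry or mapping confidence.
- The cohort GSEA p-value treats genes as independent under the null;
  inter-gene correlation in real cohorts would make it anti-
  conservative, which is why the enrichment score itself is reported
  alongside.
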