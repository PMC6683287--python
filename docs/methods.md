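# Methods

## wGRR and bidirectional best hits

The weighted gene repertoire relatedness between elements *A* and *B* is
`wGRR = 100 · Σ id(Aᵢ,Bᵢ) / min(|A|,|B|)`, summed over bidirectional best
hits (BBHs). Inputs are precomputed protein-vs-protein alignments
(12-column BLAST tabular; percent identity is divided by 100 at parse
time, so identities are fractions throughout). A hit enters BBH
resolution only when its e-value is strictly below `evalue_max`
(default 1e-5).

Choices the score definition leaves open, fixed here deterministically:

* **Best hit ranking** — highest bitscore, then lowest e-value, then
  highest identity, then lexicographically smallest subject id. The
  published score does not state a tie rule; any fixed rule gives the same
  score whenever ties are between equally good alignments, and a
  deterministic rule makes outputs reproducible.
* **Strict reciprocity** — a pair is a BBH only if each protein is the
  other's best hit *and both directional hits exist*; a missing reverse
  alignment breaks the pair.
* **Asymmetric identities** — when the two directions of a reciprocal pair
  report different identities, the pair's identity is their arithmetic
  mean.
* **Self-hits** (query = subject) are ignored in cross-element
  comparisons.

Redundancy clustering (used to deduplicate near-identical prophages at
wGRR ≥ 95) is single linkage: connected components of the
threshold graph, an absent pair counting as wGRR 0. The cluster
representative is the member with the most proteins, ties broken by
smallest element id.

## Cutoff calibration

For an attribute (family, lifestyle, host phylum) and a reference
database, the cutoff is the smallest *observed* wGRR value *t* such that
among all labelled pairs scoring ≥ *t* the fraction sharing the attribute
is at least the target (default 0.95). Concordance is therefore
**cumulative** (over the whole upper tail, not per bin), and candidate
thresholds are the observed values — the natural resolution of the data.
When no candidate attains the target the function returns an explicit
"unattainable" outcome (`None`; exit code 3 on the command line) rather
than a fabricated threshold.

Fragmentation is handled by re-estimating the cutoff on simulated
contiguous fragments of 5, 10, 15, 20, 30, 40, 50 and 60 genes. Fragments
are linear windows (no circular wraparound) with a uniformly random start;
each fragment is scored against every complete genome *except its own
source*, which would otherwise inflate concordance with near-perfect
self-matches. One fragment per phage per size is the default (the
procedure's variance at desk scale is already small; the count is
configurable). Genomes shorter than a requested size are skipped for that
size. Pairs with wGRR 0 are retained in the pair set.

The per-size cutoffs are fitted with `Y = α·e^(−βX) + γ` by nonlinear
least squares (`scipy.optimize.curve_fit`), initialised at
`(max−min cutoff, 0.1, min cutoff)`. On non-convergence the fit falls
back to a variable-projection grid over β (closed-form α, γ per β). At
least three finite per-size cutoffs are required. Applied thresholds are
floored at 0. For α, β > 0 the curve is strictly decreasing in fragment
size, the expected behaviour on real databases where short fragments pick
up spurious best hits.

## Decision algorithm

Contigs with fewer than 3 complete ORFs (genes with both start and stop
codons, enforced upstream by the gene caller) are excluded. Each
remaining contig is classified by the first matching evidence class in a
configurable precedence order, default:

1. **phage with family** — best hit in the *phage reference* database
   (never the prophage databases) with wGRR ≥ the size-adjusted family
   cutoff;
2. **putative phage** — any phage-signal category 1–6 (all six count for
   contigs; when building reference *prophage* databases categories 3 and
   6 are excluded as likely other mobile elements). Phage marker-gene
   hits (capsid/portal/protease/replication/tail profiles) are an optional
   OR-term, off by default;
3. **bacteria** — ≥ 1 bacterial marker-profile hit or a 16S hit
   (16S adapter applies E ≤ 0.1);
4. **contamination** — nucleotide hit with query coverage > 0.9 whose
   taxonomy is human, archaeal, eukaryotic or eukaryotic-virus; unknown
   taxonomy labels are logged and treated as non-contaminant;
5. **NA** otherwise.

The classification is total and deterministic. `audit_conflicts` lists
contigs carrying evidence of ≥ 2 classes — exactly the contigs whose class
can change under a different precedence — making the robustness of the
order an assertable property instead of an assumption.

**Lifestyle.** Contigs with **more than 19 proteins** use replicate
lifestyle probabilities (PHACTS-style): the predicted class is the larger
mean, *confident* iff the two means differ by at least twice the sample
SD (ddof = 1) of the predicted class's replicate scores. Which SD the
2-SD rule refers to is ambiguous in the published description; the
predicted class's replicate SD is used, with a non-strict ≥ comparison. A
tie in the means goes to *temperate* (the dominant gut-phage lifestyle),
though ties are measure-zero with real replicate scores. Shorter contigs
use the best wGRR hit's lifestyle above the lifestyle cutoff, always
labelled non-confident.

**Host.** One above-threshold hit in one database suffices, but if two or
more databases give above-threshold hits with *different* phyla the
contig is left without a host.

## Diversity statistics

Total-count normalization: `Sᵢ = Σⱼ aᵢⱼ`, `M = mean(Sᵢ)`,
`SFᵢ = Sᵢ/M`; each column divided by its size factor, so normalized
column sums all equal M and within-column proportions are conserved (both
asserted in tests). Zero-sum columns are a domain error naming the
sample.

Rarefaction draws each column without replacement (multivariate
hypergeometric), so rarefied column sums are exactly the depth. The
analytic counterpart `E[S] = Σⱼ [1 − C(S−Nⱼ, d)/C(S, d)]` is computed via
log-gamma for numerical stability and matches the Monte-Carlo mean within
3 standard errors in the tests.

Bray–Curtis is computed directly as `1 − 2·Σmin(u,v)/(Σu+Σv)` (a pair of
all-zero columns is defined as 0 with a warning, where a library routine
would return NaN); tests cross-check it against scipy's implementation.
Sample ordering uses scipy's agglomerative linkage (Ward by default) on
the dissimilarity matrix.

Richness is the number of contigs with ≥ 1 read in a sample, alpha the
mean richness, gamma the number of contigs with ≥ 1 read in any sample.
The literal beta formula `1 − gamma/alpha` is non-positive whenever
gamma ≥ alpha — which is always the case when samples share a catalog —
so it cannot match positive reported beta values; the package defaults to
the turnover form `1 − alpha/gamma` and keeps the literal form behind
`beta_mode="as_printed"`. Neither is silently altered.

## Synthetic data

The generator exists so that every stage has inputs with known structure.

* **Reference database** — `n_families × phages_per_family` phages,
  gene counts uniform in `genes_per_phage` (default 30–80, the scale of
  tailed-phage genomes). Homology is positional on a circular gene
  order — gene *g* of the longer genome pairs with gene *g mod n* of the
  shorter — so every fragment window has a homolog in every same-family
  genome. Identities are Gaussian around `within_identity = 0.90`
  (SD 0.03) within a family and `between_identity = 0.05` (SD 0.01)
  across families. The hit e-value is a deterministic function of
  identity, `10^−(40·id − 1)`, so 5%-identity cross-family alignments get
  e ≈ 0.1 and fail the 1e-5 BBH filter — as insignificant alignments
  would — giving cross-family wGRR of exactly 0 and a clean planted
  separation. Lifestyle, host phylum and nucleic-acid type are planted
  per family so every calibrated attribute carries signal.
* **Evidence bundles** — constructed per requested class (above-cutoff
  best hit for *phage with family*, a category 1–6 for *putative phage*,
  marker/16S hits for *bacteria*, a > 90%-coverage human/archaeal/
  eukaryotic nt hit for *contamination*, nothing or sub-coverage hits for
  *NA*), with the truth table returned for accuracy assertions.
* **Replicate community** — defaults match the replicate experiment the
  toolkit targets: 3 individuals × 3 replicates × {no MDA, 30-min MDA,
  90-min MDA}, a 6,056-contig catalog and 716,808 reads per sample (the
  rarefaction depth of such a design). Each individual has a log-normal
  abundance profile (σ = 2, a typically skewed metagenomic abundance
  distribution) shared by all its replicates and modes; replicates are
  independent multinomial draws. MDA bias is planted as two effects:
  per-sample dropout of a random contig fraction (0.2 short, 0.4 long) and
  a ×50 amplification of ssDNA-tagged contigs (5% of the catalog — ssDNA
  phages are rare in unamplified libraries). Dropout both lowers richness
  and raises within-replicate beta diversity; the boost shifts read mass
  toward ssDNA families.

What the generator does **not** emulate: real sequence evolution (modular
recombination, variable gene order), alignment-length effects on e-values,
assembly artefacts, chimeras, or MDA coverage waves. Passing tests
therefore demonstrate correctness of the computations and recovery of
planted effects, not performance on real viromes; in particular the
planted per-size cutoffs *rise* slightly with fragment size (identity
noise averages out in longer fragments) whereas on real databases the
cutoff falls with size because short fragments acquire spurious best hits.

## Problem sizes and numerics

The test suite and acceptance script use: 200 random ≤10-protein pairs
for the brute-force wGRR comparison; a 2 × 10-phage planted database with
60–100 genes per phage for calibration (all eight fragment sizes, 100
held-out fragments); 100 random matrices for the normalization invariant;
100,000 hypergeometric draws per column (20 columns) for the rarefaction
check; 50 seeds of the full 27-sample community for the MDA richness
ordering; and a scaled-down end-to-end CLI run (2 × 5 phages of 20–40
genes, 400-contig / 20,000-read community) executed twice and compared
byte-for-byte. Floating-point tolerances: exact hand cases to 1e-12,
noiseless fit recovery to 1e-6, column-sum equality to 1e-9, Monte-Carlo
agreement to 3 SE.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global RNG state is used anywhere.

## Known limitations

* Alignments are consumed, never produced: identity/e-value quality is
  inherited from the upstream aligner.
* The calibrated cutoffs are database-specific; swapping the reference
  database requires re-running the calibration (the constants themselves
  are not portable).
* The concordance criterion is cumulative over the upper tail; a locally
  discordant band just above the cutoff is possible in principle and is
  why held-out validation is part of the acceptance checks.
* Nucleotide-hit coverage needs contig lengths, which the 12-column
  tabular format lacks; the adapter takes an explicit length table.
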