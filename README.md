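# phageome

Classification and diversity analysis of gut-phageome (virome) metagenomic
contigs, built around the **weighted gene repertoire relatedness (wGRR)**
similarity score.

Most contigs assembled from faecal virome sequencing have no annotatable
homology at the single-gene level. `phageome` addresses this with a global,
whole-repertoire similarity to reference (pro)phage databases, turns that
similarity into statistically calibrated taxonomic / lifestyle / host
assignments that account for contig fragmentation, and quantifies how
reproducible the resulting community profiles are across replicates and
amplification protocols (multiple displacement amplification, MDA, is known
to distort ssDNA/dsDNA ratios and depress diversity). It is aimed at
microbiome bioinformaticians who already have assemblies, gene calls and
alignment tables, and need the downstream decision and statistics layer.

## The method

**wGRR.** For two genetic elements *A* and *B* with protein repertoires of
sizes |A| and |B|:

```
wGRR(A, B) = 100 · Σᵢ id(Aᵢ, Bᵢ) / min(|A|, |B|)
```

where the sum runs over the bidirectional best hits (BBHs) between the two
protein sets (reciprocal best alignments with e-value < 10⁻⁵) and
id(Aᵢ, Bᵢ) is the fractional sequence identity of pair *i*. wGRR ranges
from 0 (no significant homologs) to 100 (identical repertoires): the
identity-weighted fraction of homologs in the smaller element.

**Size-calibrated cutoffs.** A contig is assigned the family / lifestyle /
host phylum of its best wGRR hit only when the score clears a threshold at
which reference pairs agree on that attribute at least 95% of the time.
Because short contigs score differently from complete genomes, the
threshold is re-estimated on simulated genome fragments of 5, 10, 15, 20,
30, 40, 50 and 60 genes and interpolated with a negative exponential

```
Y(X) = α · e^(−βX) + γ
```

where *X* is the number of proteins of the smaller element and *Y* the
wGRR cutoff to apply.

**Decision algorithm.** Each contig with ≥ 3 complete ORFs is classified
into one of five groups — *phage with family* (above-cutoff wGRR best
hit), *putative phage* (phage-signal category 1–6), *bacteria* (bacterial
marker-gene or 16S hit), *contamination* (nucleotide hit with > 90%
coverage to human/archaeal/eukaryotic sequence), or *NA* — in a
configurable precedence order, with an audit of the contigs whose class
depends on that order. Lifestyle uses replicate probability scores (2-SD
confidence rule) for contigs with > 19 proteins and the wGRR best hit
otherwise.

**Diversity.** Count matrices (contigs × samples) support total-count
normalization, without-replacement rarefaction (and its exact
hypergeometric expected-richness counterpart), Bray–Curtis dissimilarity,
alpha/beta/gamma diversity and Ward-linkage sample ordering — the
statistics used to compare replicates and quantify MDA bias.

A seeded synthetic-data module generates reference databases with planted
family structure, evidence bundles, and replicate count matrices with a
plantable MDA effect, so the whole pipeline is testable without any
download.

## Worked example

```python
from phageome import (make_reference_db, calibrate_database, wgrr_between,
                      CommunitySpec, make_mda_panel, bray_curtis,
                      diversity_summary)
from phageome.diversity import mean_within_between

# planted two-family reference database + its protein hit table
db = make_reference_db(n_families=2, phages_per_family=10,
                       genes_per_phage=(60, 100), seed=42)
table = db.hit_table()
a, b, c = db.phages[0], db.phages[1], db.phages[10]
print(wgrr_between(a.repertoire, b.repertoire, table).value)  # 90.46  (same family)
print(wgrr_between(a.repertoire, c.repertoire, table).value)  # 0.0    (other family)

# size-dependent family cutoff at 95% concordance
curve = calibrate_database(db.phages, table, "family", "phage_ref", seed=42)
print(curve.per_size_cutoffs[5])        # 87.10  (cutoff for 5-gene fragments)
print(round(curve.cutoff_for_size(12), 2))  # 87.62 (fitted curve at 12 genes)

# replicate community: 3 individuals x 3 replicates, 6056 contigs
spec = CommunitySpec(seed=42)
m, truth = make_mda_panel(spec, modes=("none",))
s = diversity_summary(m)
print(s.alpha, s.gamma, round(s.beta, 4))   # 5603.0 6054 0.0745
d = bray_curtis(m)
print(mean_within_between(d, truth["individual_of_sample"]))
# (0.0316, 0.8431)  -> replicates of one individual are far more similar
```

The same-family wGRR (~90) reflects the planted within-family protein
identity of 0.90; the per-size cutoffs sit just below the weakest
within-family score, so every same-family fragment is recovered while
cross-family scores (0 after the e-value filter) never pass. In the
replicate community, mean Bray–Curtis between replicates of one individual
(0.03) is ~27× smaller than between individuals (0.84), the signature of a
reproducible isolation protocol.

## Command line

```bash
phageome simulate  --outdir fixtures --seed 42         # synthetic inputs
phageome calibrate --ref-fasta fixtures/ref_proteins.fasta \
                   --ref-meta fixtures/ref_phages.tsv \
                   --hits fixtures/ref_hits.tsv --out curves.json
phageome wgrr      --query-fasta fixtures/contigs.fasta \
                   --ref-fasta fixtures/ref_proteins.fasta \
                   --hits fixtures/contig_hits.tsv --out wgrr.tsv
phageome classify  --contigs fixtures/contigs.fasta --curves curves.json \
                   --wgrr wgrr.tsv --ref-meta fixtures/ref_phages.tsv \
                   --categories fixtures/categories.tsv \
                   --lifestyle fixtures/lifestyle.tsv --out classes.tsv
phageome diversity --counts fixtures/counts.tsv --outdir div --seed 42
```

Exit codes: 0 success, 1 usage error, 2 invalid input, 3 unattainable
calibration. All outputs are byte-identical on re-run with the same seed.

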