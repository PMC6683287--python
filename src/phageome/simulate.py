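"""Seeded synthetic fixtures for every stage of the toolkit.

Three generators, all pure functions of their parameters and a seed:

* :func:`make_reference_db` — a reference phage database with planted
  family / lifestyle / host structure and the matching protein-vs-protein
  hit table, for calibrating wGRR cutoffs.  Homologous proteins are paired
  positionally; identities are drawn around ``within_identity`` for
  same-family pairs and ``between_identity`` across families.  The hit
  e-value is a deterministic function of identity
  (``1e1 * 1e-40^identity``), so low-identity cross-family alignments fail
  the 1e-5 BBH filter, as insignificant alignments would.
* :func:`make_evidence_fixture` — evidence bundles constructed to yield a
  requested class under the default precedence, with truth labels.
* :func:`make_count_matrix` / :func:`make_mda_panel` — replicate count
  matrices emulating the 3-individuals x 3-replicates x {no MDA, short
  MDA, long MDA} design: log-normal per-individual abundance profiles
  shared across replicates, multinomial read sampling, and an MDA bias
  planted as per-sample contig dropout plus multiplicative amplification
  of ssDNA-tagged contigs.

Protein sequences are never simulated (identities are the model); the
FASTA emitted for the fixtures carries placeholder residues and exists to
exercise the readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CutoffCurve, cutoff_for_size, fragment_genome
from .classify import (
    BestHit,
    CLASS_BACTERIA,
    CLASS_CONTAMINATION,
    CLASS_NA,
    CLASS_PHAGE,
    CLASS_PUTATIVE,
    EvidenceBundle,
    LifestyleEvidence,
    PHAGE_REF_DB,
)
from .wgrr import HitTable, InputError, PairwiseHit, ProteinRepertoire

FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae", "Inoviridae")
SSDNA_FAMILIES = frozenset({"Microviridae", "Inoviridae"})
HOST_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Fusobacteria",
)
LIFESTYLES = ("temperate", "virulent")
CONTAMINANT_CHOICES = ("human", "archaea", "eukaryota", "eukaryotic_virus")

MDA_MODES = ("none", "short", "long")
MODE_LABELS = {"none": "S", "short": "SP30", "long": "SP90"}
DROPOUT_BY_MODE = {"none": 0.0, "short": 0.2, "long": 0.4}
INDIVIDUAL_NAMES = ("AA", "BB", "CC")


@dataclass(frozen=True)
class ReferencePhage:
    """A labelled element of a reference (pro)phage database."""

    phage_id: str
    family: str
    lifestyle: str
    host_phylum: str
    nucleic_acid: str  # ssDNA / dsDNA
    repertoire: ProteinRepertoire
    database_tag: str = PHAGE_REF_DB


@dataclass
class SyntheticReferenceDB:
    """A planted reference database plus its protein hit table."""

    phages: list[ReferencePhage]
    hits: list[PairwiseHit]

    def protein_to_element(self) -> dict[str, str]:
        return {
            pid: phage.repertoire.element_id
            for phage in self.phages
            for pid in phage.repertoire.protein_ids
        }

    def hit_table(self) -> HitTable:
        return HitTable(self.hits, self.protein_to_element())

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phage_id": p.phage_id,
                    "family": p.family,
                    "lifestyle": p.lifestyle,
                    "host_phylum": p.host_phylum,
                    "nucleic_acid": p.nucleic_acid,
                    "database_tag": p.database_tag,
                    "n_proteins": p.repertoire.n_proteins,
                }
                for p in self.phages
            ]
        )


def _identity_evalue(identity: float) -> float:
    # Significance scales with identity: 0.05 -> 1e-1 (fails the 1e-5
    # filter), 0.2 -> 1e-7, 0.9 -> 1e-35.
    return 10.0 ** (-(40.0 * identity - 1.0))


def make_reference_db(
    n_families: int = 2,
    phages_per_family: int = 10,
    genes_per_phage: tuple[int, int] = (30, 80),
    within_identity: float = 0.90,
    between_identity: float = 0.05,
    identity_sd: float = 0.03,
    between_identity_sd: float = 0.01,
    seed: int = 0,
    database_tag: str = PHAGE_REF_DB,
) -> SyntheticReferenceDB:
    """Reference database with planted family structure.

    Same-family protein pairs share identities around ``within_identity``;
    cross-family pairs around ``between_identity`` (drawn once per
    unordered pair and emitted in both directions).  Host phylum and
    lifestyle are planted per family so each attribute carries signal.
    """
    if not 0 < between_identity < within_identity <= 1.0:
        raise InputError(
            f"need 0 < between_identity < within_identity <= 1, got "
            f"({within_identity}, {between_identity})"
        )
    if n_families > len(FAMILIES):
        raise InputError(f"at most {len(FAMILIES)} families supported")
    rng = np.random.default_rng(seed)
    lo, hi = genes_per_phage
    phages: list[ReferencePhage] = []
    for f in range(n_families):
        family = FAMILIES[f]
        for p in range(phages_per_family):
            pid = f"{family[:4]}F{f + 1}P{p + 1}"
            n_genes = int(rng.integers(lo, hi + 1))
            proteins = tuple(f"{pid}_{g + 1}" for g in range(n_genes))
            phages.append(
                ReferencePhage(
                    phage_id=pid,
                    family=family,
                    lifestyle=LIFESTYLES[f % len(LIFESTYLES)],
                    host_phylum=HOST_PHYLA[f % len(HOST_PHYLA)],
                    nucleic_acid="ssDNA" if family in SSDNA_FAMILIES else "dsDNA",
                    repertoire=ProteinRepertoire(pid, proteins),
                    database_tag=database_tag,
                )
            )
    hits: list[PairwiseHit] = []
    for i, a in enumerate(phages):
        for b in phages[i + 1 :]:
            same_family = a.family == b.family
            base = within_identity if same_family else between_identity
            spread = identity_sd if same_family else between_identity_sd
            # Homology is positional on a circular gene order: gene g of the
            # longer genome pairs with gene g mod n of the shorter, so every
            # gene (hence every fragment window) has a homolog in every
            # other genome.  Both hit directions are emitted.
            long_rep, short_rep = a.repertoire, b.repertoire
            if long_rep.n_proteins < short_rep.n_proteins:
                long_rep, short_rep = short_rep, long_rep
            identities = np.clip(
                rng.normal(base, spread, size=long_rep.n_proteins), 0.01, 1.0
            ).round(6)
            for g in range(long_rep.n_proteins):
                ident = float(identities[g])
                evalue = _identity_evalue(ident)
                bitscore = round(400.0 * ident, 1)
                ql = long_rep.protein_ids[g]
                qs = short_rep.protein_ids[g % short_rep.n_proteins]
                hits.append(PairwiseHit(ql, qs, ident, evalue, bitscore))
                hits.append(PairwiseHit(qs, ql, ident, evalue, bitscore))
    return SyntheticReferenceDB(phages, hits)


def make_evidence_fixture(
    db: SyntheticReferenceDB,
    curves: Mapping[tuple[str, str], CutoffCurve],
    contigs_per_class: Mapping[str, int],
    seed: int = 0,
) -> tuple[list[EvidenceBundle], dict[str, str]]:
    """Evidence bundles constructed to classify as requested.

    Returns (bundles, truth) where truth maps contig id to the class the
    bundle was built to produce under the default precedence.
    """
    rng = np.random.default_rng(seed)
    family_curve = curves[(PHAGE_REF_DB, "family")]
    bundles: list[EvidenceBundle] = []
    truth: dict[str, str] = {}
    counter = 0
    for klass in sorted(contigs_per_class):
        for _ in range(int(contigs_per_class[klass])):
            counter += 1
            cid = f"ctg{counter:04d}"
            n = int(rng.integers(3, 31))
            bundle = EvidenceBundle(contig_id=cid, n_proteins=n)
            if klass == CLASS_PHAGE:
                ref = db.phages[int(rng.integers(0, len(db.phages)))]
                cutoff = cutoff_for_size(family_curve, n)
                wgrr = float(min(100.0, cutoff + rng.uniform(5.0, 15.0)))
                bundle.best_wgrr_hits[PHAGE_REF_DB] = BestHit(
                    ref.phage_id, wgrr, ref.family, ref.lifestyle, ref.host_phylum
                )
                if n > 19:
                    means = (0.8, 0.2) if ref.lifestyle == "virulent" else (0.2, 0.8)
                    bundle.lifestyle_probs = LifestyleEvidence(*means, 0.05)
            elif klass == CLASS_PUTATIVE:
                bundle.phage_signal_category = int(rng.integers(1, 7))
                ref = db.phages[int(rng.integers(0, len(db.phages)))]
                cutoff = cutoff_for_size(family_curve, n)
                # below-threshold hit: phage signal, but no family call
                bundle.best_wgrr_hits[PHAGE_REF_DB] = BestHit(
                    ref.phage_id,
                    max(0.0, 0.3 * cutoff),
                    ref.family,
                    ref.lifestyle,
                    ref.host_phylum,
                )
            elif klass == CLASS_BACTERIA:
                if rng.uniform() < 0.5:
                    bundle.bacterial_marker_hits = int(rng.integers(1, 6))
                else:
                    bundle.has_16s = True
            elif klass == CLASS_CONTAMINATION:
                taxon = CONTAMINANT_CHOICES[int(rng.integers(0, 4))]
                bundle.nt_hits.append((taxon, float(rng.uniform(0.91, 1.0))))
            elif klass == CLASS_NA:
                if rng.uniform() < 0.3:  # sub-coverage nt hit stays NA
                    bundle.nt_hits.append(("human", float(rng.uniform(0.1, 0.5))))
            else:
                raise InputError(f"unknown class {klass!r}")
            bundles.append(bundle)
            truth[cid] = klass
    return bundles, truth


@dataclass(frozen=True)
class ContigFixture:
    """Synthetic contigs derived from a reference db, with hit files."""

    repertoires: list[ProteinRepertoire]
    hits: list[PairwiseHit]  # contig <-> reference, both directions
    categories: dict[str, int]  # phage-signal categories for some contigs
    lifestyle_rows: pd.DataFrame  # contig_id, p_virulent, p_temperate replicates
    truth: pd.DataFrame  # contig_id, source_phage, family, size


def make_contig_fixture(
    db: SyntheticReferenceDB,
    n_fragments_per_phage: int = 2,
    fragment_sizes: Sequence[int] = (5, 10, 20, 40),
    n_na_contigs: int = 10,
    n_lifestyle_replicates: int = 10,
    seed: int = 0,
) -> ContigFixture:
    """Contigs as genome fragments plus unclassifiable contigs.

    Fragment contigs inherit their source phage's hits (restricted to the
    window, protein ids renamed to the contig convention) plus identity-1
    hits to the source itself.  NA contigs encode proteins with no hits.
    """
    rng = np.random.default_rng(seed)
    hit_lookup: dict[tuple[str, str], PairwiseHit] = {
        (h.query, h.subject): h for h in db.hits
    }
    repertoires: list[ProteinRepertoire] = []
    hits: list[PairwiseHit] = []
    categories: dict[str, int] = {}
    lifestyle_rows: list[dict] = []
    truth_rows: list[dict] = []
    counter = 0
    for phage in db.phages:
        rep = phage.repertoire
        for _ in range(n_fragments_per_phage):
            usable = [s for s in fragment_sizes if s <= rep.n_proteins]
            if not usable:
                continue
            size = int(usable[int(rng.integers(0, len(usable)))])
            frag = fragment_genome(rep, size, rng)
            counter += 1
            cid = f"ctg{counter:04d}"
            proteins = tuple(f"{cid}_{i + 1}" for i in range(size))
            repertoires.append(ProteinRepertoire(cid, proteins))
            for i, source_pid in enumerate(frag.protein_ids):
                # identical to its source protein
                hits.append(PairwiseHit(proteins[i], source_pid, 1.0, 1e-50, 400.0))
                hits.append(PairwiseHit(source_pid, proteins[i], 1.0, 1e-50, 400.0))
                for other in db.phages:
                    if other.phage_id == phage.phage_id:
                        continue
                    gene_index = (frag.start + i) % other.repertoire.n_proteins
                    other_pid = other.repertoire.protein_ids[gene_index]
                    src_hit = hit_lookup.get((source_pid, other_pid))
                    if src_hit is None:
                        continue
                    hits.append(src_hit._replace(query=proteins[i]))
                    hits.append(
                        hit_lookup[(other_pid, source_pid)]._replace(
                            subject=proteins[i]
                        )
                    )
            if rng.uniform() < 0.5:
                categories[cid] = int(rng.integers(1, 7))
            if size > 19:
                base = 0.75 if phage.lifestyle == "virulent" else 0.25
                for _ in range(n_lifestyle_replicates):
                    p_vir = float(np.clip(rng.normal(base, 0.05), 0.0, 1.0))
                    lifestyle_rows.append(
                        {
                            "contig_id": cid,
                            "p_virulent": round(p_vir, 6),
                            "p_temperate": round(1.0 - p_vir, 6),
                        }
                    )
            truth_rows.append(
                {
                    "contig_id": cid,
                    "source_phage": phage.phage_id,
                    "family": phage.family,
                    "size": size,
                }
            )
    for _ in range(n_na_contigs):
        counter += 1
        cid = f"ctg{counter:04d}"
        n = int(rng.integers(3, 9))
        repertoires.append(
            ProteinRepertoire(cid, tuple(f"{cid}_{i + 1}" for i in range(n)))
        )
        truth_rows.append(
            {"contig_id": cid, "source_phage": None, "family": None, "size": n}
        )
    return ContigFixture(
        repertoires=repertoires,
        hits=hits,
        categories=categories,
        lifestyle_rows=pd.DataFrame(
            lifestyle_rows, columns=["contig_id", "p_virulent", "p_temperate"]
        ),
        truth=pd.DataFrame(
            truth_rows, columns=["contig_id", "source_phage", "family", "size"]
        ),
    )


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the synthetic replicate community.

    Defaults mirror the target replicate design: 3 individuals x 3
    replicates, a 6,056-contig reference catalog, 716,808 reads per sample
    (the rarefaction depth), log-normal abundance profiles.  MDA bias is
    planted as per-sample contig dropout (0.2 short, 0.4 long by default)
    plus a x50 amplification of ssDNA-tagged contigs (5% of the catalog).
    """

    n_individuals: int = 3
    n_replicates: int = 3
    n_contigs: int = 6056
    reads_per_sample: int = 716_808
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    mda_mode: str = "none"
    mda_dropout: Optional[float] = None  # None -> per-mode default
    mda_ssdna_boost: float = 50.0
    ssdna_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mda_mode not in MDA_MODES:
            raise InputError(f"mda_mode must be one of {MDA_MODES}")
        for name in ("mda_dropout", "ssdna_fraction"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_individuals", "n_replicates", "n_contigs", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")

    def dropout_for(self, mode: str) -> float:
        if self.mda_dropout is not None:
            return self.mda_dropout
        return DROPOUT_BY_MODE[mode]


def _individual_name(i: int) -> str:
    return INDIVIDUAL_NAMES[i] if i < len(INDIVIDUAL_NAMES) else f"ID{i + 1}"


def make_mda_panel(
    spec: CommunitySpec,
    modes: Sequence[str] = MDA_MODES,
) -> tuple[pd.DataFrame, dict]:
    """Count matrix across amplification modes with shared profiles.

    The same per-individual abundance profile underlies every mode (the
    faecal sample is split before amplification), so mode effects are
    attributable to the planted MDA bias alone.  Returns (matrix, truth)
    where truth records the ssDNA contigs and each sample's individual and
    mode.
    """
    for mode in modes:
        if mode not in MDA_MODES:
            raise InputError(f"unknown MDA mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_contigs
    contig_ids = [f"ctg{j + 1:05d}" for j in range(n)]
    n_ssdna = int(round(spec.ssdna_fraction * n))
    ssdna_idx = rng.choice(n, size=n_ssdna, replace=False)
    ssdna_mask = np.zeros(n, dtype=bool)
    ssdna_mask[ssdna_idx] = True
    profiles = {
        _individual_name(i): rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, n)
        for i in range(spec.n_individuals)
    }
    columns: dict[str, np.ndarray] = {}
    sample_individual: dict[str, str] = {}
    sample_mode: dict[str, str] = {}
    for ind, profile in profiles.items():
        for mode in modes:
            dropout = spec.dropout_for(mode)
            for rep in range(spec.n_replicates):
                weights = profile.copy()
                if mode != "none":
                    n_drop = int(round(dropout * n))
                    if n_drop:
                        dropped = rng.choice(n, size=n_drop, replace=False)
                        weights[dropped] = 0.0
                    weights[ssdna_mask] *= spec.mda_ssdna_boost
                sample = f"{ind}_{MODE_LABELS[mode]}_{rep + 1}"
                counts = rng.multinomial(
                    spec.reads_per_sample, weights / weights.sum()
                )
                columns[sample] = counts
                sample_individual[sample] = ind
                sample_mode[sample] = mode
    matrix = pd.DataFrame(columns, index=contig_ids)
    truth = {
        "ssdna_contigs": [contig_ids[j] for j in sorted(ssdna_idx.tolist())],
        "individual_of_sample": sample_individual,
        "mode_of_sample": sample_mode,
    }
    return matrix, truth


def make_count_matrix(spec: CommunitySpec) -> tuple[pd.DataFrame, dict]:
    """Count matrix for a single amplification mode (``spec.mda_mode``)."""
    return make_mda_panel(spec, modes=(spec.mda_mode,))
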