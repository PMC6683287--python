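"""Decision algorithm for contig classification.

Each contig is sorted into one of five classes — phage with family,
putative phage, bacteria, contamination, or non-attributable (NA) — from
the evidence gathered about it:

* best wGRR hits against the reference (pro)phage databases, thresholded
  by the size-calibrated cutoff curves (family/lifestyle/host);
* a phage-signal category (Virsorter-style, 1-6; all six categories count
  for contigs) and optional phage marker-gene hits;
* bacterial marker-profile hits and 16S matches;
* nucleotide hits to human / archaeal / eukaryotic (virus) sequences with
  query coverage above 90%.

The default precedence is phage-with-family > putative phage > bacteria >
contamination > NA; the order is configurable, and
:func:`audit_conflicts` lists the contigs whose class could change under a
different order (those carrying evidence of more than one kind).

Lifestyle is predicted from replicate lifestyle probabilities (PHACTS
style) for contigs encoding more than 19 proteins — confident when the
winning mean is at least two SDs of its replicate scores away from the
other mean — and from the best wGRR hit (always non-confident) for shorter
contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .calibration import CutoffCurve, cutoff_for_size
from .wgrr import InputError, ProteinRepertoire

logger = logging.getLogger(__name__)

PHAGE_REF_DB = "phage_ref"
PROPHAGE_DBS = ("phage_ref", "prophage_complete", "prophage_draft")

#: Minimum ORF count for a contig to enter the analysis.
DEFAULT_MIN_ORFS = 3

#: Contigs with MORE than this many proteins use the replicate-probability
#: lifestyle prediction; shorter contigs fall back to the wGRR best hit.
LIFESTYLE_PROTEIN_MIN = 19

#: Taxonomy labels counted as non-bacterial contamination.
CONTAMINANT_TAXA = frozenset({"human", "archaea", "eukaryota", "eukaryotic_virus"})

#: Minimum query coverage for a nucleotide hit to count as contamination.
CONTAMINATION_COVERAGE_MIN = 0.9

#: Phage-signal categories excluded when building reference *prophage*
#: databases (they often flag other mobile elements); for contig
#: classification all six categories count.
REFERENCE_PROPHAGE_EXCLUDED_CATEGORIES = frozenset({3, 6})

CLASS_PHAGE = "phage_with_family"
CLASS_PUTATIVE = "putative_phage"
CLASS_BACTERIA = "bacteria"
CLASS_CONTAMINATION = "contamination"
CLASS_NA = "NA"

DEFAULT_PRECEDENCE: tuple[str, ...] = (
    CLASS_PHAGE,
    CLASS_PUTATIVE,
    CLASS_BACTERIA,
    CLASS_CONTAMINATION,
)

LIFESTYLE_UNCLASSIFIED = "unclassified"


class LifestyleEvidence(NamedTuple):
    """Replicate-averaged lifestyle probabilities for one contig.

    ``sd_predicted`` is the sample SD of the predicted class's replicate
    probability scores.
    """

    mean_virulent: float
    mean_temperate: float
    sd_predicted: float


class BestHit(NamedTuple):
    """Best wGRR hit of a contig in one reference database."""

    hit_id: str
    wgrr: float
    family: Optional[str] = None
    lifestyle: Optional[str] = None
    host_phylum: Optional[str] = None


@dataclass
class EvidenceBundle:
    """Everything the decision algorithm consumes for one contig."""

    contig_id: str
    n_proteins: int
    phage_signal_category: Optional[int] = None
    best_wgrr_hits: dict[str, BestHit] = field(default_factory=dict)
    bacterial_marker_hits: int = 0
    has_16s: bool = False
    nt_hits: list[tuple[str, float]] = field(default_factory=list)
    lifestyle_probs: Optional[LifestyleEvidence] = None
    phage_marker_hits: int = 0

    def __post_init__(self) -> None:
        if self.phage_signal_category is not None and not (
            1 <= self.phage_signal_category <= 6
        ):
            raise InputError(
                f"{self.contig_id}: phage signal category "
                f"{self.phage_signal_category} outside 1-6"
            )
        for hit in self.best_wgrr_hits.values():
            if not 0.0 <= hit.wgrr <= 100.0:
                raise InputError(
                    f"{self.contig_id}: wGRR {hit.wgrr} outside [0, 100]"
                )
        for taxon, coverage in self.nt_hits:
            if not 0.0 <= coverage <= 1.0:
                raise InputError(
                    f"{self.contig_id}: nt-hit coverage {coverage} outside [0, 1]"
                )


@dataclass(frozen=True)
class Classification:
    contig_id: str
    klass: str
    family: Optional[str] = None
    lifestyle: str = LIFESTYLE_UNCLASSIFIED
    host_phylum: Optional[str] = None
    best_hit: Optional[str] = None
    best_wgrr: Optional[float] = None
    cutoff_used: Optional[float] = None


CurveSet = Mapping[tuple[str, str], CutoffCurve]


def get_curve(curves: CurveSet, database: str, attribute: str) -> Optional[CutoffCurve]:
    return curves.get((database, attribute))


def filter_contigs(
    contigs: Sequence[ProteinRepertoire], min_orfs: int = DEFAULT_MIN_ORFS
) -> list[ProteinRepertoire]:
    """Keep contigs with at least ``min_orfs`` (complete) ORFs, order kept."""
    if min_orfs < 1:
        raise InputError(f"min_orfs must be >= 1, got {min_orfs}")
    return [c for c in contigs if c.n_proteins >= min_orfs]


def assign_family(ev: EvidenceBundle, curves: CurveSet) -> Optional[str]:
    """Family of the best phage-reference hit if above the size cutoff.

    Families come from the phage reference database only; prophage
    databases never contribute a family label.
    """
    curve = get_curve(curves, PHAGE_REF_DB, "family")
    hit = ev.best_wgrr_hits.get(PHAGE_REF_DB)
    if curve is None or hit is None or hit.family is None:
        return None
    if hit.wgrr >= cutoff_for_size(curve, ev.n_proteins):
        return hit.family
    return None


def assign_lifestyle(ev: EvidenceBundle, curves: CurveSet) -> str:
    """Lifestyle label with confidence qualifier.

    Contigs with more than :data:`LIFESTYLE_PROTEIN_MIN` proteins use the
    replicate probabilities: predicted class = argmax of the two means,
    confident iff |mean_predicted - mean_other| >= 2 * sd_predicted.
    Shorter contigs (or contigs without probabilities) use the best
    phage-reference hit's lifestyle when it clears the lifestyle cutoff,
    always labelled non-confident.
    """
    if ev.n_proteins > LIFESTYLE_PROTEIN_MIN and ev.lifestyle_probs is not None:
        lp = ev.lifestyle_probs
        if lp.mean_virulent > lp.mean_temperate:
            predicted, other = "virulent", lp.mean_temperate
            mean_pred = lp.mean_virulent
        else:  # tie goes to temperate, the dominant gut-phage lifestyle
            predicted, other = "temperate", lp.mean_virulent
            mean_pred = lp.mean_temperate
        confident = abs(mean_pred - other) >= 2.0 * lp.sd_predicted
        return f"{predicted}_{'confident' if confident else 'nonconfident'}"
    curve = get_curve(curves, PHAGE_REF_DB, "lifestyle")
    hit = ev.best_wgrr_hits.get(PHAGE_REF_DB)
    if curve is not None and hit is not None and hit.lifestyle is not None:
        if hit.wgrr >= cutoff_for_size(curve, ev.n_proteins):
            return f"{hit.lifestyle}_nonconfident"
    return LIFESTYLE_UNCLASSIFIED


def assign_host(ev: EvidenceBundle, curves: CurveSet) -> Optional[str]:
    """Host phylum from any above-threshold database hit.

    One above-threshold hit in one database suffices; when two or more
    databases give above-threshold hits with different phyla the contig is
    left without a host (contradiction rule).
    """
    phyla: list[str] = []
    for db, hit in sorted(ev.best_wgrr_hits.items()):
        if hit.host_phylum is None:
            continue
        curve = get_curve(curves, db, "host_phylum") or get_curve(curves, db, "host")
        if curve is None:
            continue
        if hit.wgrr >= cutoff_for_size(curve, ev.n_proteins):
            phyla.append(hit.host_phylum)
    if not phyla:
        return None
    if len(set(phyla)) > 1:
        return None
    return phyla[0]


def _has_contamination_evidence(ev: EvidenceBundle) -> bool:
    found = False
    for taxon, coverage in ev.nt_hits:
        if coverage <= CONTAMINATION_COVERAGE_MIN:
            continue
        if taxon in CONTAMINANT_TAXA:
            found = True
        else:
            logger.info(
                "%s: nt hit with unknown taxonomy label %r treated as "
                "non-contaminant",
                ev.contig_id,
                taxon,
            )
    return found


def evidence_flags(
    ev: EvidenceBundle, curves: CurveSet, use_phage_markers: bool = False
) -> dict[str, bool]:
    """Presence of each of the four evidence families for one contig."""
    return {
        CLASS_PHAGE: assign_family(ev, curves) is not None,
        CLASS_PUTATIVE: ev.phage_signal_category is not None
        or (use_phage_markers and ev.phage_marker_hits > 0),
        CLASS_BACTERIA: ev.bacterial_marker_hits >= 1 or ev.has_16s,
        CLASS_CONTAMINATION: _has_contamination_evidence(ev),
    }


def classify_contig(
    ev: EvidenceBundle,
    curves: CurveSet,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    use_phage_markers: bool = False,
) -> Classification:
    """Classify one contig by the first evidence class in ``precedence``.

    Total and deterministic: every bundle yields exactly one class
    (:data:`CLASS_NA` when no evidence is present).  Lifestyle and host are
    filled only for phage classes.
    """
    if set(precedence) != set(DEFAULT_PRECEDENCE):
        raise InputError(
            f"precedence must be a permutation of {DEFAULT_PRECEDENCE}, "
            f"got {tuple(precedence)}"
        )
    flags = evidence_flags(ev, curves, use_phage_markers)
    klass = CLASS_NA
    for candidate in precedence:
        if flags[candidate]:
            klass = candidate
            break

    family = None
    lifestyle = LIFESTYLE_UNCLASSIFIED
    host = None
    best_hit = best_wgrr = cutoff = None
    if klass == CLASS_PHAGE:
        family = assign_family(ev, curves)
    if klass in (CLASS_PHAGE, CLASS_PUTATIVE):
        lifestyle = assign_lifestyle(ev, curves)
        host = assign_host(ev, curves)
    hit = ev.best_wgrr_hits.get(PHAGE_REF_DB)
    curve = get_curve(curves, PHAGE_REF_DB, "family")
    if hit is not None:
        best_hit, best_wgrr = hit.hit_id, hit.wgrr
    if curve is not None:
        cutoff = cutoff_for_size(curve, ev.n_proteins)
    return Classification(
        contig_id=ev.contig_id,
        klass=klass,
        family=family,
        lifestyle=lifestyle,
        host_phylum=host,
        best_hit=best_hit,
        best_wgrr=best_wgrr,
        cutoff_used=cutoff,
    )


def classify_all(
    bundles: Iterable[EvidenceBundle],
    curves: CurveSet,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    use_phage_markers: bool = False,
) -> list[Classification]:
    return [
        classify_contig(ev, curves, precedence, use_phage_markers) for ev in bundles
    ]


def audit_conflicts(
    bundles: Iterable[EvidenceBundle],
    curves: CurveSet,
    use_phage_markers: bool = False,
) -> pd.DataFrame:
    """Contigs carrying evidence of more than one class.

    Only these contigs can change class under an alternative precedence
    order; the robustness claim (the decision order has little
    impact) is checked by counting them.  Columns: contig_id plus one
    boolean per evidence class.
    """
    rows = []
    for ev in bundles:
        flags = evidence_flags(ev, curves, use_phage_markers)
        if sum(flags.values()) >= 2:
            rows.append({"contig_id": ev.contig_id, **flags})
    return pd.DataFrame(
        rows, columns=["contig_id", *DEFAULT_PRECEDENCE]
    )
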