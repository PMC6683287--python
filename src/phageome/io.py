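"""Readers and writers for the tabular formats the toolkit consumes.

Protein repertoires come from FASTA with the header convention
``<contig_id>_<gene_index>`` (gene order restored from the index, so
shuffled records round-trip).  Protein and nucleotide hits are 12-column
BLAST tabular (outfmt-6: qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore; pident is a percent and divided
by 100 at parse time).  Marker and 16S hits are HMMER tblout.  Cutoff
models are JSON; count matrices, categories, lifestyle replicates and
classifications are TSV.
"""

from __future__ import annotations

import json
import math
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibration import CutoffCurve
from .classify import BestHit, Classification, EvidenceBundle, LifestyleEvidence
from .wgrr import InputError, PairwiseHit, ProteinRepertoire

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def split_protein_id(protein_id: str) -> tuple[str, int]:
    """Split ``<contig_id>_<gene_index>`` into (contig_id, index)."""
    contig, _, index = protein_id.rpartition("_")
    if not contig or not index.isdigit():
        raise InputError(
            f"protein id {protein_id!r} does not follow the "
            "<contig_id>_<gene_index> convention"
        )
    return contig, int(index)


def read_protein_fasta(path: PathLike) -> list[ProteinRepertoire]:
    """Group FASTA records into per-contig repertoires, gene-index order."""
    by_contig: dict[str, dict[int, str]] = {}
    order: list[str] = []
    seen: set[str] = set()
    for row, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            contig, index = split_protein_id(record.id)
        except InputError as exc:
            raise InputError(f"{path}, record {row}: {exc}") from None
        if record.id in seen:
            raise InputError(f"{path}, record {row}: duplicate protein id {record.id!r}")
        seen.add(record.id)
        if contig not in by_contig:
            by_contig[contig] = {}
            order.append(contig)
        if index in by_contig[contig]:
            raise InputError(
                f"{path}, record {row}: duplicate gene index {index} on {contig!r}"
            )
        by_contig[contig][index] = record.id
    return [
        ProteinRepertoire(
            contig, tuple(by_contig[contig][i] for i in sorted(by_contig[contig]))
        )
        for contig in order
    ]


def write_protein_fasta(
    repertoires: Iterable[ProteinRepertoire], path: PathLike
) -> None:
    """Write placeholder-sequence FASTA (synthetic: ids carry the signal)."""
    records = [
        SeqRecord(Seq("M" + "A" * 9), id=pid, description="")
        for rep in repertoires
        for pid in rep.protein_ids
    ]
    SeqIO.write(records, str(path), "fasta")


def read_blast_hits(path: PathLike) -> list[PairwiseHit]:
    """Read 12-column BLAST tabular hits; pident percent -> fraction."""
    frame = pd.read_csv(
        path, sep="\t", names=list(BLAST_COLUMNS), comment="#", dtype={0: str, 1: str}
    )
    hits = []
    for row in frame.itertuples(index=True):
        pident = float(row.pident)
        if not 0.0 <= pident <= 100.0 or math.isnan(pident):
            raise InputError(
                f"{path}, row {row.Index}: pident {pident} outside [0, 100]"
            )
        hits.append(
            PairwiseHit(
                query=str(row.qseqid),
                subject=str(row.sseqid),
                identity=pident / 100.0,
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
        )
    return hits


def write_blast_hits(hits: Iterable[PairwiseHit], path: PathLike) -> None:
    """Write hits as 12-column BLAST tabular (alignment geometry is nominal)."""
    with open(path, "w") as fh:
        for h in hits:
            length = 100
            mismatch = int(round((1.0 - h.identity) * length))
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity * 100.0:.4f}\t{length}\t"
                f"{mismatch}\t0\t1\t{length}\t1\t{length}\t{h.evalue:.3e}\t"
                f"{h.bitscore:.1f}\n"
            )


def read_hmmer_tblout(path: PathLike) -> pd.DataFrame:
    """Minimal HMMER tblout reader: target, query, full-sequence E, score."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise InputError(f"{path}: malformed tblout line: {line.strip()!r}")
            rows.append(
                {
                    "target": fields[0],
                    "query": fields[2],
                    "evalue": float(fields[4]),
                    "score": float(fields[5]),
                }
            )
    return pd.DataFrame(rows, columns=["target", "query", "evalue", "score"])


def write_hmmer_tblout(rows: pd.DataFrame, path: PathLike) -> None:
    """Write a minimal, re-readable tblout (synthetic fixtures only)."""
    with open(path, "w") as fh:
        fh.write("# target name  accession  query name  accession  "
                 "E-value  score  bias\n")
        for row in rows.itertuples(index=False):
            fh.write(
                f"{row.target} - {row.query} - {row.evalue:.3e} "
                f"{row.score:.1f} 0.0\n"
            )


def marker_hit_counts(tblout: pd.DataFrame) -> dict[str, int]:
    """Distinct marker-profile hits per contig (GA cutoff applied upstream)."""
    counts: dict[str, set[str]] = {}
    for row in tblout.itertuples(index=False):
        contig, _ = split_protein_id(str(row.target))
        counts.setdefault(contig, set()).add(str(row.query))
    return {contig: len(profiles) for contig, profiles in counts.items()}


def contigs_with_16s(tblout: pd.DataFrame, evalue_max: float = 0.1) -> set[str]:
    """Contigs with a 16S profile hit at E <= ``evalue_max``."""
    found = set()
    for row in tblout.itertuples(index=False):
        if float(row.evalue) <= evalue_max:
            contig, _ = split_protein_id(str(row.target))
            found.add(contig)
    return found


def read_taxonomy_map(path: PathLike) -> dict[str, str]:
    """Two-column TSV: subject_id -> taxonomy label."""
    frame = pd.read_csv(path, sep="\t", names=["subject_id", "taxonomy"], dtype=str)
    return dict(zip(frame.subject_id, frame.taxonomy))


def read_contig_lengths(path: PathLike) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", names=["contig_id", "length"], dtype={0: str})
    return dict(zip(frame.contig_id, frame.length.astype(int)))


def read_nt_hits(
    path: PathLike,
    taxonomy_map: Mapping[str, str],
    contig_lengths: Mapping[str, int],
) -> dict[str, list[tuple[str, float]]]:
    """Nucleotide hits as (taxonomy label, query coverage) per contig.

    Coverage = aligned query span / contig length; subjects absent from the
    taxonomy map are skipped with a log message.
    """
    frame = pd.read_csv(path, sep="\t", names=list(BLAST_COLUMNS), comment="#",
                        dtype={0: str, 1: str})
    hits: dict[str, list[tuple[str, float]]] = {}
    for row in frame.itertuples(index=False):
        taxon = taxonomy_map.get(str(row.sseqid))
        if taxon is None:
            logger.info("nt hit subject %r has no taxonomy label; skipped", row.sseqid)
            continue
        length = contig_lengths.get(str(row.qseqid))
        if length is None or length <= 0:
            raise InputError(f"no length known for contig {row.qseqid!r}")
        coverage = min(1.0, (abs(int(row.qend) - int(row.qstart)) + 1) / length)
        hits.setdefault(str(row.qseqid), []).append((taxon, float(coverage)))
    return hits


def read_category_table(path: PathLike) -> dict[str, int]:
    """Two-column TSV: contig_id -> phage-signal category (1-6)."""
    frame = pd.read_csv(path, sep="\t", names=["contig_id", "category"], dtype={0: str})
    out = {}
    for row in frame.itertuples(index=False):
        category = int(row.category)
        if not 1 <= category <= 6:
            raise InputError(
                f"{path}: category {category} for {row.contig_id!r} outside 1-6"
            )
        out[str(row.contig_id)] = category
    return out


def write_category_table(categories: Mapping[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for contig in sorted(categories):
            fh.write(f"{contig}\t{categories[contig]}\n")


def read_lifestyle_table(path: PathLike) -> dict[str, LifestyleEvidence]:
    """Replicate lifestyle probabilities -> per-contig evidence.

    TSV columns contig_id, p_virulent, p_temperate, one row per replicate.
    The SD reported is the sample SD of the predicted (winning) class's
    replicate scores.
    """
    frame = pd.read_csv(
        path, sep="\t", names=["contig_id", "p_virulent", "p_temperate"],
        dtype={0: str}, header=0,
    )
    out: dict[str, LifestyleEvidence] = {}
    for contig, group in frame.groupby("contig_id", sort=False):
        mean_v = float(group.p_virulent.mean())
        mean_t = float(group.p_temperate.mean())
        winner = group.p_virulent if mean_v > mean_t else group.p_temperate
        sd = float(winner.std(ddof=1)) if len(winner) > 1 else 0.0
        out[str(contig)] = LifestyleEvidence(mean_v, mean_t, sd)
    return out


def write_lifestyle_table(rows: pd.DataFrame, path: PathLike) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: PathLike) -> pd.DataFrame:
    """Count matrix TSV: first column contig_id, header row of sample ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def write_count_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="contig_id")


def read_wgrr_table(path: PathLike) -> pd.DataFrame:
    """Long-form wGRR TSV: element_a, element_b, wgrr."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["element_a", "element_b", "wgrr"]
    if list(frame.columns) != expected:
        raise InputError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return frame


def write_wgrr_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_curves_json(
    curves: Mapping[tuple[str, str], CutoffCurve], path: PathLike
) -> None:
    payload = {f"{db}:{attr}": curve.to_dict() for (db, attr), curve in curves.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_curves_json(path: PathLike) -> dict[tuple[str, str], CutoffCurve]:
    with open(path) as fh:
        payload = json.load(fh)
    curves = {}
    for key, data in payload.items():
        db, _, attr = key.partition(":")
        if not attr:
            raise InputError(f"{path}: malformed curve key {key!r}")
        curves[(db, attr)] = CutoffCurve.from_dict(data)
    return curves


def read_reference_metadata(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"phage_id": str})
    required = {"phage_id", "family", "lifestyle", "host_phylum", "database_tag"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing metadata columns {sorted(missing)}")
    return frame


def write_reference_metadata(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_classifications(
    classifications: Sequence[Classification], path: PathLike
) -> None:
    frame = pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "klass": c.klass,
                "family": c.family,
                "lifestyle": c.lifestyle,
                "host_phylum": c.host_phylum,
                "best_hit": c.best_hit,
                "best_wgrr": c.best_wgrr,
                "cutoff_used": c.cutoff_used,
            }
            for c in classifications
        ]
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_classifications(path: PathLike) -> pd.DataFrame:
    # keep_default_na=False so the literal class "NA" survives the round trip
    return pd.read_csv(path, sep="\t", dtype={"contig_id": str},
                       keep_default_na=False, na_values=[""])


def assemble_evidence(
    contigs: Sequence[ProteinRepertoire],
    wgrr_table: Optional[pd.DataFrame] = None,
    reference_metadata: Optional[pd.DataFrame] = None,
    categories: Optional[Mapping[str, int]] = None,
    lifestyle: Optional[Mapping[str, LifestyleEvidence]] = None,
    marker_counts: Optional[Mapping[str, int]] = None,
    sixteen_s: Optional[Iterable[str]] = None,
    nt_hits: Optional[Mapping[str, list[tuple[str, float]]]] = None,
    phage_marker_counts: Optional[Mapping[str, int]] = None,
) -> list[EvidenceBundle]:
    """Join the per-source evidence tables into one bundle per contig.

    The best wGRR hit per reference database is the row with the highest
    wgrr (ties broken by hit id), labelled from the reference metadata.
    """
    best_hits: dict[str, dict[str, BestHit]] = {}
    if wgrr_table is not None:
        if reference_metadata is None:
            raise InputError("wGRR table given without reference metadata")
        meta = reference_metadata.set_index("phage_id")
        for row in wgrr_table.itertuples(index=False):
            contig, ref, value = str(row.element_a), str(row.element_b), float(row.wgrr)
            if ref not in meta.index:
                raise InputError(f"wGRR hit {ref!r} absent from reference metadata")
            info = meta.loc[ref]
            db = str(info["database_tag"])
            current = best_hits.setdefault(contig, {}).get(db)
            if (
                current is None
                or value > current.wgrr
                or (value == current.wgrr and ref < current.hit_id)
            ):
                best_hits[contig][db] = BestHit(
                    hit_id=ref,
                    wgrr=value,
                    family=None if pd.isna(info["family"]) else str(info["family"]),
                    lifestyle=None
                    if pd.isna(info["lifestyle"])
                    else str(info["lifestyle"]),
                    host_phylum=None
                    if pd.isna(info["host_phylum"])
                    else str(info["host_phylum"]),
                )
    sixteen = set(sixteen_s or ())
    bundles = []
    for rep in contigs:
        cid = rep.element_id
        bundles.append(
            EvidenceBundle(
                contig_id=cid,
                n_proteins=rep.n_proteins,
                phage_signal_category=(categories or {}).get(cid),
                best_wgrr_hits=best_hits.get(cid, {}),
                bacterial_marker_hits=(marker_counts or {}).get(cid, 0),
                has_16s=cid in sixteen,
                nt_hits=list((nt_hits or {}).get(cid, [])),
                lifestyle_probs=(lifestyle or {}).get(cid),
                phage_marker_hits=(phage_marker_counts or {}).get(cid, 0),
            )
        )
    return bundles


def summarize_read_weights(
    classifications: Union[Sequence[Classification], Mapping[str, str]],
    count_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample fraction of reads mapping contigs of each class.

    Contigs in the matrix without a classification are counted as NA (and
    logged); zero-read samples yield NaN fractions.  Fractions sum to 1
    per non-empty sample.
    """
    if isinstance(classifications, Mapping):
        class_of = dict(classifications)
    else:
        class_of = {c.contig_id: c.klass for c in classifications}
    missing = [cid for cid in count_matrix.index if cid not in class_of]
    if missing:
        logger.info(
            "%d contigs in the count matrix lack a classification; counted as NA",
            len(missing),
        )
    labels = pd.Series(
        [class_of.get(cid, "NA") for cid in count_matrix.index],
        index=count_matrix.index,
    )
    by_class = count_matrix.groupby(labels).sum()
    totals = by_class.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = by_class.div(totals.where(totals > 0), axis=1)
    return fractions


def write_json(payload: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
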