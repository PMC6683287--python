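"""Weighted gene repertoire relatedness (wGRR) between protein repertoires.

The wGRR between two genetic elements A and B is

    wGRR(A, B) = 100 * sum_i id(A_i, B_i) / min(|A|, |B|)

where the sum runs over the bidirectional best hits (BBHs) between the
proteins of A and B, ``id`` is the fractional sequence identity of pair i,
and ``|A|``, ``|B|`` are the numbers of proteins encoded by each element.
It measures the identity-weighted fraction of homologs in the smaller of
the two elements and takes values in [0, 100]: 0 for elements with no
significant homologs, 100 for identical gene repertoires.

Hits are consumed as precomputed protein-vs-protein alignments (the
BLAST tabular dialect, see :mod:`phageome.io`); this module never runs an
aligner.  A hit enters BBH resolution only when its e-value is *below*
``evalue_max`` (default 1e-5).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

DEFAULT_EVALUE_MAX = 1e-5


class InputError(ValueError):
    """A malformed input row, identifier or table."""


class PairwiseHit(NamedTuple):
    """One directional protein-vs-protein alignment.

    ``identity`` is a fraction in [0, 1] (percent identities are divided
    by 100 at parse time, see :func:`phageome.io.read_blast_hits`).
    """

    query: str
    subject: str
    identity: float
    evalue: float
    bitscore: float = 0.0


class BbhPair(NamedTuple):
    """A reciprocal best hit; identity is the mean of the two directions."""

    protein_a: str
    protein_b: str
    identity: float


@dataclass(frozen=True)
class ProteinRepertoire:
    """The ordered set of proteins encoded by one contig or (pro)phage."""

    element_id: str
    protein_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))
        if not self.protein_ids:
            raise InputError(f"repertoire {self.element_id!r} has no proteins")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise InputError(
                f"duplicate protein ids in repertoire {self.element_id!r}"
            )

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


@dataclass(frozen=True)
class WgrrScore:
    """wGRR value for an (unordered) pair of elements, in [0, 100]."""

    element_a: str
    element_b: str
    value: float


def _validate_hit(hit: PairwiseHit, row: int) -> None:
    if not 0.0 <= hit.identity <= 1.0:
        raise InputError(
            f"hit row {row} ({hit.query} vs {hit.subject}): identity "
            f"{hit.identity} outside [0, 1]"
        )
    if not hit.evalue > 0.0 or math.isnan(hit.evalue):
        raise InputError(
            f"hit row {row} ({hit.query} vs {hit.subject}): e-value "
            f"{hit.evalue} is not positive"
        )


def _hit_rank(hit: PairwiseHit) -> tuple:
    # Best hit = highest bitscore, then lowest e-value, then highest
    # identity, then lexicographically smallest subject id (deterministic).
    return (-hit.bitscore, hit.evalue, -hit.identity, hit.subject)


def _best_by_query(
    hits: Iterable[PairwiseHit], evalue_max: float
) -> dict[str, PairwiseHit]:
    best: dict[str, PairwiseHit] = {}
    for row, hit in enumerate(hits):
        _validate_hit(hit, row)
        if hit.evalue >= evalue_max:
            continue
        if hit.query == hit.subject:  # self-hit, ignored in cross comparisons
            continue
        current = best.get(hit.query)
        if current is None or _hit_rank(hit) < _hit_rank(current):
            best[hit.query] = hit
    return best


def resolve_bbh(
    hits_ab: Iterable[PairwiseHit],
    hits_ba: Iterable[PairwiseHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[BbhPair]:
    """Bidirectional best hits between two protein sets.

    ``hits_ab`` are A-vs-B alignments (query in A), ``hits_ba`` the reverse
    direction.  Hits with e-value >= ``evalue_max`` are discarded first.
    A pair (a, b) is returned iff b is a's best subject AND a is b's best
    subject (strict reciprocity: a missing reverse hit breaks the pair).
    When the two directional identities differ the pair's identity is their
    arithmetic mean.
    """
    best_ab = _best_by_query(hits_ab, evalue_max)
    best_ba = _best_by_query(hits_ba, evalue_max)
    pairs: list[BbhPair] = []
    for a in sorted(best_ab):
        ha = best_ab[a]
        hb = best_ba.get(ha.subject)
        if hb is not None and hb.subject == a:
            pairs.append(
                BbhPair(a, ha.subject, (ha.identity + hb.identity) / 2.0)
            )
    return pairs


def compute_wgrr(
    rep_a: ProteinRepertoire,
    rep_b: ProteinRepertoire,
    bbh: Sequence[BbhPair],
) -> WgrrScore:
    """Evaluate wGRR = 100 * sum(identities) / min(|A|, |B|) over BBH pairs."""
    set_a = frozenset(rep_a.protein_ids)
    set_b = frozenset(rep_b.protein_ids)
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    total = 0.0
    for pair in bbh:
        if pair.protein_a not in set_a or pair.protein_b not in set_b:
            raise InputError(
                f"BBH pair ({pair.protein_a}, {pair.protein_b}) references "
                f"proteins absent from {rep_a.element_id!r}/{rep_b.element_id!r}"
            )
        if pair.protein_a in seen_a or pair.protein_b in seen_b:
            raise InputError(
                f"protein appears in more than one BBH pair: "
                f"({pair.protein_a}, {pair.protein_b})"
            )
        seen_a.add(pair.protein_a)
        seen_b.add(pair.protein_b)
        total += pair.identity
    value = 100.0 * total / min(rep_a.n_proteins, rep_b.n_proteins)
    return WgrrScore(rep_a.element_id, rep_b.element_id, value)


class HitTable:
    """Protein hits indexed by (query element, subject element).

    Built from a flat hit list plus a protein -> element map; lets callers
    pull the directional hit lists for any element pair in O(1), including
    for genome fragments (whose proteins are a subset of their source's).
    """

    def __init__(
        self,
        hits: Iterable[PairwiseHit],
        protein_to_element: Mapping[str, str],
    ) -> None:
        self.protein_to_element = dict(protein_to_element)
        self._pairs: dict[tuple[str, str], list[PairwiseHit]] = defaultdict(list)
        for row, hit in enumerate(hits):
            _validate_hit(hit, row)
            try:
                qe = self.protein_to_element[hit.query]
                se = self.protein_to_element[hit.subject]
            except KeyError as exc:
                raise InputError(
                    f"hit row {row}: protein {exc.args[0]!r} does not belong "
                    "to any known element"
                ) from None
            self._pairs[(qe, se)].append(hit)

    @classmethod
    def from_repertoires(
        cls,
        hits: Iterable[PairwiseHit],
        repertoires: Iterable[ProteinRepertoire],
    ) -> "HitTable":
        mapping: dict[str, str] = {}
        for rep in repertoires:
            for pid in rep.protein_ids:
                if pid in mapping:
                    raise InputError(f"protein id {pid!r} occurs in two elements")
                mapping[pid] = rep.element_id
        return cls(hits, mapping)

    def between(self, element_a: str, element_b: str) -> list[PairwiseHit]:
        return self._pairs.get((element_a, element_b), [])


def wgrr_between(
    rep_a: ProteinRepertoire,
    rep_b: ProteinRepertoire,
    table: HitTable,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    *,
    source_a: Optional[str] = None,
    source_b: Optional[str] = None,
) -> WgrrScore:
    """wGRR between two repertoires using hits indexed in ``table``.

    ``source_a``/``source_b`` name the elements under which the hits were
    indexed when they differ from the repertoire ids — e.g. a genome
    fragment scores against hits recorded for its source phage, restricted
    to the fragment's own proteins.
    """
    ea = source_a if source_a is not None else rep_a.element_id
    eb = source_b if source_b is not None else rep_b.element_id
    set_a = frozenset(rep_a.protein_ids)
    set_b = frozenset(rep_b.protein_ids)
    ab = [h for h in table.between(ea, eb) if h.query in set_a and h.subject in set_b]
    ba = [h for h in table.between(eb, ea) if h.query in set_b and h.subject in set_a]
    bbh = resolve_bbh(ab, ba, evalue_max)
    return compute_wgrr(rep_a, rep_b, bbh)


def wgrr_all_pairs(
    repertoires: Sequence[ProteinRepertoire],
    table: HitTable,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[WgrrScore]:
    """wGRR over every unordered pair of the given elements."""
    scores = []
    for i, rep_a in enumerate(repertoires):
        for rep_b in repertoires[i + 1 :]:
            scores.append(wgrr_between(rep_a, rep_b, table, evalue_max))
    return scores


def wgrr_cross(
    queries: Sequence[ProteinRepertoire],
    references: Sequence[ProteinRepertoire],
    table: HitTable,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[WgrrScore]:
    """wGRR of every query element against every reference element."""
    scores = []
    for q in queries:
        for r in references:
            scores.append(wgrr_between(q, r, table, evalue_max))
    return scores


def scores_to_frame(scores: Iterable[WgrrScore]) -> pd.DataFrame:
    """Long-form table (element_a, element_b, wgrr) of wGRR scores."""
    return pd.DataFrame(
        [(s.element_a, s.element_b, s.value) for s in scores],
        columns=["element_a", "element_b", "wgrr"],
    )


class _DisjointSet:
    def __init__(self, items: Iterable[str]) -> None:
        self._parent = {i: i for i in items}

    def find(self, x: str) -> str:
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra


def cluster_by_wgrr(
    scores: Iterable[WgrrScore],
    elements: Sequence[ProteinRepertoire],
    threshold: float,
) -> dict[str, list[str]]:
    """Single-linkage clustering of elements at a wGRR threshold.

    Any pair scoring >= ``threshold`` lands in the same cluster (connected
    components of the threshold graph; an absent pair counts as wGRR 0).
    Returns ``{representative: sorted members}`` where the representative is
    the member encoding the most proteins, ties broken by lexicographically
    smallest element id.  Used to deduplicate highly similar (pro)phages,
    e.g. redundancy clustering at wGRR 95.
    """
    if not 0.0 <= threshold <= 100.0:
        raise InputError(f"threshold {threshold} outside [0, 100]")
    by_id = {rep.element_id: rep for rep in elements}
    if len(by_id) != len(elements):
        raise InputError("duplicate element ids in cluster input")
    dsu = _DisjointSet(by_id)
    for score in scores:
        if score.element_a not in by_id or score.element_b not in by_id:
            raise InputError(
                f"score references unknown element: "
                f"({score.element_a}, {score.element_b})"
            )
        if score.value >= threshold:
            dsu.union(score.element_a, score.element_b)
    groups: dict[str, list[str]] = defaultdict(list)
    for eid in by_id:
        groups[dsu.find(eid)].append(eid)
    clusters: dict[str, list[str]] = {}
    for members in groups.values():
        rep = min(members, key=lambda m: (-by_id[m].n_proteins, m))
        clusters[rep] = sorted(members)
    return clusters
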