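"""Size-calibrated wGRR classification cutoffs.

Classifying a metagenomic contig by its best wGRR hit needs a threshold
below which the best hit is no longer trustworthy.  The threshold is
derived from reference elements of known classification: the cutoff for an
attribute (family, lifestyle, host phylum) is the smallest observed wGRR
value t such that, among all reference pairs scoring >= t, at least a
target fraction (default 95%) share the attribute.

Contigs are genome fragments, and small fragments score differently from
complete genomes, so the cutoff is re-estimated on simulated contiguous
fragments of fixed gene counts (5, 10, 15, 20, 30, 40, 50 and 60 genes by
default) scored against the complete reference genomes.  A negative
exponential

    Y(X) = alpha * exp(-beta * X) + gamma

is then fitted to the per-size cutoffs, giving a threshold for any contig
as a function of X, the number of proteins of the smaller element.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .wgrr import (
    DEFAULT_EVALUE_MAX,
    HitTable,
    InputError,
    ProteinRepertoire,
    wgrr_between,
)

#: Fragment sizes (in genes) at which cutoffs are re-estimated.
FRAGMENT_SIZES: tuple[int, ...] = (5, 10, 15, 20, 30, 40, 50, 60)

DEFAULT_TARGET = 0.95


class CalibrationUnattainable(RuntimeError):
    """No usable cutoff exists for the requested attribute/database."""


class FragmentTooLarge(ValueError):
    """Requested fragment size exceeds the source genome's gene count."""


class LabelledPair(NamedTuple):
    """A wGRR value for a pair of elements of known classification."""

    wgrr: float
    same_label: bool


@dataclass(frozen=True)
class GenomeFragment:
    """A contiguous window of a source phage's gene order."""

    source_phage: str
    protein_ids: tuple[str, ...]
    start: int

    @property
    def size(self) -> int:
        return len(self.protein_ids)

    def to_repertoire(self, fragment_id: Optional[str] = None) -> ProteinRepertoire:
        fid = fragment_id or f"{self.source_phage}|frag@{self.start}"
        return ProteinRepertoire(fid, self.protein_ids)


@dataclass
class CutoffCurve:
    """Fitted size-dependent wGRR cutoff for one database x attribute.

    ``per_size_cutoffs`` maps fragment size (genes) to the empirical cutoff
    (None when unattainable at that size); (alpha, beta, gamma) parametrise
    the fitted curve Y(X) = alpha*exp(-beta*X) + gamma.
    """

    database: str
    attribute: str
    alpha: float
    beta: float
    gamma: float
    per_size_cutoffs: dict[int, Optional[float]] = field(default_factory=dict)
    target: float = DEFAULT_TARGET
    seed: Optional[int] = None

    def cutoff_for_size(self, n_proteins: int) -> float:
        return cutoff_for_size(self, n_proteins)

    def to_dict(self) -> dict:
        return {
            "database": self.database,
            "attribute": self.attribute,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "per_size_cutoffs": {str(k): v for k, v in self.per_size_cutoffs.items()},
            "target": self.target,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CutoffCurve":
        return cls(
            database=data["database"],
            attribute=data["attribute"],
            alpha=float(data["alpha"]),
            beta=float(data["beta"]),
            gamma=float(data["gamma"]),
            per_size_cutoffs={
                int(k): (None if v is None else float(v))
                for k, v in data.get("per_size_cutoffs", {}).items()
            },
            target=float(data.get("target", DEFAULT_TARGET)),
            seed=data.get("seed"),
        )


def cutoff_for_size(curve: CutoffCurve, n_proteins: int) -> float:
    """Evaluate the fitted curve at ``n_proteins``, floored at 0."""
    if n_proteins < 1:
        raise InputError(f"n_proteins must be >= 1, got {n_proteins}")
    return max(0.0, curve.alpha * math.exp(-curve.beta * n_proteins) + curve.gamma)


def concordance_cutoff(
    pairs: Sequence[LabelledPair],
    target: float = DEFAULT_TARGET,
) -> Optional[float]:
    """Smallest observed wGRR t with >= ``target`` concordance above it.

    Concordance is cumulative: among all pairs with wgrr >= t, the fraction
    with same_label must be at least ``target``.  Candidate thresholds are
    the observed wGRR values.  Returns None when no candidate attains the
    target (the "unattainable" outcome).
    """
    if not 0.0 < target <= 1.0:
        raise InputError(f"target {target} outside (0, 1]")
    if len(pairs) == 0:
        raise InputError("concordance_cutoff requires at least one pair")
    w = np.asarray([p.wgrr for p in pairs], dtype=float)
    if np.any(w < 0) or np.any(w > 100) or np.any(np.isnan(w)):
        raise InputError("wGRR values must lie in [0, 100]")
    same = np.asarray([p.same_label for p in pairs], dtype=bool)
    order = np.argsort(-w, kind="stable")
    ws, ss = w[order], same[order]
    frac = np.cumsum(ss) / np.arange(1, len(ws) + 1)
    last_of_value = np.r_[ws[1:] != ws[:-1], True]  # cumulative set per candidate
    ok = last_of_value & (frac >= target)
    if not ok.any():
        return None
    return float(ws[np.nonzero(ok)[0][-1]])


def fragment_genome(
    phage: ProteinRepertoire,
    size: int,
    rng: Union[int, np.random.Generator],
) -> GenomeFragment:
    """Draw a contiguous window of ``size`` consecutive genes.

    The start index is uniform over the valid linear positions (no circular
    wraparound).  Raises :class:`FragmentTooLarge` when the genome encodes
    fewer than ``size`` proteins, which callers treat as a skip signal.
    """
    if size < 1:
        raise InputError(f"fragment size must be >= 1, got {size}")
    if size > phage.n_proteins:
        raise FragmentTooLarge(
            f"{phage.element_id}: size {size} > {phage.n_proteins} proteins"
        )
    generator = np.random.default_rng(rng) if isinstance(rng, int) else rng
    start = int(generator.integers(0, phage.n_proteins - size + 1))
    return GenomeFragment(
        source_phage=phage.element_id,
        protein_ids=phage.protein_ids[start : start + size],
        start=start,
    )


def _attribute_of(element, attribute: str):
    value = getattr(element, attribute, None)
    if value is None:
        raise InputError(
            f"element {element.repertoire.element_id!r} lacks attribute "
            f"{attribute!r} required for calibration"
        )
    return value


def fragment_pairs(
    db: Sequence,
    table: HitTable,
    attribute: str,
    size: int,
    n_fragments_per_phage: int,
    rng: np.random.Generator,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[LabelledPair]:
    """Labelled fragment-vs-complete wGRR pairs at one fragment size.

    Every db element with at least ``size`` proteins contributes fragments;
    each fragment is scored against every *other* complete genome (its own
    source is excluded to avoid self-matching inflation).  Pairs with
    wGRR = 0 are retained.
    """
    pairs: list[LabelledPair] = []
    for phage in db:
        rep = phage.repertoire
        if size > rep.n_proteins:
            continue
        label = _attribute_of(phage, attribute)
        for _ in range(n_fragments_per_phage):
            frag = fragment_genome(rep, size, rng)
            frep = frag.to_repertoire()
            for other in db:
                if other.repertoire.element_id == rep.element_id:
                    continue
                score = wgrr_between(
                    frep,
                    other.repertoire,
                    table,
                    evalue_max,
                    source_a=rep.element_id,
                )
                pairs.append(
                    LabelledPair(score.value, label == _attribute_of(other, attribute))
                )
    return pairs


def calibrate_per_size(
    db: Sequence,
    table: HitTable,
    attribute: str,
    sizes: Sequence[int] = FRAGMENT_SIZES,
    target: float = DEFAULT_TARGET,
    n_fragments_per_phage: int = 1,
    seed: int = 42,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> dict[int, Optional[float]]:
    """Re-estimate the concordance cutoff at each fragment size.

    ``db`` elements must expose ``.repertoire`` (a ProteinRepertoire) and
    the calibrated attribute (``family``/``lifestyle``/``host_phylum``).
    Returns {size: cutoff}; the value is None when the target concordance
    is unattainable at that size, and sizes larger than every genome are
    omitted.
    """
    if not sizes:
        raise InputError("at least one fragment size is required")
    for phage in db:  # fail early on missing attributes
        _attribute_of(phage, attribute)
    rng = np.random.default_rng(seed)
    cutoffs: dict[int, Optional[float]] = {}
    for size in sizes:
        pairs = fragment_pairs(
            db, table, attribute, size, n_fragments_per_phage, rng, evalue_max
        )
        if not pairs:
            continue
        cutoffs[size] = concordance_cutoff(pairs, target)
    return cutoffs


@dataclass(frozen=True)
class CurveFit:
    alpha: float
    beta: float
    gamma: float
    rss: float
    converged: bool


def _neg_exponential(x, alpha, beta, gamma):
    return alpha * np.exp(-beta * x) + gamma


def _grid_fit(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float, float]:
    # Variable-projection fallback: for each beta on a grid, (alpha, gamma)
    # have a closed-form linear least-squares solution.
    best = (0.0, 0.0, float(np.mean(ys)), float(np.sum((ys - np.mean(ys)) ** 2)))
    for beta in np.logspace(-4, 1, 200):
        basis = np.column_stack([np.exp(-beta * xs), np.ones_like(xs)])
        coef, *_ = np.linalg.lstsq(basis, ys, rcond=None)
        resid = ys - basis @ coef
        rss = float(resid @ resid)
        if rss < best[3]:
            best = (float(coef[0]), float(beta), float(coef[1]), rss)
    return best


def fit_cutoff_curve(
    per_size_cutoffs: Mapping[int, Optional[float]],
) -> CurveFit:
    """Nonlinear least-squares fit of Y = alpha*exp(-beta*X) + gamma.

    Initialised from (max - min cutoff, 0.1, min cutoff); on
    non-convergence falls back to a beta-grid search with closed-form
    (alpha, gamma).  Requires at least three sizes with finite cutoffs.
    """
    points = sorted(
        (size, cut)
        for size, cut in per_size_cutoffs.items()
        if cut is not None and math.isfinite(cut)
    )
    if len(points) < 3:
        raise InputError(
            f"curve fit needs >= 3 finite per-size cutoffs, got {len(points)}"
        )
    xs = np.asarray([p[0] for p in points], dtype=float)
    ys = np.asarray([p[1] for p in points], dtype=float)
    p0 = (float(ys.max() - ys.min()), 0.1, float(ys.min()))
    try:
        with warnings.catch_warnings():
            # degenerate (e.g. flat) data legitimately yields a singular
            # covariance; only the point estimate is used
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_neg_exponential, xs, ys, p0=p0, maxfev=20000)
        alpha, beta, gamma = (float(v) for v in popt)
        resid = ys - _neg_exponential(xs, alpha, beta, gamma)
        return CurveFit(alpha, beta, gamma, float(resid @ resid), True)
    except RuntimeError:
        alpha, beta, gamma, rss = _grid_fit(xs, ys)
        return CurveFit(alpha, beta, gamma, rss, False)


def calibrate_database(
    db: Sequence,
    table: HitTable,
    attribute: str,
    database_tag: str,
    sizes: Sequence[int] = FRAGMENT_SIZES,
    target: float = DEFAULT_TARGET,
    n_fragments_per_phage: int = 1,
    seed: int = 42,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> CutoffCurve:
    """Full per-size calibration plus curve fit for one database/attribute.

    Raises :class:`CalibrationUnattainable` when fewer than three sizes
    yield a finite cutoff (no curve can be fitted).
    """
    per_size = calibrate_per_size(
        db, table, attribute, sizes, target, n_fragments_per_phage, seed, evalue_max
    )
    try:
        fit = fit_cutoff_curve(per_size)
    except InputError as exc:
        raise CalibrationUnattainable(
            f"{database_tag}/{attribute}: {exc}"
        ) from exc
    return CutoffCurve(
        database=database_tag,
        attribute=attribute,
        alpha=fit.alpha,
        beta=fit.beta,
        gamma=fit.gamma,
        per_size_cutoffs=dict(per_size),
        target=target,
        seed=seed,
    )


def whole_genome_pairs(
    db: Sequence,
    table: HitTable,
    attribute: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[LabelledPair]:
    """Labelled wGRR pairs over all unordered complete-genome pairs."""
    pairs: list[LabelledPair] = []
    for i, a in enumerate(db):
        la = _attribute_of(a, attribute)
        for b in db[i + 1 :]:
            score = wgrr_between(a.repertoire, b.repertoire, table, evalue_max)
            pairs.append(LabelledPair(score.value, la == _attribute_of(b, attribute)))
    return pairs
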