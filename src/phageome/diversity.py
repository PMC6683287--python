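"""Count-matrix normalization, rarefaction and diversity statistics.

Operates on a contig x sample count matrix (a pandas DataFrame with contig
ids as the index and sample ids as columns).  Implements the total-count
normalization

    S_i = sum_j a_ij,   M = mean_i(S_i),   SF_i = S_i / M

(each column divided by its size factor, so every normalized column sums
to M), without-replacement rarefaction (multivariate hypergeometric) and
its analytic expected-richness counterpart, Bray-Curtis dissimilarity
between samples, alpha/beta/gamma diversity, and the hierarchical-
clustering leaf ordering used to compare replicate samples.

Beta diversity: richness is the number of contigs with at least one read
in a sample, alpha the mean richness over samples, gamma the number of
contigs with at least one read in any sample.  The literal formula
``1 - gamma/alpha`` (beta_mode="as_printed") is non-positive whenever
gamma >= alpha, so the default mode is the turnover form
``1 - alpha/gamma``; both are available and neither is silently altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from .wgrr import InputError

BETA_MODES = ("turnover", "as_printed")


class DomainError(ValueError):
    """An operation was asked of a matrix that cannot support it."""


@dataclass(frozen=True)
class NormalizationFactors:
    column_sums: pd.Series  # S_i
    grand_mean: float  # M
    size_factors: pd.Series  # SF_i = S_i / M


@dataclass(frozen=True)
class DiversitySummary:
    richness: pd.Series  # per-sample contig counts
    alpha: float  # mean richness
    gamma: int  # contigs with >= 1 read in any sample
    beta: float
    beta_mode: str

    def to_dict(self) -> dict:
        return {
            "richness": {k: int(v) for k, v in self.richness.items()},
            "alpha": self.alpha,
            "gamma": self.gamma,
            "beta": self.beta,
            "beta_mode": self.beta_mode,
        }


@dataclass(frozen=True)
class LinkageResult:
    order: list[str]  # leaf order of the merge tree
    merges: np.ndarray  # scipy linkage matrix
    method: str


def _check_matrix(m: pd.DataFrame) -> None:
    if m.index.has_duplicates or m.columns.has_duplicates:
        raise InputError("count matrix labels must be unique")
    values = m.to_numpy()
    if values.size and (values < 0).any():
        raise InputError("count matrix must be nonnegative")


def total_count_normalize(
    m: pd.DataFrame,
) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Divide each column by its size factor S_i / M.

    Every normalized column then sums to the grand mean M, while
    within-column proportions are conserved.
    """
    _check_matrix(m)
    column_sums = m.sum(axis=0).astype(float)
    zero = column_sums[column_sums == 0]
    if len(zero):
        raise DomainError(
            f"zero-sum sample(s) cannot be normalized: {list(zero.index)}"
        )
    grand_mean = float(column_sums.mean())
    size_factors = column_sums / grand_mean
    normalized = m.astype(float).div(size_factors, axis=1)
    return normalized, NormalizationFactors(column_sums, grand_mean, size_factors)


def rarefy_subsample(
    m: pd.DataFrame,
    depth: int,
    rng: Union[int, np.random.Generator],
) -> pd.DataFrame:
    """Subsample every column to exactly ``depth`` reads without replacement.

    Each column is a multivariate-hypergeometric draw, so all rarefied
    column sums equal ``depth``; reproducible from the seed.
    """
    _check_matrix(m)
    if depth < 0:
        raise DomainError(f"depth must be >= 0, got {depth}")
    generator = np.random.default_rng(rng) if isinstance(rng, int) else rng
    out = {}
    for sample in m.columns:
        column = m[sample].to_numpy().astype(np.int64)
        total = int(column.sum())
        if depth > total:
            raise DomainError(
                f"sample {sample!r}: depth {depth} exceeds column sum {total}"
            )
        out[sample] = generator.multivariate_hypergeometric(column, depth)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def rarefy_expected_richness(
    column: Sequence[int], depth: int
) -> float:
    """Analytic expected richness of a column rarefied to ``depth`` reads.

    E[S] = sum_j [ 1 - C(S - N_j, depth) / C(S, depth) ] with S the column
    sum and N_j the count of contig j — the hypergeometric probability that
    contig j survives the subsample, summed over contigs.
    """
    counts = np.asarray(column, dtype=np.int64)
    if counts.size and (counts < 0).any():
        raise InputError("counts must be nonnegative")
    total = int(counts.sum())
    if depth < 0 or depth > total:
        raise DomainError(f"depth {depth} outside [0, column sum {total}]")
    present = counts[counts > 0]
    if depth == 0 or present.size == 0:
        return 0.0

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    remaining = total - present
    p_absent = np.where(
        remaining >= depth,
        np.exp(log_comb(remaining.astype(float), depth) - log_comb(float(total), depth)),
        0.0,
    )
    return float(np.sum(1.0 - p_absent))


def bray_curtis(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    BC(u, v) = 1 - 2 * sum_j min(u_j, v_j) / (sum_j u_j + sum_j v_j);
    symmetric, zero diagonal, values in [0, 1].  A pair of all-zero columns
    is defined as 0 with a warning.
    """
    _check_matrix(m)
    values = m.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    n = values.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = sums[i] + sums[j]
            if denom == 0:
                warnings.warn(
                    f"samples {m.columns[i]!r} and {m.columns[j]!r} are both "
                    "empty; Bray-Curtis defined as 0",
                    stacklevel=2,
                )
                bc = 0.0
            else:
                shared = np.minimum(values[:, i], values[:, j]).sum()
                bc = 1.0 - 2.0 * shared / denom
            out[i, j] = out[j, i] = bc
    return pd.DataFrame(out, index=m.columns, columns=m.columns)


def diversity_summary(
    m: pd.DataFrame, beta_mode: str = "turnover"
) -> DiversitySummary:
    """Per-sample richness plus alpha/beta/gamma diversity.

    The caller is responsible for rarefying or normalizing upstream so the
    samples are comparable.
    """
    if beta_mode not in BETA_MODES:
        raise InputError(f"beta_mode must be one of {BETA_MODES}, got {beta_mode!r}")
    _check_matrix(m)
    richness = (m > 0).sum(axis=0)
    alpha = float(richness.mean())
    gamma = int(((m > 0).any(axis=1)).sum())
    if alpha == 0 or gamma == 0:
        beta = 0.0
    elif beta_mode == "as_printed":
        beta = 1.0 - gamma / alpha
    else:
        beta = 1.0 - alpha / gamma
    return DiversitySummary(richness, alpha, gamma, beta, beta_mode)


def linkage_order(d: pd.DataFrame, method: str = "ward") -> LinkageResult:
    """Agglomerative merge tree and leaf order from a dissimilarity matrix.

    ``d`` must be square, symmetric, with a zero diagonal.  Deterministic
    given ``d``.
    """
    if d.shape[0] != d.shape[1] or list(d.index) != list(d.columns):
        raise InputError("dissimilarity matrix must be square with matching labels")
    values = d.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-12):
        raise InputError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise InputError("dissimilarity matrix must have a zero diagonal")
    if d.shape[0] < 2:
        return LinkageResult(list(d.index), np.empty((0, 4)), method)
    condensed = squareform(values, checks=False)
    merges = linkage(condensed, method=method)
    order = [str(d.index[i]) for i in leaves_list(merges)]
    return LinkageResult(order, merges, method)


def mean_within_between(
    d: pd.DataFrame, group_of: Mapping[str, str]
) -> tuple[float, float]:
    """Mean dissimilarity within and between sample groups.

    Convenience for replicate-reproducibility checks: ``group_of`` maps
    each sample id to its group (e.g. individual).
    """
    within: list[float] = []
    between: list[float] = []
    samples = list(d.index)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            value = float(d.loc[a, b])
            (within if group_of[a] == group_of[b] else between).append(value)
    if not within or not between:
        raise DomainError("need at least one within-group and one between-group pair")
    return float(np.mean(within)), float(np.mean(between))
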