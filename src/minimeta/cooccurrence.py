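"""Co-occurrence statistics for contig binning.

A mini-metagenomic experiment partitions a well-mixed cell suspension
into ~96 microfluidic chambers (sub-samples).  Contigs originating from
the same genome ride along with the same cells, so their presence
patterns across chambers co-vary.  This module digitizes the noisy
MDA-amplified coverage signal into a binary occurrence map and scores
every contig pair with the single-term hypergeometric probability of
their joint presence pattern under the null hypothesis that the two
patterns are unrelated.  Small probabilities indicate contigs from the
same genome, and the probability doubles as a pairwise distance for
clustering.

For a pair of contigs X and Y the 2x2 contingency counts over chambers
are ``a`` (both present), ``b`` (X absent, Y present), ``c`` (X present,
Y absent) and ``d`` (both absent), and the score is the hypergeometric
point probability

    p = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! (a+b+c+d)!)

i.e. the probability of the observed table given both margins — not the
usual Fisher tail sum.  A two-sided tail option is available for users
who prefer the conventional test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from minimeta.io_formats import CoverageMatrix, ValidationError

#: Default presence threshold: covered base pairs needed to call a contig
#: present in a sub-sample.  Binning is robust over 2**9 .. 2**13.
DEFAULT_PRESENCE_THRESHOLD = 2**11

#: Robustness band over which binning results are expected to be stable.
PRESENCE_THRESHOLD_BAND = (2**9, 2**13)

CORRECTION_METHODS = ("bonferroni", "benjamini-hochberg", "none")


class ContingencyCounts(NamedTuple):
    """2x2 presence/absence counts for a contig pair over sub-samples."""

    a: int  # both present
    b: int  # X absent, Y present
    c: int  # X present, Y absent
    d: int  # both absent

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class OccurrenceMatrix:
    """Binary contig x sub-sample presence map with its threshold.

    ``log2_coverage`` (log2 of covered bp, zeros kept at 0) is retained
    for heat-map display only; no statistic uses it.
    """

    contig_ids: list[str]
    subsample_ids: list[str]
    presence: np.ndarray
    threshold: float
    log2_coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("occurrence entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8)
        if self.presence.shape != (len(self.contig_ids), len(self.subsample_ids)):
            raise ValidationError("occurrence shape does not match ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape


@dataclass
class PValueMatrix:
    """Symmetric matrix of pairwise co-occurrence probabilities in (0, 1].

    Each off-diagonal entry is the probability of incorrectly rejecting
    the null hypothesis that the presence patterns of the two contigs
    occur randomly.  Self-pairs carry the smallest computed off-diagonal
    value so that self-distance is minimal when the matrix is used as a
    distance metric.
    """

    contig_ids: list[str]
    p: np.ndarray
    corrected: bool = False
    correction_method: str = "none"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = len(self.contig_ids)
        if self.p.shape != (n, n):
            raise ValidationError("p-value matrix shape does not match contig ids")
        if not np.allclose(self.p, self.p.T):
            raise ValidationError("p-value matrix must be symmetric")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValidationError("p-values must lie in (0, 1]")

    def as_distances(self) -> np.ndarray:
        """Copy of the matrix with a zero diagonal, for embedding input."""
        d = self.p.copy()
        np.fill_diagonal(d, 0.0)
        return d


def binarize_coverage(
    coverage: CoverageMatrix, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> OccurrenceMatrix:
    """Threshold covered bp into a binary occurrence map.

    A contig is present in a sub-sample iff its covered bp is >= the
    threshold (boundary counts as present).  The log2-transformed
    coverage is kept alongside for heat-map output.
    """
    if threshold <= 0:
        raise ValueError(f"presence threshold must be positive, got {threshold}")
    values = coverage.values
    presence = (values >= threshold).astype(np.int8)
    log2cov = np.where(values > 0, np.log2(np.maximum(values, 1)), 0.0)
    return OccurrenceMatrix(
        list(coverage.contig_ids), list(coverage.subsample_ids), presence, threshold, log2cov
    )


def tabulate_contingency(x: np.ndarray, y: np.ndarray) -> ContingencyCounts:
    """Count the four joint presence/absence states of two binary vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("presence vectors must be 1-D and of equal length")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("presence vectors must be binary")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 0) & (y == 1)))
    c = int(np.sum((x == 1) & (y == 0)))
    d = int(np.sum((x == 0) & (y == 0)))
    return ContingencyCounts(a, b, c, d)


def _log_factorial(x) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def fisher_point_probability(counts: ContingencyCounts | tuple[int, int, int, int]) -> float:
    """Hypergeometric point probability of a 2x2 table with fixed margins.

    Evaluated in log-factorial space so that tables with totals up to
    ~1e4 do not overflow.  Returns a value in (0, 1]; empty margins give
    exactly 1.
    """
    a, b, c, d = counts
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    logp = (
        _log_factorial(a + b)
        + _log_factorial(c + d)
        + _log_factorial(a + c)
        + _log_factorial(b + d)
        - _log_factorial(a)
        - _log_factorial(b)
        - _log_factorial(c)
        - _log_factorial(d)
        - _log_factorial(a + b + c + d)
    )
    return float(min(np.exp(logp), 1.0))


def _pairwise_point_probabilities(presence: np.ndarray) -> np.ndarray:
    """Vectorized point probabilities for all contig pairs."""
    P = presence.astype(np.float64)
    n_sub = P.shape[1]
    a = P @ P.T
    row = P.sum(axis=1)
    c = row[:, None] - a  # X present, Y absent
    b = row[None, :] - a  # X absent, Y present
    d = n_sub - a - b - c
    logp = (
        _log_factorial(a + b)
        + _log_factorial(c + d)
        + _log_factorial(a + c)
        + _log_factorial(b + d)
        - _log_factorial(a)
        - _log_factorial(b)
        - _log_factorial(c)
        - _log_factorial(d)
        - _log_factorial(n_sub)
    )
    return np.minimum(np.exp(logp), 1.0)


def pairwise_pvalues(occurrence: OccurrenceMatrix, tail: str = "point") -> PValueMatrix:
    """Score every unordered contig pair from its co-occurrence pattern.

    ``tail='point'`` (default) is the single-term hypergeometric
    probability; ``tail='two-sided'`` is the conventional two-sided
    Fisher's exact test.  The matrix is symmetric and its diagonal is set
    to the smallest computed off-diagonal value.
    """
    n_contigs, n_sub = occurrence.shape
    if n_contigs < 2 or n_sub < 1:
        raise ValidationError("need at least 2 contigs and 1 sub-sample")
    if tail == "point":
        p = _pairwise_point_probabilities(occurrence.presence)
        p = (p + p.T) / 2.0  # exact symmetry despite float round-off
    elif tail == "two-sided":
        p = np.ones((n_contigs, n_contigs))
        pres = occurrence.presence
        for i in range(n_contigs):
            for j in range(i + 1, n_contigs):
                a, b, c, d = tabulate_contingency(pres[i], pres[j])
                p[i, j] = p[j, i] = fisher_exact([[a, c], [b, d]], alternative="two-sided")[1]
    else:
        raise ValueError(f"unknown tail {tail!r}; use 'point' or 'two-sided'")
    off = ~np.eye(n_contigs, dtype=bool)
    p[off] = np.clip(p[off], np.finfo(float).tiny, 1.0)
    np.fill_diagonal(p, p[off].min() if n_contigs > 1 else 1.0)
    return PValueMatrix(list(occurrence.contig_ids), p)


def correct_pvalues(
    pmatrix: PValueMatrix, method: str = "bonferroni", m: int | None = None
) -> PValueMatrix:
    """Multiple-comparison correction over the distinct contig pairs.

    ``m`` defaults to the number of distinct pairs.  Corrected values are
    capped at 1; the diagonal is reset to the smallest corrected
    off-diagonal value.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}; use one of {CORRECTION_METHODS}")
    if pmatrix.corrected:
        raise ValueError("p-value matrix is already corrected")
    n = len(pmatrix.contig_ids)
    p = pmatrix.p.copy()
    if method == "none" or n < 2:
        return PValueMatrix(list(pmatrix.contig_ids), p, corrected=False, correction_method="none")
    iu = np.triu_indices(n, k=1)
    flat = p[iu]
    if method == "bonferroni":
        m_eff = m if m is not None else flat.size
        adj = np.minimum(flat * m_eff, 1.0)
    else:  # benjamini-hochberg
        adj = multipletests(flat, method="fdr_bh")[1]
    adj = np.clip(adj, np.finfo(float).tiny, 1.0)
    p[iu] = adj
    p[(iu[1], iu[0])] = adj
    np.fill_diagonal(p, adj.min())
    return PValueMatrix(list(pmatrix.contig_ids), p, corrected=True, correction_method=method)
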