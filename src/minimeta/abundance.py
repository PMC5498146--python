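"""Genome abundance by Poisson occupancy inversion.

Cells from a well-mixed suspension land in the n microfluidic chambers
independently and uniformly at random, so the number of cells of a given
genome per chamber is Poisson with mean X/n, where X is the total number
of cells of that genome loaded.  The expected fraction of chambers with
zero cells is then k/n = exp(-X/n), which inverts to the cell-count
estimator

    X = -n * ln(k / n)

with k the observed number of empty chambers.  A chamber counts as
occupied when strictly more than 50% of the bin's contigs show read
support there.  The model counts chambers, not cells: multiple cells in
one chamber are resolved only through the Poisson inversion, never
enumerated directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from minimeta.binning import GenomeBin
from minimeta.cooccurrence import OccurrenceMatrix
from minimeta.io_formats import CoverageMatrix, ValidationError

PRESENCE_RULES = ("read-support", "occurrence-threshold")

#: Fraction of a bin's contigs that must be supported for a chamber to
#: count as occupied (strictly greater than).
PRESENCE_FRACTION = 0.5


@dataclass
class AbundanceEstimate:
    """Poisson-inverted cell count for one genome bin.

    ``saturated`` flags k = 0 (genome seen in every chamber), where the
    estimator diverges; ``cells`` then holds the k = 1 lower bound
    -n*ln(1/n) rather than a point estimate.
    """

    bin_id: str
    n: int
    k: int
    cells: float
    saturated: bool = False
    relative_abundance: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValidationError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")


def genome_presence_profile(
    matrix: CoverageMatrix | OccurrenceMatrix,
    bin_: GenomeBin,
    rule: str = "read-support",
) -> np.ndarray:
    """Binary per-chamber occupancy vector for a genome bin.

    ``rule='read-support'`` (default) counts a contig as supported in a
    chamber when any of its bases are covered (>= 1 covered bp);
    ``rule='occurrence-threshold'`` reuses the binarized occurrence map
    (the binning threshold).  The chamber is occupied iff strictly more
    than half of the bin's contigs are supported.
    """
    if rule not in PRESENCE_RULES:
        raise ValueError(f"unknown presence rule {rule!r}; use one of {PRESENCE_RULES}")
    if not bin_.contig_ids:
        raise ValidationError(f"bin {bin_.bin_id} has no contigs")
    if rule == "read-support":
        if not isinstance(matrix, CoverageMatrix):
            raise TypeError("read-support rule needs a CoverageMatrix")
        support = matrix.values >= 1
        index = {c: i for i, c in enumerate(matrix.contig_ids)}
    else:
        if not isinstance(matrix, OccurrenceMatrix):
            raise TypeError("occurrence-threshold rule needs an OccurrenceMatrix")
        support = matrix.presence.astype(bool)
        index = {c: i for i, c in enumerate(matrix.contig_ids)}
    try:
        rows = [index[c] for c in bin_.contig_ids]
    except KeyError as exc:
        raise ValidationError(f"bin contig {exc} absent from matrix") from exc
    frac = support[rows].mean(axis=0)
    return (frac > PRESENCE_FRACTION).astype(np.int8)


def estimate_cell_count(k: int, n: int, bin_id: str = "") -> AbundanceEstimate:
    """Invert the empty-chamber fraction into a total cell count.

    X = -n*ln(k/n) for k >= 1; k = n gives X = 0; k = 0 saturates the
    estimator and the k = 1 lower bound is reported with the flag set.
    """
    if n < 1:
        raise ValidationError("need at least one chamber")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return AbundanceEstimate(bin_id, n, k, -n * math.log(1.0 / n), saturated=True)
    return AbundanceEstimate(bin_id, n, k, -n * math.log(k / n), saturated=False)


def estimate_bin_abundances(
    matrix: CoverageMatrix | OccurrenceMatrix,
    bins: Sequence[GenomeBin],
    rule: str = "read-support",
) -> list[AbundanceEstimate]:
    """Presence profile + Poisson inversion for every reported bin."""
    estimates = []
    for b in bins:
        if b.is_unbinned:
            continue
        profile = genome_presence_profile(matrix, b, rule)
        n = profile.size
        k = int(n - profile.sum())
        estimates.append(estimate_cell_count(k, n, bin_id=b.bin_id))
    return estimates


def relative_abundance(estimates: Sequence[AbundanceEstimate]) -> list[AbundanceEstimate]:
    """Normalize cell counts to fractions summing to 1 over reported bins.

    Saturated estimates contribute their lower bound.  At least one
    non-saturated estimate is required.
    """
    if not estimates or all(e.saturated for e in estimates):
        raise ValidationError("relative abundance needs at least one non-saturated estimate")
    total = sum(e.cells for e in estimates)
    if total <= 0:
        raise ValidationError("total estimated cells is zero; cannot normalize")
    out = []
    for e in estimates:
        out.append(
            AbundanceEstimate(e.bin_id, e.n, e.k, e.cells, e.saturated, e.cells / total)
        )
    return out
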