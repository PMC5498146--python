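"""Sequence-independent contig binning from co-occurrence p-values.

The pairwise probability matrix is treated directly as a distance matrix
(small p = contigs co-occur far more often than chance = same genome),
embedded in two dimensions, and clustered with DBSCAN.  Two embeddings
are available: classical (Torgerson) multidimensional scaling, which is
exact and fully deterministic, and t-SNE, which is reproducible for a
fixed seed.  Clusters below a minimum contig count, and points DBSCAN
leaves as noise, are labeled with the reserved ``unbinned`` id; bins are
then filtered by total assembled length (default > 0.5 Mbp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from minimeta.cooccurrence import PValueMatrix
from minimeta.io_formats import ValidationError

#: Reserved bin id for contigs not incorporated into a large enough cluster.
UNBINNED_LABEL = "unbinned"

#: Genome bins must exceed this total assembled length (bp) to be reported.
DEFAULT_MIN_BIN_LENGTH = 500_000

DEFAULT_PERPLEXITY = 30.0
DEFAULT_TSNE_ITERATIONS = 1000
DEFAULT_MIN_POINTS = 4
DEFAULT_MIN_BIN_CONTIGS = 5


@dataclass
class Embedding:
    """2-D coordinates of contigs derived from the p-value distance matrix."""

    contig_ids: list[str]
    coordinates: np.ndarray
    seed: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.contig_ids), 2):
            raise ValidationError("embedding needs one 2-D point per contig")


@dataclass
class GenomeBin:
    """A cluster of contigs attributed to one genome."""

    bin_id: str
    contig_ids: list[str]
    contig_lengths: Mapping[str, int] | None = None
    consensus_lineage: str | None = None
    lineage_fraction: float | None = None

    @property
    def total_length(self) -> int | None:
        if self.contig_lengths is None:
            return None
        return int(sum(self.contig_lengths[c] for c in self.contig_ids))

    @property
    def is_unbinned(self) -> bool:
        return self.bin_id == UNBINNED_LABEL

    def __len__(self) -> int:
        return len(self.contig_ids)


def embed_pvalue_distances(
    pmatrix: PValueMatrix,
    seed: int = 0,
    perplexity: float = DEFAULT_PERPLEXITY,
    method: str = "tsne",
    n_iter: int = DEFAULT_TSNE_ITERATIONS,
) -> Embedding:
    """Embed contigs in 2-D using the p-value matrix as pairwise distances.

    ``method='tsne'`` (default) preserves local neighborhoods, which is
    what separates many near-equidistant genome clusters in two
    dimensions; it is reproducible for a fixed seed.  ``method='cmds'``
    is classical (Torgerson) multidimensional scaling — exact and fully
    deterministic, but it preserves large distances at the expense of
    cluster separation, so with more than a handful of genomes the 2-D
    projection can overlay clusters.
    """
    n = len(pmatrix.contig_ids)
    if n < 3:
        raise ValidationError(
            "need at least 3 contigs to embed; cluster the distance matrix directly"
        )
    if perplexity <= 0:
        raise ValueError("perplexity must be positive")
    D = pmatrix.as_distances()
    if method == "cmds":
        coords = _classical_mds(D)
        params = {"method": "cmds"}
    elif method == "tsne":
        perp = min(perplexity, (n - 1) / 3.0)
        tsne = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            random_state=seed,
            perplexity=perp,
            max_iter=n_iter,
        )
        coords = tsne.fit_transform(D)
        params = {"method": "tsne", "perplexity": perp, "n_iter": n_iter}
    else:
        raise ValueError(f"unknown embedding method {method!r}; use 'cmds' or 'tsne'")
    return Embedding(list(pmatrix.contig_ids), coords, seed, params)


def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Torgerson scaling: top-2 eigenpairs of the double-centered Gram matrix."""
    n = D.shape[0]
    D2 = D.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))[None, :]
    # Fix the eigenvector sign ambiguity so output is bit-stable.
    for k in range(coords.shape[1]):
        col = coords[:, k]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            coords[:, k] = -col
    return coords


def _knee_eps(coords: np.ndarray, min_points: int) -> float:
    """eps from the knee of the sorted k-NN distance curve.

    The knee is the density break: the first pronounced jump (consecutive
    ratio >= 2) in the upper half of the sorted ``min_points``-NN distance
    curve separates the cluster regime from outliers, and eps is set just
    below it.  A curve without such a jump is one density regime and eps
    sits just above its maximum.
    """
    k = min(min_points, len(coords) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists = np.sort(nn.kneighbors(coords)[0][:, -1])
    if dists[-1] <= 0:
        return np.finfo(float).eps
    start = len(dists) // 2
    for i in range(max(start, 1), len(dists) - 1):
        if dists[i] > 0 and dists[i + 1] / dists[i] >= 2.0:
            return float(dists[i]) * 1.05
    eps = float(dists[-1]) * 1.05
    return eps if eps > 0 else np.finfo(float).eps


def cluster_embedding(
    embedding: Embedding,
    eps: float | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
    min_bin_contigs: int = DEFAULT_MIN_BIN_CONTIGS,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GenomeBin]:
    """Density-cluster the embedded contigs into genome bins.

    ``eps=None`` picks the DBSCAN radius at the knee of the
    ``min_points``-NN distance curve.  Noise points and clusters with
    fewer than ``min_bin_contigs`` members are collected in a trailing
    bin labeled :data:`UNBINNED_LABEL`.  Bins are ordered by decreasing
    size and labeled ``bin_001``, ``bin_002``, ...
    """
    if eps is not None and eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    coords = embedding.coordinates
    if eps is None:
        eps = _knee_eps(coords, min_points)
    labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(coords)

    ids = np.asarray(embedding.contig_ids)
    clusters: list[list[str]] = []
    unbinned: list[str] = list(ids[labels == -1])
    for lab in np.unique(labels[labels >= 0]):
        members = list(ids[labels == lab])
        if len(members) < min_bin_contigs:
            unbinned.extend(members)
        else:
            clusters.append(members)
    # deterministic order: big bins first, ties broken by first contig id
    clusters.sort(key=lambda m: (-len(m), m[0]))
    bins = [
        GenomeBin(f"bin_{i + 1:03d}", members, contig_lengths)
        for i, members in enumerate(clusters)
    ]
    bins.append(GenomeBin(UNBINNED_LABEL, sorted(unbinned, key=list(ids).index), contig_lengths))
    return bins


def filter_bins_by_size(
    bins: Sequence[GenomeBin],
    contig_lengths: Mapping[str, int],
    min_total_length: int = DEFAULT_MIN_BIN_LENGTH,
    allow_singletons: bool = False,
) -> list[GenomeBin]:
    """Keep bins whose total assembled length exceeds the cutoff.

    Contigs of dropped bins join the unbinned set.  With
    ``allow_singletons``, an unbinned contig longer than the cutoff by
    itself is promoted to its own bin — a multi-Mbp singleton can be a
    complete genome that simply never fragmented into a cluster.
    """
    retained: list[GenomeBin] = []
    unbinned: list[str] = []
    for b in bins:
        missing = [c for c in b.contig_ids if c not in contig_lengths]
        if missing:
            raise ValidationError(f"no length for contigs {missing[:3]} in bin {b.bin_id}")
        if b.is_unbinned:
            unbinned.extend(b.contig_ids)
            continue
        total = sum(contig_lengths[c] for c in b.contig_ids)
        if total > min_total_length:
            retained.append(
                GenomeBin(b.bin_id, list(b.contig_ids), contig_lengths,
                          b.consensus_lineage, b.lineage_fraction)
            )
        else:
            unbinned.extend(b.contig_ids)
    if allow_singletons:
        still_unbinned = []
        for cid in unbinned:
            if contig_lengths[cid] > min_total_length:
                retained.append(GenomeBin(f"singleton_{cid}", [cid], contig_lengths))
            else:
                still_unbinned.append(cid)
        unbinned = still_unbinned
    retained.append(GenomeBin(UNBINNED_LABEL, unbinned, contig_lengths))
    return retained


def consensus_lineage(
    bin_: GenomeBin,
    contig_lineages: Mapping[str, str],
    unassigned_label: str = "unassigned",
) -> tuple[str, float]:
    """Majority lineage among the bin's assigned contigs.

    Returns ``(label, fraction_of_assigned_supporting_it)``.  Bins where
    fewer than half the contigs carry an assignment are flagged
    ``predominantly unassigned`` via the label suffix ``*`` convention in
    the output table; here we simply return the majority label and let
    callers inspect the assigned fraction.
    """
    counts: dict[str, int] = {}
    n_assigned = 0
    for cid in bin_.contig_ids:
        lab = contig_lineages.get(cid, unassigned_label)
        if lab != unassigned_label:
            counts[lab] = counts.get(lab, 0) + 1
            n_assigned += 1
    if n_assigned == 0:
        return unassigned_label, 0.0
    label = max(sorted(counts), key=counts.get)
    fraction = counts[label] / n_assigned
    bin_.consensus_lineage = label
    bin_.lineage_fraction = fraction
    return label, fraction


def predominantly_unassigned(
    bin_: GenomeBin, contig_lineages: Mapping[str, str], unassigned_label: str = "unassigned"
) -> bool:
    """True when fewer than half the bin's contigs carry a lineage."""
    n_assigned = sum(
        1 for c in bin_.contig_ids if contig_lineages.get(c, unassigned_label) != unassigned_label
    )
    return n_assigned < len(bin_.contig_ids) / 2


@dataclass
class BinningScores:
    """Agreement between inferred bins and a known contig->genome truth."""

    ari: float
    purity: dict[str, float]
    completeness: dict[str, float]


def evaluate_binning(
    bins: Sequence[GenomeBin],
    truth: Mapping[str, str],
    contig_lengths: Mapping[str, int] | None = None,
) -> BinningScores:
    """Score bins against ground truth (simulator validation harness).

    ARI is computed over binned contigs only; purity is each bin's
    largest single-genome fraction; completeness is, per true genome, the
    fraction of its total contig length (or contig count when lengths are
    unavailable) recovered in the best-matching single bin.
    """
    binned = [(cid, b.bin_id) for b in bins if not b.is_unbinned for cid in b.contig_ids]
    missing = [cid for cid, _ in binned if cid not in truth]
    if missing:
        raise ValidationError(f"truth is missing binned contigs {missing[:3]}")
    if not binned:
        raise ValidationError("no binned contigs to evaluate")
    pred = [bid for _, bid in binned]
    true = [truth[cid] for cid, _ in binned]
    ari = float(adjusted_rand_score(true, pred))

    purity: dict[str, float] = {}
    weight = (lambda c: contig_lengths[c]) if contig_lengths else (lambda c: 1)
    per_bin_genome: dict[str, dict[str, float]] = {}
    for b in bins:
        if b.is_unbinned or not b.contig_ids:
            continue
        tally: dict[str, float] = {}
        for cid in b.contig_ids:
            tally[truth[cid]] = tally.get(truth[cid], 0) + weight(cid)
        per_bin_genome[b.bin_id] = tally
        purity[b.bin_id] = max(tally.values()) / sum(tally.values())

    genome_total: dict[str, float] = {}
    for cid, g in truth.items():
        if contig_lengths is not None and cid not in contig_lengths:
            raise ValidationError(f"no length for truth contig {cid!r}")
        genome_total[g] = genome_total.get(g, 0) + weight(cid)
    completeness = {}
    for g, total in genome_total.items():
        best = max((tally.get(g, 0.0) for tally in per_bin_genome.values()), default=0.0)
        completeness[g] = best / total if total else 0.0
    return BinningScores(ari, purity, completeness)
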