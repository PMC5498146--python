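"""End-to-end orchestration: coverage table in, genome bins and per-bin
statistics out.  Thin glue over the stage modules; the CLI and the test
harness both drive the pipeline through these functions so they agree
exactly on stage order and defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from minimeta import abundance as _abundance
from minimeta import binning as _binning
from minimeta import cooccurrence as _cooccurrence
from minimeta import variation as _variation
from minimeta.abundance import AbundanceEstimate
from minimeta.binning import Embedding, GenomeBin
from minimeta.cooccurrence import OccurrenceMatrix, PValueMatrix
from minimeta.io_formats import CoverageMatrix, OrfTable, SnpTable


@dataclass
class PipelineConfig:
    """Effective parameter set for one pipeline run (echoed to outputs)."""

    threshold: float = _cooccurrence.DEFAULT_PRESENCE_THRESHOLD
    correction: str = "bonferroni"
    tail: str = "point"
    embedding_method: str = "tsne"
    perplexity: float = _binning.DEFAULT_PERPLEXITY
    eps: float | None = None
    min_points: int = _binning.DEFAULT_MIN_POINTS
    min_bin_contigs: int = _binning.DEFAULT_MIN_BIN_CONTIGS
    min_bin_length: int = _binning.DEFAULT_MIN_BIN_LENGTH
    allow_singletons: bool = False
    abundance_rule: str = "read-support"
    quality_min: float = _variation.DEFAULT_QUALITY_MIN
    depth_min: int = _variation.DEFAULT_DEPTH_MIN
    dnds_method: str = "ng86"
    seed: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class BinningResult:
    occurrence: OccurrenceMatrix
    pvalues: PValueMatrix              # uncorrected; the distance metric
    pvalues_corrected: PValueMatrix    # for reporting / heat-map shading
    embedding: Embedding
    bins: list[GenomeBin]


def bin_contigs(
    coverage: CoverageMatrix,
    contig_lengths: Mapping[str, int],
    config: PipelineConfig | None = None,
) -> BinningResult:
    """Coverage -> occurrence -> pairwise p-values -> embedding -> bins.

    The uncorrected p-value matrix is the pairwise distance metric fed
    to the embedding; the corrected matrix is computed alongside for
    reporting.
    """
    cfg = config or PipelineConfig()
    occurrence = _cooccurrence.binarize_coverage(coverage, cfg.threshold)
    pvalues = _cooccurrence.pairwise_pvalues(occurrence, tail=cfg.tail)
    corrected = (
        _cooccurrence.correct_pvalues(pvalues, cfg.correction)
        if cfg.correction != "none"
        else pvalues
    )
    embedding = _binning.embed_pvalue_distances(
        pvalues, seed=cfg.seed, perplexity=cfg.perplexity, method=cfg.embedding_method
    )
    bins = _binning.cluster_embedding(
        embedding, eps=cfg.eps, min_points=cfg.min_points,
        min_bin_contigs=cfg.min_bin_contigs, contig_lengths=contig_lengths,
    )
    bins = _binning.filter_bins_by_size(
        bins, contig_lengths, cfg.min_bin_length, cfg.allow_singletons
    )
    return BinningResult(occurrence, pvalues, corrected, embedding, bins)


def estimate_abundances(
    coverage: CoverageMatrix,
    bins: Sequence[GenomeBin],
    rule: str = "read-support",
) -> list[AbundanceEstimate]:
    """Per-bin Poisson cell counts with relative abundances."""
    estimates = _abundance.estimate_bin_abundances(coverage, bins, rule)
    return _abundance.relative_abundance(estimates) if estimates else []


def summarize_bin_variation(
    bins: Sequence[GenomeBin],
    snps: SnpTable,
    orfs: OrfTable,
    contig_seqs: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> list[_variation.VariationSummary]:
    """Filter, classify and summarize SNPs for every reported bin."""
    cfg = config or PipelineConfig()
    filtered = _variation.filter_snps(snps, cfg.quality_min, cfg.depth_min)
    out = []
    for b in bins:
        if b.is_unbinned:
            continue
        out.append(
            _variation.summarize_variation(
                b, filtered, orfs, contig_seqs, method=cfg.dnds_method
            )
        )
    return out
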