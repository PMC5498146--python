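"""Simulated mini-metagenomic experiments with full ground truth.

The generator emulates the structure a real experiment produces after
alignment and tabulation, so every pipeline stage is testable offline:

* cells of G genomes are loaded into n microfluidic chambers
  independently; the per-chamber cell count of genome g is
  Poisson(lambda_g), and the genome is present in a chamber iff at
  least one of its cells landed there;
* each contig of a present genome independently escapes MDA dropout
  (probability ``1 - contig_dropout``) and receives a lognormal
  covered-bp draw at or above the presence threshold (capped at the
  contig length); dropped contigs receive sub-threshold noise; contigs
  of absent genomes receive zero coverage — chambers are physically
  separate, so there is no cross-chamber signal;
* each genome carries polymorphic sites whose alternate allele is borne
  by each cell independently with a fixed allele frequency; per-chamber
  allele depths are Poisson around ``depth_per_cell`` reads per carrying
  cell, and sites are emitted as SNP calls when any alternate read is
  observed.  At coding sites the proposed substitution is uniform over
  the three alternative bases; nonsynonymous proposals are accepted with
  probability ``nonsyn_acceptance`` (1 = neutral, <1 = purifying).

All randomness flows from one seed through named sub-streams (genome
structure, cell loading, coverage, SNPs), so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from minimeta import io_formats
from minimeta.io_formats import (
    CoverageMatrix,
    OrfRecord,
    OrfTable,
    SnpRecord,
    SnpTable,
    ValidationError,
)
from minimeta.cooccurrence import DEFAULT_PRESENCE_THRESHOLD
from minimeta.variation import CLASS_NONSYNONYMOUS, classify_snp

_PHYLA = (
    "Bacteroidetes", "Chlorobi", "Ignavibacteriae", "Thermodesulfobacteria",
    "Spirochaetes", "Euryarchaeota", "Deferribacteres", "Bathyarchaeota",
    "Chloroflexi", "Aminicenantes",
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES = "ACGT"


@dataclass(frozen=True)
class GenomeSpec:
    """One simulated genome: its contig makeup and loading rate."""

    genome_id: str
    n_contigs: int
    mean_cells_per_chamber: float  # Poisson rate lambda_g
    contig_length_log_mean: float = float(np.log(30_000))
    contig_length_log_sigma: float = 0.35
    lineage: str | None = None

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValidationError(f"{self.genome_id}: need at least one contig")
        if self.mean_cells_per_chamber <= 0:
            raise ValidationError(f"{self.genome_id}: lambda must be positive")


@dataclass
class CommunityConfig:
    """Study conditions for one simulated experiment."""

    genomes: list[GenomeSpec]
    n_subsamples: int = 96
    contig_dropout: float = 0.2
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    coverage_log2_mean: float = 2.0   # median covered bp = threshold * 2**mean
    coverage_log2_sigma: float = 1.0
    min_contig_length: int = 10_000
    max_contig_length: int = 200_000
    snp_sites_per_genome: int = 40
    snp_alt_freq: float = 0.3
    nonsyn_acceptance: float = 1.0
    depth_per_cell: float = 8.0
    lineage_assigned_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValidationError("need at least one genome")
        if self.n_subsamples < 1:
            raise ValidationError("need at least one sub-sample")
        if not 0.0 <= self.contig_dropout < 1.0:
            raise ValidationError("contig_dropout must lie in [0, 1)")
        if self.presence_threshold <= 0:
            raise ValidationError("presence threshold must be positive")
        if not 0.0 < self.snp_alt_freq < 1.0:
            raise ValidationError("snp_alt_freq must lie in (0, 1)")
        if not 0.0 <= self.nonsyn_acceptance <= 1.0:
            raise ValidationError("nonsyn_acceptance must lie in [0, 1]")
        if self.snp_sites_per_genome < 0 or self.depth_per_cell <= 0:
            raise ValidationError("SNP model counts must be positive")
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate genome ids")

    @property
    def total_loading(self) -> float:
        """Expected total cells per chamber, summed over genomes."""
        return sum(g.mean_cells_per_chamber for g in self.genomes)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    contig_to_genome: dict[str, str]
    genome_ids: list[str]
    subsample_ids: list[str]
    cell_counts: np.ndarray            # genomes x chambers
    snp_classes: list[tuple[str, int, str]]  # (contig, position, class)
    contig_sequences: dict[str, str]
    genome_lineages: dict[str, str]

    @property
    def true_cell_totals(self) -> dict[str, int]:
        return {
            g: int(self.cell_counts[i].sum()) for i, g in enumerate(self.genome_ids)
        }

    @property
    def genome_presence(self) -> np.ndarray:
        """Binary genomes x chambers matrix (>= 1 cell)."""
        return (self.cell_counts >= 1).astype(np.int8)


@dataclass
class SimulatedCommunity:
    """Bundle of simulator outputs mirroring a tabulated experiment."""

    coverage: CoverageMatrix
    snps: SnpTable
    orfs: OrfTable
    lineages: dict[str, str]          # contig -> phylum or "unassigned"
    truth: GroundTruth
    config: CommunityConfig

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(zip(self.coverage.contig_ids, self.coverage.contig_lengths))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_community(config: CommunityConfig) -> SimulatedCommunity:
    """Run one simulated experiment under ``config`` (deterministic per seed)."""
    root = np.random.SeedSequence(config.seed)
    rng_structure, rng_cells, rng_cov, rng_snp = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    n_sub = config.n_subsamples
    subsample_ids = [f"s{j + 1:02d}" for j in range(n_sub)]
    genome_ids = [g.genome_id for g in config.genomes]

    # --- genome structure: contigs, sequences, ORFs, lineages ---
    contig_ids: list[str] = []
    lengths: list[int] = []
    contig_to_genome: dict[str, str] = {}
    sequences: dict[str, str] = {}
    orf_records: list[OrfRecord] = []
    lineages: dict[str, str] = {}
    genome_lineages: dict[str, str] = {}
    for gi, g in enumerate(config.genomes):
        phylum = g.lineage or _PHYLA[gi % len(_PHYLA)]
        genome_lineages[g.genome_id] = phylum
        for ci in range(g.n_contigs):
            cid = f"{g.genome_id}_c{ci + 1:03d}"
            ln = int(
                np.clip(
                    rng_structure.lognormal(g.contig_length_log_mean, g.contig_length_log_sigma),
                    config.min_contig_length,
                    config.max_contig_length,
                )
            )
            contig_ids.append(cid)
            lengths.append(ln)
            contig_to_genome[cid] = g.genome_id
            sequences[cid] = _random_sequence(rng_structure, ln)
            n_codons = max(1, int(0.8 * ln) // 3)
            start = 101 if ln > 100 + 3 * n_codons else 1
            end = min(ln, start + 3 * n_codons - 1)
            end = start + ((end - start + 1) // 3) * 3 - 1  # full codons only
            strand = "+" if ci % 2 == 0 else "-"
            orf_records.append(OrfRecord(cid, start, end, strand, f"{cid}_g1"))
            lineages[cid] = (
                phylum if rng_structure.random() < config.lineage_assigned_fraction
                else "unassigned"
            )
    lengths_arr = np.array(lengths, dtype=np.int64)
    orfs = OrfTable(orf_records)

    # --- cell loading: Poisson occupancy per genome per chamber ---
    lambdas = np.array([g.mean_cells_per_chamber for g in config.genomes])
    cell_counts = rng_cells.poisson(lambdas[:, None], size=(len(config.genomes), n_sub))

    # --- coverage with MDA dropout ---
    threshold = config.presence_threshold
    values = np.zeros((len(contig_ids), n_sub), dtype=np.int64)
    escaped = np.zeros((len(contig_ids), n_sub), dtype=bool)
    row = 0
    for gi, g in enumerate(config.genomes):
        present = cell_counts[gi] >= 1
        for _ in range(g.n_contigs):
            esc = present & (rng_cov.random(n_sub) >= config.contig_dropout)
            escaped[row] = esc
            hi = np.round(
                threshold
                * 2.0 ** rng_cov.normal(config.coverage_log2_mean, config.coverage_log2_sigma, n_sub)
            )
            hi = np.clip(hi, threshold, lengths_arr[row]).astype(np.int64)
            noise_cap = max(2, int(threshold) // 2)
            noise = rng_cov.integers(0, noise_cap, size=n_sub)
            dropped = present & ~esc
            values[row][esc] = hi[esc]
            values[row][dropped] = noise[dropped]
            row += 1
    coverage = CoverageMatrix(contig_ids, subsample_ids, values, lengths_arr)

    # --- SNP alleles segregating across chambers ---
    snp_records, snp_classes = _simulate_snps(
        config, rng_snp, contig_ids, lengths_arr, sequences, orfs,
        contig_to_genome, cell_counts, escaped, subsample_ids, genome_ids,
    )

    truth = GroundTruth(
        contig_to_genome=contig_to_genome,
        genome_ids=genome_ids,
        subsample_ids=subsample_ids,
        cell_counts=cell_counts,
        snp_classes=snp_classes,
        contig_sequences=sequences,
        genome_lineages=genome_lineages,
    )
    return SimulatedCommunity(coverage, SnpTable(snp_records, subsample_ids),
                              orfs, lineages, truth, config)


def _simulate_snps(
    config: CommunityConfig,
    rng: np.random.Generator,
    contig_ids: list[str],
    lengths: np.ndarray,
    sequences: Mapping[str, str],
    orfs: OrfTable,
    contig_to_genome: Mapping[str, str],
    cell_counts: np.ndarray,
    escaped: np.ndarray,
    subsample_ids: list[str],
    genome_ids: list[str],
) -> tuple[list[SnpRecord], list[tuple[str, int, str]]]:
    records: list[SnpRecord] = []
    classes: list[tuple[str, int, str]] = []
    contig_row = {c: i for i, c in enumerate(contig_ids)}
    for gi, g in enumerate(config.genomes):
        members = [c for c in contig_ids if contig_to_genome[c] == g.genome_id]
        member_lengths = np.array([lengths[contig_row[c]] for c in members], dtype=float)
        weights = member_lengths / member_lengths.sum()
        chosen: set[tuple[str, int]] = set()
        attempts = 0
        while len(chosen) < config.snp_sites_per_genome and attempts < 200 * config.snp_sites_per_genome:
            attempts += 1
            cid = members[rng.choice(len(members), p=weights)]
            pos = int(rng.integers(1, lengths[contig_row[cid]] + 1))
            if (cid, pos) in chosen:
                continue
            ref = sequences[cid][pos - 1]
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
            probe = SnpRecord(cid, pos, ref, alt, 1000.0, {})
            klass = classify_snp(probe, orfs, sequences[cid])
            if klass == CLASS_NONSYNONYMOUS and rng.random() >= config.nonsyn_acceptance:
                continue  # substitution purged by selection; re-propose
            chosen.add((cid, pos))
            # per-chamber allele depths
            cells = cell_counts[gi]
            esc = escaped[contig_row[cid]]
            n_alt = rng.binomial(cells, config.snp_alt_freq)
            ref_depth = rng.poisson(config.depth_per_cell * (cells - n_alt))
            alt_depth = rng.poisson(config.depth_per_cell * n_alt)
            ref_depth = np.where(esc, ref_depth, 0)
            alt_depth = np.where(esc, alt_depth, 0)
            if alt_depth.sum() == 0:
                continue  # no alternate read observed anywhere: not a call
            quality = float(150.0 + rng.exponential(200.0))
            depths = {
                sid: (int(rd), int(ad))
                for sid, rd, ad in zip(subsample_ids, ref_depth, alt_depth)
            }
            records.append(SnpRecord(cid, pos, ref, alt, quality, depths))
            classes.append((cid, pos, klass))
    return records, classes


def reference_scenario(seed: int = 101) -> CommunityConfig:
    """The canonical simulated community used throughout the test suite.

    Eight genomes with loading rates log-spaced over 0.05–1.0 cells per
    chamber (summed loading ~2.8 cells/chamber, spanning an abundant
    genome present in most chambers down to a rare lineage in a handful),
    20–60 contigs each, 96 chambers, 20% per-contig MDA dropout, and a
    neutral SNP model with 40 polymorphic sites per genome.
    """
    n_contigs = np.linspace(20, 60, 8).round().astype(int)
    lambdas = np.geomspace(0.05, 1.0, 8)
    genomes = [
        GenomeSpec(f"g{i + 1}", int(n_contigs[i]), float(lambdas[i]))
        for i in range(8)
    ]
    return CommunityConfig(genomes=genomes, seed=seed)


def variation_scenario(seed: int = 0, nonsyn_acceptance: float = 1.0,
                       snp_sites: int = 120) -> CommunityConfig:
    """A small single-genome community for exercising the variation stage.

    One well-sampled genome (1.5 cells/chamber) with many polymorphic
    sites; ``nonsyn_acceptance=1`` is the neutral null (dN/dS ~ 1),
    values below 1 emulate purifying selection.
    """
    return CommunityConfig(
        genomes=[GenomeSpec("g1", 6, 1.5)],
        snp_sites_per_genome=snp_sites,
        nonsyn_acceptance=nonsyn_acceptance,
        seed=seed,
    )


def write_community(sim: SimulatedCommunity, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write all simulator outputs in the dialects the readers consume.

    Returns a name -> path map: coverage, lengths, contigs (FASTA), orfs,
    snps (VCF), lineages and the true contig -> genome table.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    params = {"seed": sim.config.seed}
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("coverage", "coverage.tsv"), ("lengths", "contig_lengths.tsv"),
        ("contigs", "contigs.fasta"), ("orfs", "orfs.tsv"),
        ("snps", "snps.vcf"), ("lineages", "lineages.tsv"),
        ("truth", "true_bins.tsv"),
    ]}
    io_formats.write_coverage_table(sim.coverage, paths["coverage"], params)
    io_formats.write_contig_lengths(sim.contig_lengths, paths["lengths"], params)
    io_formats.write_contig_sequences(sim.truth.contig_sequences, paths["contigs"])
    io_formats.write_orf_table(sim.orfs, paths["orfs"], params)
    io_formats.write_snp_table(sim.snps, paths["snps"], sim.contig_lengths)
    lines = [io_formats._header_comment(params), "contig_id\tlineage\n"]
    lines += [f"{c}\t{l}\n" for c, l in sim.lineages.items()]
    io_formats._atomic_write_text(paths["lineages"], "".join(lines))
    lines = [io_formats._header_comment(params), "contig_id\tgenome_id\n"]
    lines += [f"{c}\t{g}\n" for c, g in sim.truth.contig_to_genome.items()]
    io_formats._atomic_write_text(paths["truth"], "".join(lines))
    return paths
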