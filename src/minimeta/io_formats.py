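"""Readers and writers for the tabular/sequence formats the pipeline touches.

All on-disk formats are plain text: tab-separated tables with a header row
(missing values as ``NA``), FASTA for contig sequences, and VCF for SNP
calls.  Positions are 1-based inclusive everywhere on disk and in the
domain types below.

The coverage table is expected to be the per-sub-sample tabulation of the
number of reference base pairs of each contig covered by at least one
aligned read (e.g. counted from per-sub-sample BAMs as positions with
depth >= 1).  Any non-negative integer table with contigs as rows and
sub-samples as columns is accepted.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Default gate on sequencing effort per sub-sample (paired-end reads).
DEFAULT_MIN_READS_PER_SUBSAMPLE = 800_000

NA_TOKEN = "NA"


class FormatError(ValueError):
    """Malformed input file (structure, duplicates, non-numeric cells)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CoverageMatrix:
    """Contig x sub-sample table of covered base pairs.

    Parameters
    ----------
    contig_ids, subsample_ids
        Unique, ordered identifiers for rows and columns.
    values
        Non-negative integer array of shape ``(n_contigs, n_subsamples)``;
        entry ``[i, j]`` is the number of base pairs of contig ``i``
        covered by reads of sub-sample ``j``.
    contig_lengths
        Optional per-contig lengths in bp.  When given, every coverage
        entry is validated against the contig length.
    """

    contig_ids: list[str]
    subsample_ids: list[str]
    values: np.ndarray
    contig_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contig_ids = list(self.contig_ids)
        self.subsample_ids = list(self.subsample_ids)
        self.values = np.asarray(self.values)
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise FormatError("duplicate contig ids in coverage matrix")
        if len(set(self.subsample_ids)) != len(self.subsample_ids):
            raise FormatError("duplicate sub-sample ids in coverage matrix")
        if self.values.shape != (len(self.contig_ids), len(self.subsample_ids)):
            raise ValidationError(
                f"coverage shape {self.values.shape} does not match "
                f"{len(self.contig_ids)} contigs x {len(self.subsample_ids)} sub-samples"
            )
        if np.any(self.values < 0):
            raise FormatError("negative coverage values")
        if self.contig_lengths is not None:
            self.contig_lengths = np.asarray(self.contig_lengths, dtype=np.int64)
            if self.contig_lengths.shape != (len(self.contig_ids),):
                raise ValidationError("need one contig length per contig")
            if np.any(self.contig_lengths <= 0):
                raise ValidationError("contig lengths must be positive")
            bad = np.argwhere(self.values > self.contig_lengths[:, None])
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"coverage {self.values[i, j]} exceeds length "
                    f"{self.contig_lengths[i]} of contig {self.contig_ids[i]!r} "
                    f"in sub-sample {self.subsample_ids[j]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.contig_ids, columns=self.subsample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageMatrix):
            return NotImplemented
        lengths_equal = (self.contig_lengths is None) == (other.contig_lengths is None) and (
            self.contig_lengths is None
            or np.array_equal(self.contig_lengths, other.contig_lengths)
        )
        return (
            self.contig_ids == other.contig_ids
            and self.subsample_ids == other.subsample_ids
            and np.array_equal(self.values, other.values)
            and lengths_equal
        )


@dataclass(frozen=True)
class OrfRecord:
    """One protein-coding ORF on a contig; 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"ORF {self.gene_id}: need 1 <= start <= end")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"ORF {self.gene_id}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class OrfTable:
    """Ordered collection of ORFs, indexable by contig."""

    records: list[OrfRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.contig_id, rec.gene_id)
            if key in seen:
                raise FormatError(f"duplicate gene id {rec.gene_id!r} on {rec.contig_id!r}")
            seen.add(key)
        self._by_contig: dict[str, list[OrfRecord]] = {}
        for rec in self.records:
            self._by_contig.setdefault(rec.contig_id, []).append(rec)

    def on_contig(self, contig_id: str) -> list[OrfRecord]:
        return self._by_contig.get(contig_id, [])

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with per-sub-sample allele depths.

    ``depths`` maps sub-sample id to ``(ref_depth, alt_depth)``.
    """

    contig_id: str
    position: int
    ref: str
    alt: str
    quality: float
    depths: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("SNP position must be 1-based positive")
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles must differ")
        if self.quality < 0:
            raise ValidationError("site quality must be non-negative")
        for sid, (rd, ad) in self.depths.items():
            if rd < 0 or ad < 0:
                raise ValidationError(f"negative allele depth for sub-sample {sid!r}")


@dataclass
class SnpTable:
    """Ordered collection of biallelic SNP records."""

    records: list[SnpRecord]
    subsample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subsample_ids:
            seen: dict[str, None] = {}
            for rec in self.records:
                for sid in rec.depths:
                    seen.setdefault(sid)
            self.subsample_ids = list(seen)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN], **kwargs)


def read_coverage_table(
    path: str | os.PathLike,
    min_reads_per_subsample: int = DEFAULT_MIN_READS_PER_SUBSAMPLE,
    subsample_read_counts: Mapping[str, float] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> CoverageMatrix:
    """Read a contig x sub-sample covered-bp table.

    The file is tab-separated with a header row of sub-sample ids and the
    first column holding contig ids.  When ``subsample_read_counts`` is
    supplied (sub-sample id -> total paired-end reads), sub-samples below
    ``min_reads_per_subsample`` are dropped and the drop is logged;
    coverage tables alone cannot reconstruct read counts, so without the
    sidecar no gate is applied.
    """
    df = _read_tsv(path, index_col=0, dtype_backend="numpy_nullable")
    if df.index.has_duplicates:
        raise FormatError(f"duplicate contig ids in {path}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sub-sample ids in {path}")
    if df.isna().any().any():
        raise FormatError(f"missing or non-numeric coverage cells in {path}")
    try:
        values = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric coverage cell in {path}: {exc}") from exc
    if np.any(values < 0):
        raise FormatError(f"negative coverage cell in {path}")

    subsample_ids = [str(c) for c in df.columns]
    if subsample_read_counts is not None:
        keep = []
        for sid in subsample_ids:
            n_reads = subsample_read_counts.get(sid)
            if n_reads is not None and n_reads < min_reads_per_subsample:
                logger.info(
                    "dropping sub-sample %s: %d reads < %d",
                    sid, int(n_reads), min_reads_per_subsample,
                )
            else:
                keep.append(sid)
        values = values[:, [subsample_ids.index(s) for s in keep]]
        subsample_ids = keep

    contig_ids = [str(i) for i in df.index]
    lengths = None
    if contig_lengths is not None:
        missing = [c for c in contig_ids if c not in contig_lengths]
        if missing:
            raise ValidationError(f"no length for contigs {missing[:3]}...")
        lengths = np.array([contig_lengths[c] for c in contig_ids], dtype=np.int64)
    return CoverageMatrix(contig_ids, subsample_ids, values, lengths)


def read_contig_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Contig lengths from FASTA or a 2-column (contig_id, length) TSV.

    FASTA lengths are sequence character counts with line breaks excluded.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        lengths: dict[str, int] = {}
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in lengths:
                raise FormatError(f"duplicate FASTA id {rec.id!r}")
            if len(rec.seq) == 0:
                raise FormatError(f"empty sequence for {rec.id!r}")
            lengths[rec.id] = len(rec.seq)
        return lengths
    df = _read_tsv(path, header=0)
    if df.shape[1] < 2:
        raise FormatError("length TSV needs two columns: contig_id, length")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise FormatError("duplicate contig ids in length table")
    lens = df.iloc[:, 1].astype(int)
    if (lens <= 0).any():
        raise FormatError("contig lengths must be positive")
    return dict(zip(ids, lens))


def read_contig_sequences(path: str | os.PathLike) -> dict[str, str]:
    """Contig id -> uppercase sequence from FASTA."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_orf_table(path: str | os.PathLike) -> OrfTable:
    """ORF coordinates from a GFF-like TSV.

    Columns: contig_id, start, end, strand, gene_id (1-based inclusive).
    """
    df = _read_tsv(path)
    required = {"contig_id", "start", "end", "strand", "gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"ORF table missing columns {sorted(required - set(df.columns))}")
    records = [
        OrfRecord(str(r.contig_id), int(r.start), int(r.end), str(r.strand), str(r.gene_id))
        for r in df.itertuples()
    ]
    return OrfTable(records)


def read_snp_table(
    path: str | os.PathLike,
    on_multiallelic: str = "split",
) -> SnpTable:
    """Read biallelic SNPs from a VCF with per-sample AD fields.

    One :class:`SnpRecord` per biallelic SNP row; indel rows are skipped
    with a warning.  Multiallelic rows are split into one record per
    alternate allele (``on_multiallelic='split'``) or rejected
    (``'reject'``).  Positions remain 1-based.
    """
    if on_multiallelic not in {"split", "reject"}:
        raise ValueError("on_multiallelic must be 'split' or 'reject'")
    records: list[SnpRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = list(vf.header.samples)
        for row in vf:
            if row.qual is None:
                raise FormatError(
                    f"missing QUAL at {row.contig}:{row.pos}; site quality is required"
                )
            alts = row.alts or ()
            if len(alts) > 1 and on_multiallelic == "reject":
                raise FormatError(f"multiallelic row at {row.contig}:{row.pos}")
            for alt_index, alt in enumerate(alts):
                if len(row.ref) != 1 or len(alt) != 1 or alt == "*":
                    logger.warning("skipping indel at %s:%d", row.contig, row.pos)
                    continue
                depths: dict[str, tuple[int, int]] = {}
                for sid in samples:
                    ad = row.samples[sid].get("AD")
                    if ad is None or ad[0] is None:
                        depths[sid] = (0, 0)
                    else:
                        depths[sid] = (int(ad[0]), int(ad[alt_index + 1]))
                records.append(
                    SnpRecord(str(row.contig), int(row.pos), row.ref, alt, float(row.qual), depths)
                )
    return SnpTable(records, samples)


# ---------------------------------------------------------------------------
# Writers (atomic: write to a temp file, then rename)
# ---------------------------------------------------------------------------


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header_comment(params: Mapping[str, object] | None) -> str:
    from minimeta import __version__

    items = "".join(f" {k}={v}" for k, v in (params or {}).items())
    return f"# minimeta v{__version__}{items}\n"


def write_coverage_table(
    coverage: CoverageMatrix, path: str | os.PathLike, params: Mapping[str, object] | None = None
) -> None:
    text = _header_comment(params) + coverage.to_frame().to_csv(
        sep="\t", index_label="contig_id"
    )
    _atomic_write_text(path, text)


def write_contig_lengths(
    lengths: Mapping[str, int], path: str | os.PathLike, params: Mapping[str, object] | None = None
) -> None:
    lines = [_header_comment(params), "contig_id\tlength\n"]
    lines += [f"{cid}\t{ln}\n" for cid, ln in lengths.items()]
    _atomic_write_text(path, "".join(lines))


def write_contig_sequences(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    lines = []
    for cid, seq in seqs.items():
        lines.append(f">{cid}\n")
        for i in range(0, len(seq), 80):
            lines.append(seq[i : i + 80] + "\n")
    _atomic_write_text(path, "".join(lines))


def write_orf_table(
    orfs: OrfTable, path: str | os.PathLike, params: Mapping[str, object] | None = None
) -> None:
    lines = [_header_comment(params), "contig_id\tstart\tend\tstrand\tgene_id\n"]
    lines += [
        f"{r.contig_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.gene_id}\n" for r in orfs
    ]
    _atomic_write_text(path, "".join(lines))


def write_occurrence(
    occurrence, path: str | os.PathLike, params: Mapping[str, object] | None = None
) -> None:
    """Write a binary contig x sub-sample occurrence matrix as TSV."""
    merged = {"threshold": occurrence.threshold}
    merged.update(params or {})
    df = pd.DataFrame(
        occurrence.presence.astype(int),
        index=occurrence.contig_ids,
        columns=occurrence.subsample_ids,
    )
    text = _header_comment(merged) + df.to_csv(sep="\t", index_label="contig_id")
    _atomic_write_text(path, text)


def read_occurrence(path: str | os.PathLike):
    """Read an occurrence TSV written by :func:`write_occurrence`."""
    from minimeta.cooccurrence import OccurrenceMatrix

    threshold = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if token.startswith("threshold="):
                    threshold = float(token.split("=", 1)[1])
    df = _read_tsv(path, index_col=0)
    values = df.to_numpy(dtype=np.int8)
    return OccurrenceMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        values,
        threshold if threshold is not None else float("nan"),
    )


def write_bins(
    bins: Iterable,
    path: str | os.PathLike,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write genome bins as TSV (contig_id, bin_id, contig_length, consensus_lineage)."""
    lines = [_header_comment(params), "contig_id\tbin_id\tcontig_length\tconsensus_lineage\n"]
    for b in bins:
        lineage = b.consensus_lineage if b.consensus_lineage is not None else NA_TOKEN
        lengths = b.contig_lengths if b.contig_lengths is not None else {}
        for cid in b.contig_ids:
            ln = lengths.get(cid, NA_TOKEN) if isinstance(lengths, Mapping) else NA_TOKEN
            lines.append(f"{cid}\t{b.bin_id}\t{ln}\t{lineage}\n")
    _atomic_write_text(path, "".join(lines))


def read_bins(path: str | os.PathLike) -> list:
    """Read a bin table written by :func:`write_bins`."""
    from minimeta.binning import GenomeBin

    df = _read_tsv(path, dtype={"contig_id": str, "bin_id": str})
    bins: list[GenomeBin] = []
    for bin_id, grp in df.groupby("bin_id", sort=False):
        lengths = None
        if grp["contig_length"].notna().all():
            lengths = dict(zip(grp["contig_id"], grp["contig_length"].astype(int)))
        lineage = grp["consensus_lineage"].iloc[0]
        bins.append(
            GenomeBin(
                bin_id=str(bin_id),
                contig_ids=list(grp["contig_id"]),
                contig_lengths=lengths,
                consensus_lineage=None if pd.isna(lineage) else str(lineage),
            )
        )
    return bins


def write_snp_table(
    snps: SnpTable,
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNPs as VCFv4.2 with per-sample AD fields."""
    header = pysam.VariantHeader()
    header.add_meta("source", "minimeta")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    contigs = {r.contig_id for r in snps}
    if contig_lengths:
        contigs |= set(contig_lengths)
    for cid in sorted(contigs):
        if contig_lengths and cid in contig_lengths:
            header.contigs.add(cid, length=int(contig_lengths[cid]))
        else:
            header.contigs.add(cid)
    for sid in snps.subsample_ids:
        header.add_sample(sid)
    path = os.fspath(path)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for rec in sorted(snps.records, key=lambda r: (r.contig_id, r.position)):
            row = vf.new_record(
                contig=rec.contig_id,
                start=rec.position - 1,
                alleles=(rec.ref, rec.alt),
                qual=rec.quality,
            )
            for sid in snps.subsample_ids:
                rd, ad = rec.depths.get(sid, (0, 0))
                row.samples[sid]["AD"] = (rd, ad)
            vf.write(row)
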