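"""Population variation within genome bins: SNP filtering, classification
and dN/dS.

Variant calls made over all sub-samples jointly are filtered with three
confidence rules before any interpretation:

1. site quality strictly greater than ``quality_min`` (default 180, on
   the caller's QUAL scale, taken at face value);
2. per-sub-sample allele calls are made only where the sub-sample has at
   least ``depth_min`` reads (default 5) at the site — a sub-sample with
   both alleles at or above the depth floor is called heterozygous and
   contributes one dominant and one alternate allele to tallies, since
   it likely held multiple cells of the genome;
3. the alternate allele must appear as the only allele in at least one
   sub-sample.

Surviving SNPs are classified against ORF coordinates as noncoding,
synonymous or nonsynonymous (bacterial/archaeal translation table 11 by
default), and summarized per bin as a SNP rate (SNPs per assembled bp)
and a dN/dS ratio.  dN/dS uses equal-rate (NG86-style) site counting
over the bin's coding regions by default — each codon position
contributes the fraction of its three possible substitutions that are
synonymous to the synonymous site total — so a value near 1 indicates no
selection and values near 0 strong purifying selection.  The raw
nonsynonymous/synonymous count ratio is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from minimeta.binning import GenomeBin
from minimeta.io_formats import OrfRecord, OrfTable, SnpRecord, SnpTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_QUALITY_MIN = 180.0
DEFAULT_DEPTH_MIN = 5
DEFAULT_TRANSLATION_TABLE = 11

CALL_DOMINANT = "dominant"
CALL_ALTERNATE = "alternate"
CALL_HETEROZYGOUS = "heterozygous"
CALL_ABSENT = "absent"

CLASS_NONCODING = "noncoding"
CLASS_SYNONYMOUS = "synonymous"
CLASS_NONSYNONYMOUS = "nonsynonymous"

DNDS_METHODS = ("ng86", "count-ratio")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = ("A", "C", "G", "T")


@dataclass
class FilteredSnp:
    """A SNP that passed all confidence filters, with per-chamber calls."""

    record: SnpRecord
    calls: dict[str, str]
    classification: str | None = None

    @property
    def contig_id(self) -> str:
        return self.record.contig_id

    @property
    def position(self) -> int:
        return self.record.position


@dataclass
class VariationSummary:
    """Per-bin variation report."""

    bin_id: str
    n_noncoding: int
    n_synonymous: int
    n_nonsynonymous: int
    assembled_length: int
    snp_rate: float
    dn_ds: float | None
    dn_ds_method: str = "ng86"

    @property
    def n_snps(self) -> int:
        return self.n_noncoding + self.n_synonymous + self.n_nonsynonymous


def _call_subsample(ref_depth: int, alt_depth: int, depth_min: int) -> str:
    """Allele call for one sub-sample at one site."""
    if ref_depth + alt_depth < depth_min:
        return CALL_ABSENT
    if ref_depth >= depth_min and alt_depth >= depth_min:
        return CALL_HETEROZYGOUS
    # one allele dominates; call the majority allele
    return CALL_DOMINANT if ref_depth > alt_depth else CALL_ALTERNATE


def filter_snps(
    snps: SnpTable | Sequence[SnpRecord],
    quality_min: float = DEFAULT_QUALITY_MIN,
    depth_min: int = DEFAULT_DEPTH_MIN,
) -> list[FilteredSnp]:
    """Apply the quality / depth / alternate-only confidence filters.

    Retains SNPs with site quality > ``quality_min`` and at least one
    sub-sample where the alternate allele is the only allele observed
    (alt reads >= ``depth_min`` and zero reference reads).  Per-sample
    calls are recorded for downstream allele tallies; an empty result is
    allowed.
    """
    out: list[FilteredSnp] = []
    for rec in snps:
        if rec.quality <= quality_min:
            continue
        calls = {
            sid: _call_subsample(rd, ad, depth_min) for sid, (rd, ad) in sorted(rec.depths.items())
        }
        alt_only = any(
            ad >= depth_min and rd == 0 for rd, ad in rec.depths.values()
        )
        if not alt_only:
            continue
        out.append(FilteredSnp(rec, calls))
    return out


def allele_tallies(snp: FilteredSnp) -> tuple[int, int]:
    """(dominant, alternate) allele counts over sub-samples.

    A heterozygous sub-sample contributes one of each.
    """
    dom = alt = 0
    for call in snp.calls.values():
        if call == CALL_DOMINANT:
            dom += 1
        elif call == CALL_ALTERNATE:
            alt += 1
        elif call == CALL_HETEROZYGOUS:
            dom += 1
            alt += 1
    return dom, alt


def _codon_for_position(
    orf: OrfRecord, position: int, seq: str
) -> tuple[str, int] | None:
    """Codon containing a 1-based contig position, and the offset within it.

    Returns ``None`` for positions in an incomplete trailing codon.  The
    codon is given in coding orientation (reverse-complemented for the
    minus strand).
    """
    if len(orf) % 3 != 0:
        logger.warning(
            "ORF %s length %d not a multiple of 3; reading frame taken from its start",
            orf.gene_id, len(orf),
        )
    if orf.strand == "+":
        offset = position - orf.start
    else:
        offset = orf.end - position
    codon_index = offset // 3
    within = offset % 3
    if 3 * codon_index + 3 > len(orf):
        return None
    if orf.strand == "+":
        s = orf.start - 1 + 3 * codon_index
        codon = seq[s : s + 3]
    else:
        e = orf.end - 3 * codon_index
        codon = seq[e - 3 : e].translate(_COMPLEMENT)[::-1]
    return codon.upper(), within


def _translate(codon: str, table: CodonTable.CodonTable) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table.get(codon, "X")


def classify_snp(
    snp: FilteredSnp | SnpRecord,
    orfs: OrfTable,
    contig_seq: str,
    translation_table: int = DEFAULT_TRANSLATION_TABLE,
) -> str:
    """Classify a SNP as noncoding, synonymous or nonsynonymous.

    The alternate base is substituted into the codon containing the site
    (reverse-complemented on the minus strand) and the encoded amino
    acids compared.  A site inside overlapping ORFs is nonsynonymous if
    the substitution changes the protein of any of them (conservative).
    """
    rec = snp.record if isinstance(snp, FilteredSnp) else snp
    table = CodonTable.unambiguous_dna_by_id[translation_table]
    pos = rec.position
    if not 1 <= pos <= len(contig_seq):
        raise ValidationError(
            f"SNP position {pos} outside contig {rec.contig_id!r} (length {len(contig_seq)})"
        )
    ref_base = contig_seq[pos - 1].upper()
    if ref_base != rec.ref.upper():
        logger.warning(
            "reference mismatch at %s:%d (sequence %s, record %s)",
            rec.contig_id, pos, ref_base, rec.ref,
        )
    hits = [o for o in orfs.on_contig(rec.contig_id) if o.start <= pos <= o.end]
    if len(hits) > 1:
        logger.info("SNP %s:%d lies in %d overlapping ORFs", rec.contig_id, pos, len(hits))
    verdicts = []
    for orf in hits:
        located = _codon_for_position(orf, pos, contig_seq)
        if located is None:
            continue
        codon, within = located
        alt_base = rec.alt.upper() if orf.strand == "+" else rec.alt.upper().translate(_COMPLEMENT)
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        verdicts.append(
            CLASS_SYNONYMOUS
            if _translate(codon, table) == _translate(alt_codon, table)
            else CLASS_NONSYNONYMOUS
        )
    if not verdicts:
        return CLASS_NONCODING
    return CLASS_NONSYNONYMOUS if CLASS_NONSYNONYMOUS in verdicts else CLASS_SYNONYMOUS


def classify_snps(
    snps: Sequence[FilteredSnp],
    orfs: OrfTable,
    contig_seqs: Mapping[str, str],
    translation_table: int = DEFAULT_TRANSLATION_TABLE,
) -> list[FilteredSnp]:
    """Classify each filtered SNP in place (returns the same objects)."""
    for snp in snps:
        seq = contig_seqs.get(snp.contig_id)
        if seq is None:
            raise ValidationError(f"no sequence for contig {snp.contig_id!r}")
        snp.classification = classify_snp(snp, orfs, seq, translation_table)
    return list(snps)


def snp_rate(n_snps: int, assembled_length: int) -> float:
    """SNPs per assembled base pair."""
    if assembled_length <= 0:
        raise ValidationError("assembled length must be positive")
    return n_snps / assembled_length


def count_sites(
    orfs: OrfTable,
    contig_seqs: Mapping[str, str],
    contig_ids: Sequence[str] | None = None,
    translation_table: int = DEFAULT_TRANSLATION_TABLE,
) -> tuple[float, float]:
    """Equal-rate (synonymous, nonsynonymous) site counts over coding regions.

    Each codon position contributes f/3-of-3 fractions: the fraction of
    its three possible base changes that preserve the amino acid counts
    toward synonymous sites, the rest toward nonsynonymous sites.  Stop
    codons in-frame are skipped.
    """
    table = CodonTable.unambiguous_dna_by_id[translation_table]
    syn = nonsyn = 0.0
    wanted = set(contig_ids) if contig_ids is not None else None
    for orf in orfs:
        if wanted is not None and orf.contig_id not in wanted:
            continue
        seq = contig_seqs.get(orf.contig_id)
        if seq is None:
            raise ValidationError(f"no sequence for contig {orf.contig_id!r}")
        if orf.strand == "+":
            coding = seq[orf.start - 1 : orf.end].upper()
        else:
            coding = seq[orf.start - 1 : orf.end].upper().translate(_COMPLEMENT)[::-1]
        for i in range(0, len(coding) - len(coding) % 3, 3):
            codon = coding[i : i + 3]
            if codon in table.stop_codons or any(b not in _BASES for b in codon):
                continue
            aa = _translate(codon, table)
            for within in range(3):
                n_syn_changes = sum(
                    1
                    for b in _BASES
                    if b != codon[within]
                    and _translate(codon[:within] + b + codon[within + 1 :], table) == aa
                )
                syn += n_syn_changes / 3.0
                nonsyn += (3 - n_syn_changes) / 3.0
    return syn, nonsyn


def dn_ds(
    n_synonymous: int,
    n_nonsynonymous: int,
    syn_sites: float | None = None,
    nonsyn_sites: float | None = None,
    method: str = "ng86",
) -> float | None:
    """dN/dS from class tallies and (for ``ng86``) site counts.

    ``ng86``: (nonsyn count / nonsyn sites) / (syn count / syn sites).
    ``count-ratio``: plain nonsyn/syn count ratio.  Returns ``None``
    (undefined) when the synonymous tally is zero.
    """
    if method not in DNDS_METHODS:
        raise ValueError(f"unknown dN/dS method {method!r}; use one of {DNDS_METHODS}")
    if n_synonymous == 0:
        return None
    if method == "count-ratio":
        return n_nonsynonymous / n_synonymous
    if syn_sites is None or nonsyn_sites is None or syn_sites <= 0 or nonsyn_sites <= 0:
        raise ValidationError("ng86 dN/dS needs positive synonymous and nonsynonymous site counts")
    return (n_nonsynonymous / nonsyn_sites) / (n_synonymous / syn_sites)


def summarize_variation(
    bin_: GenomeBin,
    snps: Sequence[FilteredSnp],
    orfs: OrfTable,
    contig_seqs: Mapping[str, str],
    assembled_length: int | None = None,
    method: str = "ng86",
    translation_table: int = DEFAULT_TRANSLATION_TABLE,
) -> VariationSummary:
    """Classify a bin's SNPs and compute its SNP rate and dN/dS.

    ``assembled_length`` defaults to the bin's total contig length (the
    assembled-size denominator); pass the total sequenced length to use
    the alternative normalization.
    """
    members = set(bin_.contig_ids)
    mine = [s for s in snps if s.contig_id in members]
    classify_snps(mine, orfs, contig_seqs, translation_table)
    tallies = {CLASS_NONCODING: 0, CLASS_SYNONYMOUS: 0, CLASS_NONSYNONYMOUS: 0}
    for s in mine:
        tallies[s.classification] += 1
    if assembled_length is None:
        assembled_length = bin_.total_length
        if assembled_length is None:
            raise ValidationError(f"bin {bin_.bin_id} carries no contig lengths")
    syn_sites, nonsyn_sites = count_sites(orfs, contig_seqs, bin_.contig_ids, translation_table)
    if tallies[CLASS_SYNONYMOUS] == 0:
        ratio = None
    elif method == "ng86":
        ratio = dn_ds(tallies[CLASS_SYNONYMOUS], tallies[CLASS_NONSYNONYMOUS],
                      syn_sites, nonsyn_sites, method="ng86")
    else:
        ratio = dn_ds(tallies[CLASS_SYNONYMOUS], tallies[CLASS_NONSYNONYMOUS],
                      method="count-ratio")
    return VariationSummary(
        bin_id=bin_.bin_id,
        n_noncoding=tallies[CLASS_NONCODING],
        n_synonymous=tallies[CLASS_SYNONYMOUS],
        n_nonsynonymous=tallies[CLASS_NONSYNONYMOUS],
        assembled_length=int(assembled_length),
        snp_rate=snp_rate(sum(tallies.values()), int(assembled_length)),
        dn_ds=ratio,
        dn_ds_method=method,
    )
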