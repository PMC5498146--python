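"""Per-bin KEGG-module gene ratios.

For each genome bin and each KEGG module, the statistic is the fraction
of the module's KO terms found among the bin's KO assignments:

    ratio[bin, module] = |bin KOs  ∩  module KOs| / |module KOs|

Set semantics throughout — duplicated KO assignments within a bin do not
change the ratio — and deliberately no normalization by genome size or
completeness, which would inflate the apparent importance of genes from
small or partial genomes.  Module definitions are supplied by the user
as a TSV; there is no live KEGG access.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from minimeta.io_formats import FormatError, _atomic_write_text, _header_comment, _read_tsv


@dataclass(frozen=True)
class ModuleDefinition:
    """A KEGG module: an id, a display name and its set of KO terms."""

    module_id: str
    name: str
    ko_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ko_terms:
            raise FormatError(f"module {self.module_id!r} has an empty KO set")


def read_module_definitions(path: str | os.PathLike) -> list[ModuleDefinition]:
    """Load module definitions from TSV (module_id, name, comma-separated KOs)."""
    df = _read_tsv(path, dtype=str)
    required = {"module_id", "name", "ko_terms"}
    if not required.issubset(df.columns):
        raise FormatError(f"module table missing columns {sorted(required - set(df.columns))}")
    modules = []
    for row in df.itertuples():
        if pd.isna(row.ko_terms) or not str(row.ko_terms).strip():
            raise FormatError(f"module {row.module_id!r} has an empty KO set")
        kos = frozenset(k.strip() for k in str(row.ko_terms).split(",") if k.strip())
        modules.append(ModuleDefinition(str(row.module_id), str(row.name), kos))
    return modules


def read_ko_assignments(path: str | os.PathLike) -> pd.DataFrame:
    """Per-gene KO assignments from TSV (contig_id, gene_id, ko)."""
    df = _read_tsv(path, dtype=str)
    required = {"contig_id", "gene_id", "ko"}
    if not required.issubset(df.columns):
        raise FormatError(f"KO table missing columns {sorted(required - set(df.columns))}")
    return df


def bin_ko_sets(ko_assignments: pd.DataFrame, bins: Iterable) -> dict[str, set[str]]:
    """Collect each bin's distinct KO terms from per-gene assignments."""
    by_contig: dict[str, set[str]] = {}
    for row in ko_assignments.itertuples():
        if pd.notna(row.ko):
            by_contig.setdefault(str(row.contig_id), set()).add(str(row.ko))
    out: dict[str, set[str]] = {}
    for b in bins:
        if getattr(b, "is_unbinned", False):
            continue
        kos: set[str] = set()
        for cid in b.contig_ids:
            kos |= by_contig.get(cid, set())
        out[b.bin_id] = kos
    return out


def compute_module_ratios(
    bin_kos: Mapping[str, set[str]],
    modules: Sequence[ModuleDefinition],
) -> pd.DataFrame:
    """Bins x modules matrix of KO-coverage fractions in [0, 1]."""
    data = {
        m.module_id: [
            len(set(bin_kos[b]) & m.ko_terms) / len(m.ko_terms) for b in bin_kos
        ]
        for m in modules
    }
    return pd.DataFrame(data, index=list(bin_kos))


def write_module_ratios(
    ratios: pd.DataFrame, path: str | os.PathLike, params: Mapping[str, object] | None = None
) -> None:
    text = _header_comment(params) + ratios.to_csv(sep="\t", index_label="bin_id")
    _atomic_write_text(path, text)
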