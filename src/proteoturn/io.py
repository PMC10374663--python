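"""Readers and writers for the tabular formats the pipeline touches.

Vendor tables (MaxQuant proteinGroups, Spectronaut reports) are mapped onto
the package's logical column names through a :class:`ColumnMap`, so header
differences between software versions stay out of the analysis code. All
writers emit tab-separated UTF-8 with '.' decimals; ``read(write(x))``
round-trips every typed table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ColumnMap",
    "read_quant_table",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
]

# logical fields that must be numeric after mapping
_NUMERIC_FIELDS = {
    "ratio_hl", "intensity_h", "intensity_l", "time_h",
    "n_unique_peptides", "temp_c", "abundance", "intensity",
}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from logical field names to source column headers."""

    mapping: Mapping[str, str]
    dialect: str = "generic"

    @classmethod
    def maxquant(cls, **overrides: str) -> "ColumnMap":
        base = {
            "protein_id": "Protein IDs",
            "ratio_hl": "Ratio H/L",
            "intensity_h": "Intensity H",
            "intensity_l": "Intensity L",
            "n_unique_peptides": "Unique peptides",
            "reverse": "Reverse",
            "contaminant": "Potential contaminant",
        }
        base.update(overrides)
        return cls(base, dialect="maxquant")

    @classmethod
    def spectronaut(cls, **overrides: str) -> "ColumnMap":
        base = {
            "protein_id": "PG.ProteinGroups",
            "abundance": "PG.Quantity",
        }
        base.update(overrides)
        return cls(base, dialect="spectronaut")

    @classmethod
    def generic(cls, **overrides: str) -> "ColumnMap":
        """Identity mapping for tidy tables already using logical names."""
        base = {
            "protein_id": "protein_id",
            "strain": "strain",
            "replicate": "replicate",
            "time_h": "time_h",
            "ratio_hl": "ratio_hl",
            "intensity_h": "intensity_h",
            "intensity_l": "intensity_l",
            "ria": "ria",
            "n_unique_peptides": "n_unique_peptides",
            "temp_c": "temp_c",
            "abundance": "abundance",
        }
        base.update(overrides)
        return cls(base, dialect="generic")


def read_quant_table(
    path: str | Path,
    column_map: ColumnMap,
    zero_as_missing: bool = True,
) -> pd.DataFrame:
    """Read a vendor quantification table into logical columns.

    Only mapped columns that exist are required to be *numeric-parseable*;
    malformed numeric cells raise a row-level warning and become NaN. Zero
    intensities are treated as missing by default (the common DIA/LFQ
    convention). Decoy/contaminant indicator columns, when mapped, are
    carried through unchanged for downstream filtering.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [src for src in column_map.mapping.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"mapped column(s) absent from {path.name}: {missing}")
    out = pd.DataFrame(index=raw.index)
    for logical, src in column_map.mapping.items():
        col = raw[src]
        if logical in _NUMERIC_FIELDS:
            parsed = pd.to_numeric(col, errors="coerce")
            bad = parsed.isna() & col.notna() & (col.str.strip() != "") & (
                col.str.lower() != "nan"
            )
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} malformed numeric value(s) in column "
                    f"{src!r}; set to missing",
                    stacklevel=2,
                )
            if zero_as_missing and logical.startswith(("intensity", "abundance")):
                parsed = parsed.replace(0.0, np.nan)
            out[logical] = parsed
        else:
            out[logical] = col
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; UniProt-style accessions become the keys.

    Headers like ``sp|P12345|NAME_YEAST`` yield ``P12345``; other headers
    use the first whitespace-delimited token. Duplicate accessions and
    empty files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        acc = parts[1] if len(parts) >= 3 and parts[1] else rec.id
        if acc in seqs:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seqs[acc] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    """Write sequences with UniProt-style ``sp|ACC|ACC_SYNTH`` headers."""
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">sp|{acc}|{acc}_SYNTH\n{seq}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a typed table as tab-separated UTF-8."""
    df.to_csv(path, sep="\t", index=index, encoding="utf-8")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a tab-separated table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col, encoding="utf-8")
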