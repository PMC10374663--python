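"""Intensity-matrix utilities: validity filtering, imputation, iBAQ.

Implements the standard Perseus-style preprocessing of MS intensity
matrices — keep features with more than a given fraction of valid values in
at least one condition, impute the remaining missing values from a
downshifted normal distribution per sample (left-censored missingness
model), strip decoy/contaminant rows — plus intensity-based absolute
quantification (iBAQ): summed peptide intensity divided by the number of
theoretically observable peptides from an in-silico digest. A dedicated
mode restricts iBAQ to light-channel, lysine-containing peptides, the proxy
for newly synthesized protein abundance in a lysine pSILAC chase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser

__all__ = [
    "DigestSpec",
    "filter_valid",
    "impute_downshift",
    "count_theoretical_peptides",
    "ibaq",
    "filter_decoys_contaminants",
]

logger = logging.getLogger(__name__)

# cleavage regexes: cut after the matched residue
_PROTEASE_RULES = {
    "trypsin": r"[KR](?!P)",
    "lysc": r"K",
}


@dataclass(frozen=True)
class DigestSpec:
    """In-silico digestion parameters for the iBAQ denominator."""

    protease: str = "trypsin"
    min_len: int = 7
    max_len: int = 30
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.protease not in _PROTEASE_RULES:
            raise ValueError(f"unknown protease {self.protease!r}")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def filter_valid(
    matrix: pd.DataFrame, groups: Mapping[str, str], min_frac: float = 0.5
) -> pd.DataFrame:
    """Keep rows with more than ``min_frac`` valid values in some group.

    ``groups`` maps each sample column to its experimental condition. The
    inequality is strict: a row with exactly half of a group's values valid
    does not qualify through that group.
    """
    keep = np.zeros(len(matrix), dtype=bool)
    for group in dict.fromkeys(groups.values()):
        cols = [c for c, g in groups.items() if g == group]
        frac = matrix[cols].notna().sum(axis=1) / len(cols)
        keep |= (frac > min_frac).to_numpy()
    return matrix[keep]


def impute_downshift(
    matrix: pd.DataFrame,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing values from a downshifted normal, per sample.

    For each column, missing cells are drawn from
    ``Normal(mean_obs - shift * sd_obs, (width * sd_obs)**2)`` where
    mean/sd are over the observed values of that column — emulating the
    left-censored tail of low-abundance features. Observed values are never
    overwritten. Returns ``(imputed, mask)`` with a boolean mask of imputed
    cells; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    mask = matrix.isna()
    for col in matrix.columns:
        obs = matrix[col].dropna()
        n_miss = int(mask[col].sum())
        if n_miss == 0:
            continue
        if len(obs) < 2:
            raise ValueError(
                f"column {col!r} has fewer than 2 observed values; "
                "cannot estimate imputation moments"
            )
        mu = obs.mean() - shift * obs.std(ddof=1)
        sd = width * obs.std(ddof=1)
        out.loc[mask[col], col] = rng.normal(mu, sd, size=n_miss)
    return out, mask


def count_theoretical_peptides(protein_seq: str, spec: DigestSpec = DigestSpec()) -> int:
    """Number of theoretically observable peptides from an in-silico digest.

    Peptides are enumerated positionally (fully cleaved plus up to
    ``missed_cleavages`` missed sites) and counted when their length lies
    within ``[min_len, max_len]``. A sequence without cleavage sites yields
    the whole chain as its single peptide.
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    rule = _PROTEASE_RULES[spec.protease]
    seen = {
        (pos, pep)
        for pos, pep in pyt_parser.icleave(
            protein_seq, rule, missed_cleavages=spec.missed_cleavages
        )
        if spec.min_len <= len(pep) <= spec.max_len
    }
    return len(seen)


def ibaq(
    peptides: pd.DataFrame,
    protein_seq: str,
    spec: DigestSpec = DigestSpec(),
    newly_synthesized: bool = False,
) -> float:
    """Intensity-based absolute quantification of one protein.

    ``peptides`` needs columns peptide_seq and intensity (and channel,
    'L'/'H', when ``newly_synthesized`` is on). The iBAQ value is the sum of
    qualifying peptide intensities divided by the theoretical peptide count
    of the protein. In newly-synthesized mode only light-channel,
    lysine-containing peptides qualify — the signature of proteins made
    after a light-lysine pulse. Returns NaN (logged) when the protein has
    zero theoretical peptides.
    """
    n_theoretical = count_theoretical_peptides(protein_seq, spec)
    if n_theoretical == 0:
        logger.warning("zero theoretical peptides; iBAQ undefined")
        return float("nan")
    sub = peptides
    if newly_synthesized:
        has_lys = sub["peptide_seq"].str.contains("K")
        light = sub["channel"].eq("L") if "channel" in sub.columns else True
        sub = sub[has_lys & light]
    return float(sub["intensity"].sum()) / n_theoretical


def filter_decoys_contaminants(
    table: pd.DataFrame,
    reverse_col: str = "reverse",
    contaminant_col: str = "contaminant",
    flag: str = "+",
) -> pd.DataFrame:
    """Remove reverse-decoy and common-contaminant rows.

    Rows whose indicator column equals ``flag`` are dropped; removed counts
    are logged. Missing indicator columns produce a warning and are ignored
    (pass-through).
    """
    keep = np.ones(len(table), dtype=bool)
    for col, what in ((reverse_col, "decoy"), (contaminant_col, "contaminant")):
        if col not in table.columns:
            warnings.warn(f"indicator column {col!r} absent; skipping {what} filter",
                          stacklevel=2)
            continue
        flagged = (table[col] == flag).to_numpy()
        logger.info("removing %d %s rows", int(flagged.sum()), what)
        keep &= ~flagged
    return table[keep]
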