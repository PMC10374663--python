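"""N-terminal peptide validation, NAT substrate classification, summaries.

Co-translational N-terminal acetylation is installed by N-terminal
acetyltransferase (NAT) complexes whose specificity is read off the first
residues of the mature N-terminus:

* **NatA** acts on the small residues Ala, Thr, Ser, Val and Gly exposed
  after the initiator methionine (iMet) has been excised by methionine
  aminopeptidases (start position 2).
* **NatB** acts on Met-retained termini with Asp, Asn, Glu or Gln at
  position +2.
* **NatC-type** (including NatE overlap) acts on Met-retained termini with a
  hydrophobic +2 residue; canonically Met-Phe and Met-Leu, extended here to
  Ile and Trp per the standard NatC specificity (configurable).

Only peptides covering the first or second residue of the annotated protein
sequence are valid N-terminal evidence; everything else is an internal
peptide. Coordinates are 1-based: start position 1 means iMet retained,
start position 2 means iMet cleaved.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "NAT_A_RESIDUES",
    "NAT_B_RESIDUES",
    "NAT_C_RESIDUES",
    "validate_nt_peptide",
    "nat_class",
    "classify_table",
    "collapse_redundant",
    "acetylation_summary",
    "match_wt_acetyl_ko_free",
    "sequence_window",
    "logo_contrast",
]

#: NatA substrates: position-2 residues acetylated after iMet excision.
#: Cys is deliberately not included (configurable via the ``nata`` argument).
NAT_A_RESIDUES = frozenset("ATSVG")
#: NatB substrates: +2 residues behind a retained iMet.
NAT_B_RESIDUES = frozenset("DNEQ")
#: NatC/NatE-type substrates: hydrophobic +2 residues behind a retained iMet.
NAT_C_RESIDUES = frozenset("LFIW")


def validate_nt_peptide(peptide_seq: str, protein_seq: str) -> tuple[bool, int | None]:
    """Check whether a peptide is genuine N-terminal evidence.

    Valid iff the peptide matches the annotated protein prefix at residue 1
    (iMet retained) or residue 2 (iMet cleaved). Returns
    ``(valid, start_pos)`` with 1-based start position, or ``(False, None)``
    for internal peptides.
    """
    if not peptide_seq or not protein_seq:
        return False, None
    if protein_seq.startswith(peptide_seq):
        return True, 1
    if protein_seq[1:].startswith(peptide_seq):
        return True, 2
    return False, None


def nat_class(
    peptide_seq: str,
    start_pos: int,
    nata: frozenset[str] = NAT_A_RESIDUES,
    natb: frozenset[str] = NAT_B_RESIDUES,
    natc: frozenset[str] = NAT_C_RESIDUES,
) -> str:
    """Assign the NAT substrate class of a valid N-terminal peptide.

    iMet-cleaved termini (start 2) beginning with a NatA residue are NatA;
    Met-retained termini (start 1) are NatB or NatC-type by their +2
    residue; everything else is ``unclassified``. The three residue sets
    partition every input into exactly one class.
    """
    if start_pos == 2:
        return "NatA" if peptide_seq[:1] in nata else "unclassified"
    if start_pos == 1:
        pos2 = peptide_seq[1:2]
        if pos2 in natb:
            return "NatB"
        if pos2 in natc:
            return "NatC_E"
        return "unclassified"
    raise ValueError(f"start_pos must be 1 or 2, got {start_pos}")


def classify_table(
    records: pd.DataFrame,
    sequences: Mapping[str, str] | None = None,
    **residue_sets,
) -> pd.DataFrame:
    """Validate and classify a table of Nt-peptide observations.

    ``records`` needs protein_id and peptide_seq columns; if ``sequences``
    (protein id -> sequence) is given, peptides are validated against the
    annotated sequence and invalid (internal) peptides dropped, otherwise a
    start_pos column must already be present. Adds start_pos and nat_class.
    """
    out = records.copy()
    if sequences is not None:
        valid_flags, starts = [], []
        for pid, pep in zip(out["protein_id"], out["peptide_seq"]):
            ok, start = validate_nt_peptide(pep, sequences.get(pid, ""))
            valid_flags.append(ok)
            starts.append(start)
        out["start_pos"] = starts
        out = out[pd.Series(valid_flags, index=out.index)].copy()
        out["start_pos"] = out["start_pos"].astype(int)
    elif "start_pos" not in out.columns:
        raise ValueError("either sequences or a start_pos column is required")
    out["nat_class"] = [
        nat_class(pep, start, **residue_sets)
        for pep, start in zip(out["peptide_seq"], out["start_pos"])
    ]
    return out


def collapse_redundant(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse observations to non-redundant N-termini.

    One row per (protein_id, start_pos, genotype); a terminus counts as
    acetylated when any constituent observation is acetylated. The number
    of constituent observations is retained.
    """
    keys = ["protein_id", "start_pos"]
    if "genotype" in records.columns:
        keys.append("genotype")
    agg: dict[str, tuple] = {
        "acetylated": ("acetylated", "any"),
        "n_observations": ("acetylated", "size"),
        "peptide_seq": ("peptide_seq", "first"),
    }
    if "nat_class" in records.columns:
        agg["nat_class"] = ("nat_class", "first")
    return records.groupby(keys, sort=False).agg(**agg).reset_index()


def acetylation_summary(
    table: pd.DataFrame, genotypes: Sequence[str] | None = None
) -> dict:
    """Acetylation fractions per genotype, NatA share, and the KO reduction.

    On a collapsed (non-redundant) classified table, computes per genotype
    the fraction of N-termini acetylated and, among acetylated termini, the
    fraction that are NatA-class substrates. With two genotypes (reference
    first) the relative reduction of the acetylated fraction,
    ``(f_ref - f_alt) / f_ref``, is reported as well.
    """
    if genotypes is None:
        genotypes = list(dict.fromkeys(table["genotype"]))
    per_genotype = {}
    for g in genotypes:
        sub = table[table["genotype"] == g]
        if len(sub) == 0:
            raise ValueError(f"no records for genotype {g!r}")
        frac = float(sub["acetylated"].mean())
        acet = sub[sub["acetylated"]]
        nata_share = (
            float((acet["nat_class"] == "NatA").mean()) if len(acet) else float("nan")
        )
        per_genotype[g] = {
            "n_termini": int(len(sub)),
            "fraction_acetylated": frac,
            "nata_share_of_acetylated": nata_share,
        }
    result = {"per_genotype": per_genotype}
    if len(genotypes) == 2:
        f0 = per_genotype[genotypes[0]]["fraction_acetylated"]
        f1 = per_genotype[genotypes[1]]["fraction_acetylated"]
        result["acetylation_reduction"] = (f0 - f1) / f0 if f0 > 0 else float("nan")
    return result


def match_wt_acetyl_ko_free(
    wt_table: pd.DataFrame, ko_table: pd.DataFrame
) -> pd.DataFrame:
    """Pair WT-acetylated NatA termini with their free counterpart in the KO.

    Selects (protein_id, start_pos = 2) NatA-class N-termini acetylated in
    the WT table and unmodified in the KO table — the operational definition
    of NatA-type substrates whose acetylation the knockout abolished. An
    empty result is allowed.
    """
    wt = wt_table[
        (wt_table["start_pos"] == 2)
        & (wt_table["nat_class"] == "NatA")
        & wt_table["acetylated"]
    ]
    ko = ko_table[
        (ko_table["start_pos"] == 2)
        & (ko_table["nat_class"] == "NatA")
        & ~ko_table["acetylated"].astype(bool)
    ]
    pairs = wt.merge(
        ko, on=["protein_id", "start_pos"], suffixes=("_wt", "_ko")
    )
    cols = ["protein_id", "start_pos"]
    extra = [c for c in ("peptide_seq_wt", "peptide_seq_ko") if c in pairs.columns]
    return pairs[cols + extra]


def sequence_window(sequences: Iterable[str], n: int = 5) -> pd.DataFrame:
    """Per-position residue counts over the first ``n`` residues.

    Returns an n x residues count matrix (rows = positions 1..n). The raw
    export behind sequence-logo rendering; drawing is out of scope.
    """
    counts: dict[int, dict[str, int]] = {i: {} for i in range(1, n + 1)}
    for seq in sequences:
        for i, res in enumerate(seq[:n], start=1):
            counts[i][res] = counts[i].get(res, 0) + 1
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    df.index.name = "position"
    return df.sort_index(axis=1)


def logo_contrast(
    sequences_a: Iterable[str], sequences_b: Iterable[str], n: int = 5
) -> pd.DataFrame:
    """Position-wise residue frequency differences between two groups (a - b)."""
    ca = sequence_window(sequences_a, n)
    cb = sequence_window(sequences_b, n)
    fa = ca.div(ca.sum(axis=1).replace(0, 1), axis=0)
    fb = cb.div(cb.sum(axis=1).replace(0, 1), axis=0)
    return fa.sub(fb, fill_value=0.0)
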