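"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage assumes:

* :func:`simulate_psilac` — first-order heavy-label loss with a shared
  per-strain dilution constant plus protein-specific degradation rates and
  multiplicative (log-additive) ratio noise.
* :func:`simulate_meltome` — sigmoidal four-parameter log-logistic melting
  curves with protein-specific T50, slope and plateaus.
* :func:`simulate_nterm` — Nt-peptides with initiator-methionine cleavage
  and genotype-dependent acetylation probabilities per NAT substrate class.
* :func:`simulate_quant_matrix` — log-normal intensity matrices with
  intensity-dependent (left-censored) missingness and injected group effects.

All generators are deterministic given the :class:`SimConfig` seed and return
the ground-truth parameters alongside the data, so recovery can be asserted
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from proteoturn.meltome import fourpl

__all__ = [
    "SimConfig",
    "EffectSpec",
    "ConfigError",
    "NME_POS2_RESIDUES",
    "simulate_psilac",
    "simulate_meltome",
    "simulate_nterm",
    "simulate_quant_matrix",
    "write_dataset",
]

LN2 = float(np.log(2.0))

#: Position-2 residues after which methionine aminopeptidases excise the
#: initiator Met (the small-residue N-end rule). Broader than the NatA
#: substrate set {A,T,S,V,G}: Cys and Pro are also cleaved but not NatA
#: substrates here.
NME_POS2_RESIDUES = frozenset("ACGPSTV")

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Position-2 residue pools per NAT class used by the generator. NatC-type
# termini are emitted with Phe/Leu only (the canonical Met-Phe / Met-Leu);
# the classifier's set is configurable and broader.
_CLASS_POS2 = {
    "NatA": "ATSVG",
    "NatB": "DNEQ",
    "NatC_E": "FL",
    "unclassified": "KRHMP",
}


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect injected into a subset of proteins.

    Effects apply in every strain/genotype except the first (reference)
    entry of ``kdil_per_strain`` / the WT genotype.
    """

    n_affected: int = 0
    kdeg_multiplier: float = 1.0
    delta_t50_c: float = 0.0
    log2fc: float = 0.0
    drop_acetylation: bool = False


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all four generators, with invariant checking.

    Defaults mirror the study conditions: six chase time points within two
    to three doublings of a 1.9 h cell cycle, a WT dilution constant
    ln(2)/1.9 per hour, log-normal degradation rates with median 0.05 per
    hour, and a 10-point 37–67 degC thermal gradient.
    """

    seed: int = 0
    n_proteins: int = 300
    n_replicates: int = 2
    timepoints_h: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.5, 6.0)
    kdil_per_strain: Mapping[str, float] = field(
        default_factory=lambda: {"WT": LN2 / 1.9}
    )
    kdeg_logmean: float = float(np.log(0.05))
    kdeg_logsd: float = 1.0
    ratio_noise_sd: float = 0.1
    missing_rate: float = 0.0
    melt_temps_c: tuple[float, ...] = tuple(np.linspace(37.0, 67.0, 10).round(2))
    t50_mean_c: float = 48.0
    t50_sd_c: float = 3.0
    slope_range: tuple[float, float] = (20.0, 60.0)
    plateau_range: tuple[float, float] = (0.0, 0.15)
    upper_plateau_range: tuple[float, float] = (0.9, 1.1)
    melt_noise_sd: float = 0.03
    quant_noise_sd: float = 0.3
    quant_log2_mean: float = 25.0
    quant_log2_sd: float = 2.0
    # Acetylation probability per NAT class, (WT, NatA-null) pair.
    acetyl_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "NatA": (0.9, 0.0),
            "NatB": (0.95, 0.95),
            "NatC_E": (0.6, 0.6),
            "unclassified": (0.05, 0.05),
        }
    )
    nat_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "NatA": 0.40,
            "NatB": 0.25,
            "NatC_E": 0.10,
            "unclassified": 0.25,
        }
    )
    effect_spec: Mapping[str, EffectSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size < 2:
            raise ConfigError("at least 2 timepoints required")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ConfigError("timepoints must be non-negative and strictly increasing")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")
        if not self.kdil_per_strain:
            raise ConfigError("kdil_per_strain must name at least one strain")
        for strain, kdil in self.kdil_per_strain.items():
            if not kdil > 0:
                raise ConfigError(f"kdil for strain {strain!r} must be > 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigError("missing_rate must lie in [0, 1]")
        if self.ratio_noise_sd < 0 or self.melt_noise_sd < 0 or self.quant_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        temps = np.asarray(self.melt_temps_c, dtype=float)
        if np.any(np.diff(temps) <= 0):
            raise ConfigError("melt temperatures must be strictly increasing")
        if temps.size < 8:
            raise ConfigError("at least 8 melt temperatures required by default")
        frac = sum(self.nat_class_fractions.values())
        if not np.isclose(frac, 1.0):
            raise ConfigError("nat_class_fractions must sum to 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kdil_per_strain"] = dict(self.kdil_per_strain)
        d["acetyl_probs"] = {k: list(v) for k, v in self.acetyl_probs.items()}
        d["nat_class_fractions"] = dict(self.nat_class_fractions)
        d["effect_spec"] = {k: dataclasses.asdict(v) for k, v in self.effect_spec.items()}
        return d


def _effect_labels(config: SimConfig) -> np.ndarray:
    """Assign each protein index its effect label ('' = background).

    Effects occupy consecutive index blocks starting at 0 so subsets are
    reproducible and disjoint.
    """
    labels = np.array([""] * config.n_proteins, dtype=object)
    start = 0
    for name, eff in config.effect_spec.items():
        stop = start + eff.n_affected
        if stop > config.n_proteins:
            raise ConfigError("effect_spec covers more proteins than n_proteins")
        labels[start:stop] = name
        start = stop
    return labels


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def simulate_psilac(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a pulsed-SILAC chase: heavy-label loss over time.

    The heavy fraction (relative isotope abundance, RIA) of protein *i* in a
    strain with dilution constant ``kdil`` decays as
    ``RIA(t) = exp(-(kdeg_i + kdil) * t)``. Noise is additive on ln(H/L)
    (log-normal on the ratio), the standard MS ratio error model. At t = 0
    the light channel is exactly zero, so rows carry the (H, L) intensity
    pair and the ratio is left undefined there rather than infinite.

    Returns
    -------
    (data, truth)
        ``data`` is a tidy table with columns protein_id, strain, replicate,
        time_h, intensity_h, intensity_l, ratio_hl, ria, n_unique_peptides;
        masked entries have NaN intensities/ratios. ``truth`` carries the
        generating kdeg/kdil per protein and strain.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = _protein_ids(n)
    effects = _effect_labels(config)
    kdeg = rng.lognormal(config.kdeg_logmean, config.kdeg_logsd, size=n)
    # per-protein unique peptide support; occasional singletons exercise filters
    n_pep = 1 + rng.poisson(4.0, size=n)
    base_total = rng.lognormal(np.log(1e6), 0.8, size=n)
    times = np.asarray(config.timepoints_h, dtype=float)

    strains = list(config.kdil_per_strain)
    rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for si, strain in enumerate(strains):
        kdil = float(config.kdil_per_strain[strain])
        kd = kdeg.copy()
        if si > 0:
            for name, eff in config.effect_spec.items():
                kd[effects == name] *= eff.kdeg_multiplier
        k_total = kd + kdil
        truth_rows.append(
            pd.DataFrame(
                {
                    "protein_id": ids,
                    "strain": strain,
                    "kdeg_true": kd,
                    "kdil_true": kdil,
                    "k_total_true": k_total,
                    "n_unique_peptides": n_pep,
                    "effect": effects,
                }
            )
        )
        for rep in range(1, config.n_replicates + 1):
            for t in times:
                ria_true = np.exp(-k_total * t)
                if t == 0.0:
                    h = base_total
                    light = np.zeros(n)
                    ratio = np.full(n, np.nan)
                    ria_obs = np.ones(n)
                else:
                    ln_ratio = np.log(ria_true / (1.0 - ria_true))
                    if config.ratio_noise_sd > 0:
                        ln_ratio = ln_ratio + rng.normal(
                            0.0, config.ratio_noise_sd, size=n
                        )
                    ratio = np.exp(ln_ratio)
                    ria_obs = ratio / (1.0 + ratio)
                    h = base_total * ria_obs
                    light = base_total - h
                miss = rng.random(n) < config.missing_rate
                rows.append(
                    pd.DataFrame(
                        {
                            "protein_id": ids,
                            "strain": strain,
                            "replicate": rep,
                            "time_h": t,
                            "intensity_h": np.where(miss, np.nan, h),
                            "intensity_l": np.where(miss, np.nan, light),
                            "ratio_hl": np.where(miss, np.nan, ratio),
                            "ria": np.where(miss, np.nan, ria_obs),
                            "missing": miss,
                            "n_unique_peptides": n_pep,
                        }
                    )
                )
    data = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return data, truth


def simulate_meltome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate thermal-proteome-profiling soluble fractions.

    Each protein gets its own (a, d, b, T50); abundances are the 4PL forward
    model times log-normal noise of relative scale ``melt_noise_sd``.
    Injected ``delta_t50_c`` effects shift the non-reference strain.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_proteins
    ids = _protein_ids(n)
    effects = _effect_labels(config)
    a = rng.uniform(*config.upper_plateau_range, size=n)
    d = rng.uniform(*config.plateau_range, size=n)
    b = rng.uniform(*config.slope_range, size=n)
    t50 = rng.normal(config.t50_mean_c, config.t50_sd_c, size=n)
    temps = np.asarray(config.melt_temps_c, dtype=float)

    rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for si, strain in enumerate(config.kdil_per_strain):
        t50_s = t50.copy()
        if si > 0:
            for name, eff in config.effect_spec.items():
                t50_s[effects == name] += eff.delta_t50_c
        truth_rows.append(
            pd.DataFrame(
                {
                    "protein_id": ids,
                    "strain": strain,
                    "a_true": a,
                    "d_true": d,
                    "b_true": b,
                    "t50_true": t50_s,
                    "effect": effects,
                }
            )
        )
        for rep in range(1, config.n_replicates + 1):
            for temp in temps:
                y = fourpl(temp, a, d, b, t50_s)
                if config.melt_noise_sd > 0:
                    y = y * np.exp(rng.normal(0.0, config.melt_noise_sd, size=n))
                miss = rng.random(n) < config.missing_rate
                rows.append(
                    pd.DataFrame(
                        {
                            "protein_id": ids,
                            "strain": strain,
                            "replicate": rep,
                            "temp_c": temp,
                            "abundance": np.where(miss, np.nan, y),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)


def simulate_nterm(
    config: SimConfig, genotypes: Sequence[str] = ("WT", "naa10d")
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Simulate N-terminal peptide observations for two genotypes.

    Protein sequences start with the initiator Met followed by a position-2
    residue drawn so that NAT substrate classes occur at configurable
    proportions. Proteins whose position-2 residue lies in
    :data:`NME_POS2_RESIDUES` are emitted initiator-Met-cleaved (start
    position 2), others Met-retained (start position 1). Acetylation is
    Bernoulli with per-class probabilities that differ between genotypes
    only for NatA substrates (abolished in the NatA-null genotype).

    Returns ``(records, truth, sequences)`` where ``sequences`` maps protein
    id to its (synthetic) sequence for FASTA-based validation.
    """
    if len(genotypes) != 2:
        raise ConfigError("exactly two genotypes expected (reference first)")
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_proteins
    ids = _protein_ids(n)
    classes = list(config.nat_class_fractions)
    probs = np.array([config.nat_class_fractions[c] for c in classes])
    cls = rng.choice(classes, size=n, p=probs)

    seqs: dict[str, str] = {}
    start_pos = np.empty(n, dtype=int)
    for i, pid in enumerate(ids):
        pos2 = _CLASS_POS2[cls[i]][rng.integers(len(_CLASS_POS2[cls[i]]))]
        tail = "".join(
            _AMINO_ACIDS[j] for j in rng.integers(0, len(_AMINO_ACIDS), size=12)
        )
        seqs[pid] = "M" + pos2 + tail
        start_pos[i] = 2 if pos2 in NME_POS2_RESIDUES else 1

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "sequence": [seqs[p] for p in ids],
            "start_pos": start_pos,
            "nat_class_true": cls,
        }
    )

    rows = []
    for gi, genotype in enumerate(genotypes):
        for rep in range(1, config.n_replicates + 1):
            observed = rng.random(n) >= config.missing_rate
            acet_p = np.array([config.acetyl_probs[c][gi] for c in cls])
            acet = rng.random(n) < acet_p
            for i in np.flatnonzero(observed):
                pid = ids[i]
                pep = seqs[pid][start_pos[i] - 1 : start_pos[i] - 1 + 10]
                rows.append(
                    (pid, genotype, rep, int(start_pos[i]), pep, bool(acet[i]))
                )
    records = pd.DataFrame(
        rows,
        columns=["protein_id", "genotype", "replicate", "start_pos", "peptide_seq", "acetylated"],
    )
    return records, truth, seqs


def simulate_quant_matrix(
    config: SimConfig,
    n_replicates: int | None = None,
    groups: Sequence[str] = ("WT", "KO"),
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Simulate a log2 intensity matrix with left-censored missingness.

    Missingness probability decreases with the true intensity via a logistic
    ramp whose location is set so the overall missing fraction is close to
    ``config.missing_rate``. Injected ``log2fc`` effects shift the second
    group. Returns ``(matrix, group_map, truth)`` where ``matrix`` is
    features x samples with NaN for missing and ``group_map`` maps sample
    column to group label.
    """
    if len(groups) < 2:
        raise ConfigError("at least 2 groups required")
    reps = n_replicates if n_replicates is not None else max(config.n_replicates, 2)
    if reps < 2:
        raise ConfigError("at least 2 replicates per group required")
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_proteins
    ids = _protein_ids(n)
    effects = _effect_labels(config)
    mu = rng.normal(config.quant_log2_mean, config.quant_log2_sd, size=n)

    shift = np.zeros(n)
    for name, eff in config.effect_spec.items():
        shift[effects == name] = eff.log2fc

    cols: dict[str, np.ndarray] = {}
    group_map: dict[str, str] = {}
    for gi, g in enumerate(groups):
        for rep in range(1, reps + 1):
            col = f"{g}_{rep}"
            group_map[col] = g
            true = mu + (shift if gi > 0 else 0.0)
            vals = true + rng.normal(0.0, config.quant_noise_sd, size=n)
            if config.missing_rate > 0:
                # logistic left-censoring centred at the missing_rate quantile
                c = np.quantile(true, config.missing_rate)
                p_miss = 1.0 / (1.0 + np.exp((vals - c) / 0.7))
                vals = np.where(rng.random(n) < p_miss, np.nan, vals)
            cols[col] = vals
    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    truth = pd.DataFrame(
        {"protein_id": ids, "mu_log2": mu, "log2fc_true": shift, "effect": effects}
    ).set_index("protein_id")
    return matrix, group_map, truth


def write_dataset(outdir: str | Path, config: SimConfig, kind: str = "psilac") -> dict:
    """Generate one dataset and write tidy TSVs plus a JSON run manifest.

    ``kind`` is one of ``psilac``, ``meltome``, ``nterm``, ``quant``.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    if kind == "psilac":
        data, truth = simulate_psilac(config)
        data.to_csv(outdir / "psilac.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "psilac_truth.tsv", sep="\t", index=False)
        files = {"data": "psilac.tsv", "truth": "psilac_truth.tsv"}
    elif kind == "meltome":
        data, truth = simulate_meltome(config)
        data.to_csv(outdir / "meltome.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "meltome_truth.tsv", sep="\t", index=False)
        files = {"data": "meltome.tsv", "truth": "meltome_truth.tsv"}
    elif kind == "nterm":
        records, truth, seqs = simulate_nterm(config)
        records.to_csv(outdir / "nterm.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "nterm_truth.tsv", sep="\t", index=False)
        with open(outdir / "proteins.fasta", "w") as fh:
            for pid, seq in seqs.items():
                fh.write(f">sp|{pid}|{pid}_SYNTH\n{seq}\n")
        files = {"data": "nterm.tsv", "truth": "nterm_truth.tsv", "fasta": "proteins.fasta"}
    elif kind == "quant":
        matrix, group_map, truth = simulate_quant_matrix(config)
        matrix.to_csv(outdir / "quant_matrix.tsv", sep="\t")
        truth.to_csv(outdir / "quant_truth.tsv", sep="\t")
        pd.Series(group_map, name="group").rename_axis("sample").to_csv(
            outdir / "design.tsv", sep="\t"
        )
        files = {"data": "quant_matrix.tsv", "truth": "quant_truth.tsv", "design": "design.tsv"}
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    manifest = {"kind": kind, "seed": config.seed, "config": config.to_dict(), "files": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
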