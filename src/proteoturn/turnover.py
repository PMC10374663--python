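"""Pulsed-SILAC protein turnover: RIA, decay fits, dilution correction.

During a pulsed-SILAC chase the pre-existing (heavy-labelled) pool of a
protein decays with first-order kinetics at the total loss rate
``k = kdeg + kdil``: intracellular degradation plus dilution by cell growth.
The heavy fraction RIA(t) = H/(H+L) then follows ``A * exp(-k t)``, so
ln RIA is linear in time and ordinary least squares on (t, ln RIA) yields
``k`` as the negative slope and the half-life as ``ln(2)/|k|``.

The strain growth rate (dilution constant ``Kdil``) is estimated from the
decay of the proteome-median RIA: the median protein is dominated by
dilution, and the median is robust to fast-degrading outliers. Replicate
Kdil estimates are cleaned with a MAD outlier rule and averaged. Turnover
is then growth-normalized as ``theta = Kdeg / Kdil`` with
``Kdeg = max(k - Kdil, 0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from proteoturn.meltome import mad_filter

__all__ = [
    "TurnoverFit",
    "GrowthEstimate",
    "FitError",
    "compute_ria",
    "filter_psilac",
    "fit_decay",
    "fit_decay_table",
    "combine_replicates",
    "estimate_kdil",
    "normalize_turnover",
    "model_halflife_shift",
    "compare_turnover",
]

LN2 = math.log(2.0)


class FitError(ValueError):
    """Raised when a decay regression cannot be performed."""


@dataclass(frozen=True)
class TurnoverFit:
    """Result of one log-linear label-loss fit."""

    protein_id: str
    strain: str
    k: float  # total loss rate per hour, |slope|
    intercept_lnA: float
    half_life_h: float  # ln(2)/k, +inf when k == 0
    r_squared: float
    n_points_used: int
    passed_qc: bool
    replicate: int | None = None


@dataclass(frozen=True)
class GrowthEstimate:
    """Per-strain dilution constant from the median-RIA procedure."""

    strain: str
    kdil: float
    tdil_h: float
    per_replicate_kdil: tuple[float, ...] = field(default_factory=tuple)
    outlier_mask: tuple[bool, ...] = field(default_factory=tuple)


def compute_ria(hl_ratio=None, intensity_h=None, intensity_l=None):
    """Relative isotope abundance: heavy fraction of the total signal.

    From a heavy/light ratio ``r``: ``RIA = r / (1 + r)``. From the (H, L)
    intensity pair: ``RIA = H / (H + L)``, identical where both are defined
    but well-behaved at L = 0 (pre-chase boundary, RIA = 1).
    Accepts scalars or arrays.
    """
    if hl_ratio is not None:
        r = np.asarray(hl_ratio, dtype=float)
        if np.any(r[np.isfinite(r)] < 0):
            raise ValueError("H/L ratio must be non-negative")
        out = r / (1.0 + r)
        return float(out) if np.isscalar(hl_ratio) else out
    if intensity_h is None or intensity_l is None:
        raise ValueError("provide hl_ratio or both intensity_h and intensity_l")
    h = np.asarray(intensity_h, dtype=float)
    light = np.asarray(intensity_l, dtype=float)
    total = h + light
    if np.any(total[np.isfinite(total)] <= 0):
        raise ValueError("H + L must be positive")
    out = h / total
    return float(out) if np.isscalar(intensity_h) else out


def filter_psilac(
    data: pd.DataFrame, min_peptides: int = 2, min_timepoints: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard poorly supported series before fitting.

    A series (protein x strain x replicate) is kept when it has at least
    ``min_peptides`` unique peptides and at least ``min_timepoints``
    timepoints with a non-missing RIA. Returns ``(kept, rejection_log)``
    where the log has one row per rejected series with the reason.
    """
    key = ["protein_id", "strain", "replicate"]
    g = data.groupby(key, sort=False)
    summary = g.agg(
        n_unique_peptides=("n_unique_peptides", "max"),
        n_timepoints=("ria", lambda s: int(s.notna().sum())),
    ).reset_index()
    too_few_pep = summary["n_unique_peptides"] < min_peptides
    too_few_tp = summary["n_timepoints"] < min_timepoints
    reasons = np.where(
        too_few_pep & too_few_tp,
        "unique_peptides_and_timepoints",
        np.where(too_few_pep, "unique_peptides", np.where(too_few_tp, "timepoints", "")),
    )
    summary["reason"] = reasons
    rejected = summary[summary["reason"] != ""]
    keep_keys = summary.loc[summary["reason"] == "", key]
    kept = data.merge(keep_keys, on=key, how="inner")
    return kept, rejected[key + ["n_unique_peptides", "n_timepoints", "reason"]]


def fit_decay(
    times_h,
    ria,
    max_time_h: float = 6.0,
    r2_min: float = 0.8,
    protein_id: str = "",
    strain: str = "",
    replicate: int | None = None,
) -> TurnoverFit:
    """Fit ln(RIA) = -k t + ln A by ordinary least squares.

    Uses points with 0 < t <= ``max_time_h`` and RIA > 0 (t = 0 carries no
    information: RIA is 1 by construction). ``k`` is the absolute slope;
    half-life is ``ln(2)/k``. ``passed_qc`` is False for non-negative slopes
    (label gain) or r-squared below ``r2_min``.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(ria, dtype=float)
    mask = np.isfinite(t) & np.isfinite(y) & (y > 0) & (t > 0) & (t <= max_time_h)
    if mask.sum() < 2:
        raise FitError(
            f"fewer than 2 usable points for {protein_id or 'series'} "
            f"(RIA > 0, 0 < t <= {max_time_h})"
        )
    tt, ly = t[mask], np.log(y[mask])
    tbar, ybar = tt.mean(), ly.mean()
    sxx = np.sum((tt - tbar) ** 2)
    slope = float(np.sum((tt - tbar) * (ly - ybar)) / sxx)
    intercept = float(ybar - slope * tbar)
    resid = ly - (slope * tt + intercept)
    ss_tot = float(np.sum((ly - ybar) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    k = abs(slope)
    half_life = LN2 / k if k > 0 else math.inf
    return TurnoverFit(
        protein_id=protein_id,
        strain=strain,
        replicate=replicate,
        k=k,
        intercept_lnA=intercept,
        half_life_h=half_life,
        r_squared=r2,
        n_points_used=int(mask.sum()),
        passed_qc=(slope < 0) and (r2 >= r2_min),
    )


def fit_decay_table(
    data: pd.DataFrame, max_time_h: float = 6.0, r2_min: float = 0.8
) -> pd.DataFrame:
    """Fit every (protein, strain, replicate) series in a tidy table.

    Series that cannot be fit (fewer than 2 usable points) are dropped with
    a ``fit_error`` entry instead of a row. Returns one row per fit.
    """
    rows = []
    for (pid, strain, rep), sub in data.groupby(
        ["protein_id", "strain", "replicate"], sort=False
    ):
        try:
            fit = fit_decay(
                sub["time_h"], sub["ria"], max_time_h, r2_min, pid, strain, rep
            )
        except FitError:
            continue
        rows.append(
            {
                "protein_id": pid,
                "strain": strain,
                "replicate": rep,
                "k": fit.k,
                "intercept_lnA": fit.intercept_lnA,
                "half_life_h": fit.half_life_h,
                "r_squared": fit.r_squared,
                "n_points_used": fit.n_points_used,
                "passed_qc": fit.passed_qc,
            }
        )
    return pd.DataFrame(rows)


def combine_replicates(fits: pd.DataFrame, require_qc: bool = True) -> pd.DataFrame:
    """Average k across replicates (QC-passing by default) per protein/strain."""
    sub = fits[fits["passed_qc"]] if require_qc else fits
    out = (
        sub.groupby(["protein_id", "strain"], sort=False)
        .agg(k=("k", "mean"), n_replicates=("k", "size"), r_squared=("r_squared", "mean"))
        .reset_index()
    )
    out["half_life_h"] = np.where(out["k"] > 0, LN2 / out["k"], np.inf)
    return out


def estimate_kdil(
    data: pd.DataFrame, max_time_h: float = 6.0, k_mad: float = 1.0
) -> dict[str, GrowthEstimate]:
    """Estimate strain dilution constants from the median-RIA decay.

    Per strain and replicate, the median RIA across proteins is taken at
    each timepoint and ln(median RIA) is regressed on time (t <= 6 h);
    the replicate Kdil is the absolute slope. Replicates outside the MAD
    range relative to the median are deemed outliers and excluded; the
    strain Kdil is the mean of the survivors and the doubling time
    ``Tdil = ln(2)/Kdil``.
    """
    out: dict[str, GrowthEstimate] = {}
    for strain, sub in data.groupby("strain", sort=False):
        rep_kdils: list[float] = []
        for rep, rsub in sub.groupby("replicate", sort=False):
            med = rsub.groupby("time_h")["ria"].median().dropna()
            med = med[(med.index > 0) & (med.index <= max_time_h) & (med > 0)]
            if len(med) < 2:
                raise FitError(
                    f"strain {strain!r} replicate {rep!r}: fewer than 2 usable timepoints"
                )
            fit = fit_decay(med.index.to_numpy(), med.to_numpy(), max_time_h)
            rep_kdils.append(fit.k)
        kdils = np.asarray(rep_kdils)
        outliers = mad_filter(kdils, k_mad=k_mad) if len(kdils) > 1 else np.zeros(
            len(kdils), dtype=bool
        )
        kdil = float(kdils[~outliers].mean())
        out[strain] = GrowthEstimate(
            strain=strain,
            kdil=kdil,
            tdil_h=LN2 / kdil,
            per_replicate_kdil=tuple(float(x) for x in kdils),
            outlier_mask=tuple(bool(x) for x in outliers),
        )
    return out


def normalize_turnover(
    fits: pd.DataFrame, growth: dict[str, GrowthEstimate], mode: str = "subtract"
) -> pd.DataFrame:
    """Growth-normalize total loss rates.

    ``mode='subtract'`` (default): ``kdeg = max(k - kdil, 0)`` and
    ``theta = kdeg / kdil`` — the two-compartment reading where the fitted
    slope is degradation plus dilution. ``mode='divide'`` keeps the raw
    slope and reports ``theta = k / kdil``.
    """
    if mode not in ("subtract", "divide"):
        raise ValueError("mode must be 'subtract' or 'divide'")
    out = fits.copy()
    kdil = out["strain"].map(
        {s: g.kdil for s, g in growth.items()}
    ).astype(float)
    if kdil.isna().any():
        missing = sorted(out.loc[kdil.isna(), "strain"].unique())
        raise ValueError(f"no growth estimate for strain(s) {missing}")
    if (kdil <= 0).any():
        raise ValueError("kdil must be positive")
    if mode == "subtract":
        out["kdeg"] = np.maximum(out["k"] - kdil, 0.0)
    else:
        out["kdeg"] = out["k"]
    out["kdil"] = kdil
    out["theta"] = out["kdeg"] / kdil
    return out


def model_halflife_shift(t_half_wt_h, kdil_wt: float, kdil_alt: float):
    """Predict a WT half-life under an altered dilution constant.

    In the two-compartment model the total loss rate splits as
    ``k = kdeg + kdil``, so ``kdeg = max(ln2/t_half - kdil_wt, 0)`` and the
    predicted half-life under ``kdil_alt`` is ``ln2 / (kdeg + kdil_alt)``.
    Long-lived proteins (kdeg << kdil) track the dilution change while
    short-lived proteins are essentially unaffected. Accepts scalars or
    arrays of WT half-lives.
    """
    t = np.asarray(t_half_wt_h, dtype=float)
    if np.any(t <= 0) or kdil_wt <= 0 or kdil_alt <= 0:
        raise ValueError("half-lives and dilution constants must be positive")
    kdeg = np.maximum(LN2 / t - kdil_wt, 0.0)
    out = LN2 / (kdeg + kdil_alt)
    return float(out) if np.isscalar(t_half_wt_h) else out


def compare_turnover(
    thetas_wt: pd.DataFrame,
    thetas_ko: pd.DataFrame,
    s0: float = 0.1,
    n_rand: int = 250,
    seed: int = 0,
    tiers: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Differential turnover between strains (KO minus WT).

    Inputs are proteins x replicates tables of normalized turnover
    (``theta``); rows are aligned on the shared protein index. Delegates to
    the s0-moderated permutation-FDR machinery and classifies significant
    proteins as ``fast`` (higher turnover in KO) or ``slow`` by the sign of
    the difference.
    """
    from proteoturn import stats

    diff = stats.differential_from_replicates(
        thetas_wt, thetas_ko, s0=s0, n_rand=n_rand, seed=seed, tiers=tiers
    )
    return stats.volcano_table(diff, labels=("slow", "fast"))
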