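"""Thermal proteome profiling: melting-curve fits, consensus Tm, ITSA.

Soluble-fraction abundance across a temperature gradient is summarized with
a four-parameter log-logistic model

    f(T) = d + (a - d) / (1 + (T / T50)**b)

with upper plateau ``a`` (abundance at the lowest temperature), lower
plateau ``d``, inflection slope ``b`` and midpoint ``T50``; the melting
temperature Tm is the T50, the temperature at which half of the protein is
unfolded, since f(T50) = (a + d) / 2 identically. Fits use at least eight
data points. Replicate T50 values are cleaned with a MAD rule before the
consensus median.

The isothermal shift assay (ITSA) compares soluble and precipitated
fractions at a handful of temperatures against the lowest-temperature
reference (25 degC), turning thermal stability into simple log2
fold-changes amenable to the volcano statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MeltFit",
    "MeltFitError",
    "fourpl",
    "scale_to_reference",
    "fit_melting_curve",
    "fit_meltome_table",
    "mad_filter",
    "protein_tm",
    "tm_consensus_table",
    "compare_tm",
    "itsa_contrast",
    "itsa_volcano",
]

# fit bounds on reference-scaled abundances
_BOUNDS_LO = (0.3, 0.0, 1e-6, None)  # a, d, b, t50
_BOUNDS_HI = (1.5, 0.8, 500.0, None)
_B_STARTS = (10.0, 35.0, 80.0)


class MeltFitError(ValueError):
    """Raised when a melting curve cannot be fit (e.g. too few points)."""


@dataclass(frozen=True)
class MeltFit:
    """Four-parameter log-logistic fit of one melting curve."""

    protein_id: str
    a: float  # upper plateau (abundance at minimum T)
    d: float  # lower plateau (abundance at maximum T)
    b: float  # slope at the inflection point
    t50_c: float  # mid-range temperature
    converged: bool
    rss: float
    n_points: int
    strain: str = ""
    replicate: int | None = None

    @property
    def tm_c(self) -> float:
        """Melting temperature: T at which half the protein is unfolded."""
        return self.t50_c


def fourpl(temp_c, a: float, d: float, b: float, t50_c: float):
    """Evaluate the four-parameter log-logistic melting model.

    ``f(T) = d + (a - d) / (1 + (T / T50)**b)``; at T = T50 the value is
    exactly ``(a + d) / 2``, and for b > 0 the curve decays from ``a`` at
    low T to ``d`` at high T.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    out = d + (a - d) / (1.0 + (temp_c / t50_c) ** b)
    return float(out) if out.ndim == 0 else out


def scale_to_reference(temps_c, abundances) -> np.ndarray:
    """Scale a curve to its lowest-temperature abundance.

    Divides every abundance by the value at the lowest temperature with a
    non-missing measurement, so the first point becomes 1 and the rest are
    fold-changes. Stand-in for a full variance-stabilizing normalization;
    plug externally normalized intensities in directly if preferred.
    """
    t = np.asarray(temps_c, dtype=float)
    y = np.asarray(abundances, dtype=float)
    order = np.argsort(t)
    ref = np.nan
    for i in order:
        if np.isfinite(y[i]):
            ref = y[i]
            break
    if not np.isfinite(ref) or ref <= 0:
        raise MeltFitError("reference (lowest-temperature) abundance missing or zero")
    return y / ref


def fit_melting_curve(
    temps_c,
    abundances,
    min_points: int = 8,
    protein_id: str = "",
    strain: str = "",
    replicate: int | None = None,
    scaled: bool = True,
) -> MeltFit:
    """Nonlinear least-squares fit of the 4PL melting model.

    Requires at least ``min_points`` non-missing points. With
    ``scaled=True`` (default) abundances are first divided by the
    lowest-temperature value. Initialization is multi-start: T50 starts at
    the temperature nearest the half-range crossing and +-3 degC around it,
    b starts at {10, 35, 80}; the best residual sum of squares wins.
    Plateaus are bounded (a in [0.3, 1.5], d in [0, 0.8] on the scaled
    axis) and T50 is constrained to the sampled range +-5 degC.
    """
    t = np.asarray(temps_c, dtype=float)
    y = np.asarray(abundances, dtype=float)
    mask = np.isfinite(t) & np.isfinite(y)
    t, y = t[mask], y[mask]
    if t.size < min_points:
        raise MeltFitError(
            f"insufficient points for {protein_id or 'curve'}: "
            f"{t.size} < {min_points}"
        )
    order = np.argsort(t)
    t, y = t[order], y[order]
    if scaled:
        y = scale_to_reference(t, y)

    lo = (_BOUNDS_LO[0], _BOUNDS_LO[1], _BOUNDS_LO[2], t.min() - 5.0)
    hi = (_BOUNDS_HI[0], _BOUNDS_HI[1], _BOUNDS_HI[2], t.max() + 5.0)

    a0 = float(np.clip(y[0], lo[0] + 1e-9, hi[0] - 1e-9))
    d0 = float(np.clip(y[-1], lo[1] + 1e-9, hi[1] - 1e-9))
    half = (y.max() + y.min()) / 2.0
    t50_guess = float(t[np.argmin(np.abs(y - half))])

    def residuals(p):
        a, d, b, t50 = p
        return fourpl(t, a, d, b, t50) - y

    best = None
    for dt in (0.0, -3.0, 3.0):
        t50_0 = float(np.clip(t50_guess + dt, lo[3] + 1e-9, hi[3] - 1e-9))
        for b0 in _B_STARTS:
            try:
                res = least_squares(
                    residuals,
                    x0=(a0, d0, b0, t50_0),
                    bounds=(lo, hi),
                    xtol=1e-8,
                    ftol=1e-8,
                    gtol=1e-8,
                    max_nfev=1000,
                )
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        return MeltFit(
            protein_id, math.nan, math.nan, math.nan, math.nan,
            converged=False, rss=math.nan, n_points=int(t.size),
            strain=strain, replicate=replicate,
        )
    rss, res = best
    a, d, b, t50 = (float(v) for v in res.x)
    return MeltFit(
        protein_id=protein_id, a=a, d=d, b=b, t50_c=t50,
        converged=bool(res.success), rss=rss, n_points=int(t.size),
        strain=strain, replicate=replicate,
    )


def fit_meltome_table(
    data: pd.DataFrame, min_points: int = 8, scaled: bool = True
) -> pd.DataFrame:
    """Fit every (protein, strain, replicate) curve in a tidy table.

    Curves with fewer than ``min_points`` valid points are recorded with
    ``rejected=True`` and the reason instead of parameters.
    """
    rows = []
    for (pid, strain, rep), sub in data.groupby(
        ["protein_id", "strain", "replicate"], sort=False
    ):
        base = {"protein_id": pid, "strain": strain, "replicate": rep}
        try:
            fit = fit_melting_curve(
                sub["temp_c"], sub["abundance"], min_points, pid, strain, rep,
                scaled=scaled,
            )
        except MeltFitError as exc:
            rows.append({**base, "rejected": True, "reason": str(exc)})
            continue
        rows.append(
            {
                **base,
                "a": fit.a, "d": fit.d, "b": fit.b, "t50_c": fit.t50_c,
                "tm_c": fit.tm_c, "converged": fit.converged,
                "rss": fit.rss, "n_points": fit.n_points,
                "rejected": False, "reason": "",
            }
        )
    return pd.DataFrame(rows)


def mad_filter(values, k_mad: float = 1.0) -> np.ndarray:
    """Flag values outside the MAD range relative to the median.

    Returns a boolean mask (True = outlier) for ``|x - median| >
    k_mad * MAD`` where MAD is the median absolute deviation. When the MAD
    is zero (ties), any value different from the median is flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_filter requires at least one value")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) > k_mad * mad


def protein_tm(t50_values, k_mad: float = 1.0) -> tuple[float, np.ndarray]:
    """Consensus melting temperature across replicate fits.

    MAD-filters the replicate T50 values and returns the median of the
    survivors together with the outlier mask (provenance).
    """
    x = np.asarray(t50_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no converged T50 values")
    outliers = mad_filter(x, k_mad=k_mad) if x.size > 1 else np.zeros(x.size, bool)
    return float(np.median(x[~outliers])), outliers


def tm_consensus_table(fits: pd.DataFrame, k_mad: float = 1.0) -> pd.DataFrame:
    """Per protein/strain consensus Tm from a fit table (converged fits only)."""
    rows = []
    ok = fits[~fits.get("rejected", False) & fits["converged"]]
    for (pid, strain), sub in ok.groupby(["protein_id", "strain"], sort=False):
        tm, outliers = protein_tm(sub["t50_c"].to_numpy(), k_mad=k_mad)
        rows.append(
            {
                "protein_id": pid,
                "strain": strain,
                "tm_c": tm,
                "n_replicates": len(sub),
                "n_outliers": int(outliers.sum()),
            }
        )
    return pd.DataFrame(rows)


def compare_tm(
    tms_wt: pd.DataFrame,
    tms_ko: pd.DataFrame,
    s0: float = 0.1,
    n_rand: int = 250,
    seed: int = 0,
    tiers: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Differential melting temperature, KO minus WT.

    Inputs are proteins x replicates tables of per-replicate T50 values.
    Negative differences mean destabilization in the KO. Delegates to the
    s0-moderated permutation-FDR machinery.
    """
    from proteoturn import stats

    diff = stats.differential_from_replicates(
        tms_wt, tms_ko, s0=s0, n_rand=n_rand, seed=seed, tiers=tiers
    )
    return stats.volcano_table(diff, labels=("destabilized", "stabilized"))


def itsa_contrast(data: pd.DataFrame, ref_temp_c: float = 25.0) -> pd.DataFrame:
    """Isothermal shift contrasts against the low-temperature reference.

    ``data`` is tidy with columns protein_id, strain, replicate, fraction
    (soluble|precipitate), temp_c, abundance. For every series the log2
    fold-change of each temperature against the ``ref_temp_c`` abundance is
    returned; the reference rows are dropped from the output.
    """
    temps = set(data["temp_c"].unique())
    if ref_temp_c not in temps:
        raise ValueError(f"reference temperature {ref_temp_c} missing from data")
    key = ["protein_id", "strain", "replicate", "fraction"]
    ref = (
        data[data["temp_c"] == ref_temp_c]
        .set_index(key)["abundance"]
        .rename("ref_abundance")
    )
    out = data[data["temp_c"] != ref_temp_c].join(ref, on=key)
    if out["ref_abundance"].isna().any():
        missing = out.loc[out["ref_abundance"].isna(), "protein_id"].unique()
        raise ValueError(f"reference abundance missing for {sorted(missing)[:5]}")
    out = out.copy()
    out["log2fc"] = np.log2(out["abundance"] / out["ref_abundance"])
    return out[key + ["temp_c", "log2fc"]]


def itsa_volcano(
    contrasts: pd.DataFrame,
    wt: str = "WT",
    s0: float = 0.1,
    n_rand: int = 250,
    seed: int = 0,
    tiers: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Volcano statistics per (fraction, temperature) on ITSA contrasts.

    Compares KO vs WT log2 fold-changes per protein at each temperature and
    fraction using the s0 permutation-FDR machinery; results are stacked
    with fraction/temp_c columns.
    """
    from proteoturn import stats

    strains = sorted(contrasts["strain"].unique())
    if wt not in strains or len(strains) != 2:
        raise ValueError("expected exactly two strains including the reference")
    ko = next(s for s in strains if s != wt)
    out = []
    for (fraction, temp), sub in contrasts.groupby(["fraction", "temp_c"], sort=False):
        wide = sub.pivot_table(
            index="protein_id", columns=["strain", "replicate"], values="log2fc"
        )
        diff = stats.differential_from_replicates(
            wide[wt], wide[ko], s0=s0, n_rand=n_rand, seed=seed, tiers=tiers
        )
        diff = stats.volcano_table(diff, labels=("destabilized", "stabilized"))
        diff.insert(0, "fraction", fraction)
        diff.insert(1, "temp_c", temp)
        out.append(diff)
    return pd.concat(out, ignore_index=True)
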