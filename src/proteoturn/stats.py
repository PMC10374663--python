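"""Differential-analysis core: s0 t-statistic, permutation FDR, BH.

The moderated statistic follows the SAM/Perseus convention: a two-sample
pooled-variance t-statistic whose denominator is inflated by a constant
``s0`` (in the units of the analysis scale), de-emphasizing features whose
tiny variance would otherwise produce huge t-values at negligible effect
sizes:

    d_i = (mean_b - mean_a) / (se_pooled_i + s0)

Significance is assigned by comparing observed |d| against a pooled null
from label permutations: for a cutoff c the estimated FDR is the mean
number of null |d| values >= c per permutation divided by the number of
observed |d| >= c, and a feature's q-value is the best (smallest) FDR over
cutoffs it passes. Tier membership at 1% / 5% FDR is the contract; the
geometry of any particular volcano-curve drawing is not reproduced.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "s0_tstat",
    "permutation_fdr",
    "differential_from_replicates",
    "bh_adjust",
    "volcano_table",
]


def s0_tstat(group_a, group_b, s0: float = 0.1) -> tuple[float, float]:
    """s0-moderated two-sample statistic and the group difference.

    Returns ``(stat, difference)`` with ``difference = mean(b) - mean(a)``
    and ``stat = difference / (se_pooled + s0)`` using the pooled-variance
    (Student, not Welch) standard error. With ``s0 = 0`` this is exactly the
    classic two-sample t statistic. Groups with fewer than 2 finite values
    give ``(nan, nan)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return math.nan, math.nan
    na, nb = a.size, b.size
    diff = float(b.mean() - a.mean())
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return diff / (se + s0), diff


def _moderated_stats(matrix: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float):
    """Vectorized s0 statistic per row; rows with <2 valid per group -> NaN."""
    a = matrix[:, idx_a]
    b = matrix[:, idx_b]
    na = np.sum(np.isfinite(a), axis=1)
    nb = np.sum(np.isfinite(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    valid = (na >= 2) & (nb >= 2)
    diff = mb - ma
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    stat = np.where(valid, diff / (se + s0), np.nan)
    diff = np.where(valid, diff, np.nan)
    return stat, diff, ma, mb


def _distinct_splits(
    n: int, idx_a_obs: tuple[int, ...], n_rand: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Distinct label arrangements (as sorted index tuples for group A).

    The observed arrangement is excluded from the null. When group sizes
    are equal, a split and its complement give the same |d| and are
    deduplicated. If fewer distinct arrangements exist than requested, all
    of them are used (with a warning).
    """
    na = len(idx_a_obs)
    total = math.comb(n, na)
    balanced = 2 * na == n

    def canonical(comb: tuple[int, ...]) -> tuple[int, ...]:
        if balanced:
            comp = tuple(i for i in range(n) if i not in comb)
            return min(comb, comp)
        return comb

    obs = canonical(tuple(sorted(idx_a_obs)))
    n_distinct = (total // 2 if balanced else total) - 1
    if n_distinct <= n_rand:
        if n_distinct < n_rand:
            warnings.warn(
                f"only {n_distinct} distinct label arrangements available; "
                f"using all of them instead of {n_rand}",
                stacklevel=3,
            )
        splits = {
            canonical(c) for c in itertools.combinations(range(n), na)
        }
        splits.discard(obs)
        return sorted(splits)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < n_rand:
        perm = rng.permutation(n)
        cand = canonical(tuple(sorted(int(i) for i in perm[:na])))
        if cand != obs:
            chosen.add(cand)
    return sorted(chosen)


def permutation_fdr(
    matrix: pd.DataFrame,
    labels,
    s0: float = 0.1,
    n_rand: int = 250,
    seed: int = 0,
    tiers: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """s0-moderated two-group test with SAM-style permutation FDR.

    Parameters
    ----------
    matrix
        Features x samples table (NaN = missing).
    labels
        Group label per column; exactly two groups. The difference is
        mean(second group) - mean(first group), groups ordered by first
        appearance.
    s0, n_rand, seed, tiers
        Moderation constant, number of label randomizations, RNG seed and
        the (strict, loose) FDR tier thresholds.

    Returns a table with columns feature_id, mean_a, mean_b, difference,
    s0_stat, p_classic (two-sided Student t), q_perm and tier
    (``fdr01``/``fdr05``/``ns`` for default tiers).
    """
    labels = list(labels)
    if len(labels) != len(matrix.columns):
        raise ValueError("one label per column required")
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ga, gb = groups
    idx_a = np.array([i for i, l in enumerate(labels) if l == ga])
    idx_b = np.array([i for i, l in enumerate(labels) if l == gb])
    x = matrix.to_numpy(dtype=float)
    stat, diff, ma, mb = _moderated_stats(x, idx_a, idx_b, s0)

    # classic two-sided Student t p-values for reporting
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_res = sps.ttest_ind(
            x[:, idx_b], x[:, idx_a], axis=1, nan_policy="omit", equal_var=True
        )
    p_classic = np.asarray(t_res.pvalue, dtype=float)

    rng = np.random.default_rng(seed)
    n = len(labels)
    splits = _distinct_splits(n, tuple(idx_a), n_rand, rng)
    null_abs: list[np.ndarray] = []
    for comb in splits:
        pa = np.array(comb)
        pb = np.array([i for i in range(n) if i not in comb])
        ns, _, _, _ = _moderated_stats(x, pa, pb, s0)
        null_abs.append(np.abs(ns[np.isfinite(ns)]))
    n_perm = len(splits)

    obs_abs = np.abs(stat)
    valid = np.isfinite(obs_abs)
    q = np.full(matrix.shape[0], np.nan)
    if valid.any() and n_perm > 0:
        cutoffs = np.unique(obs_abs[valid])  # ascending
        obs_sorted = np.sort(obs_abs[valid])
        null_all = np.concatenate(null_abs) if null_abs else np.array([])
        null_sorted = np.sort(null_all)
        # counts of observed/null |d| >= each cutoff
        n_obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, cutoffs, side="left")
        n_null_ge = null_sorted.size - np.searchsorted(null_sorted, cutoffs, side="left")
        fdr_at = np.minimum(1.0, (n_null_ge / n_perm) / n_obs_ge)
        # q at cutoff c = min FDR over cutoffs <= c (prefix minimum, ascending)
        prefix_min = np.minimum.accumulate(fdr_at)
        pos = np.searchsorted(cutoffs, obs_abs[valid])
        q[valid] = prefix_min[pos]

    strict, loose = sorted(tiers)
    tier = np.where(
        q <= strict, "fdr01", np.where(q <= loose, "fdr05", "ns")
    )
    tier = np.where(np.isnan(q), "ns", tier)
    return pd.DataFrame(
        {
            "feature_id": matrix.index,
            "mean_a": ma,
            "mean_b": mb,
            "difference": diff,
            "s0_stat": stat,
            "p_classic": p_classic,
            "q_perm": q,
            "tier": tier,
        }
    ).reset_index(drop=True)


def differential_from_replicates(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    s0: float = 0.1,
    n_rand: int = 250,
    seed: int = 0,
    tiers: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Two-group differential table from per-group replicate matrices.

    ``values_a`` / ``values_b`` are features x replicates with a shared
    feature index (e.g. per-replicate theta or T50 per protein); rows are
    aligned on the index intersection. The difference reported is
    mean(b) - mean(a).
    """
    common = values_a.index.intersection(values_b.index)
    if len(common) == 0:
        raise ValueError("no overlapping features between the two groups")
    a = values_a.loc[common]
    b = values_b.loc[common]
    if isinstance(a, pd.Series):
        a = a.to_frame()
    if isinstance(b, pd.Series):
        b = b.to_frame()
    mat = pd.concat(
        [a.set_axis([f"a{i}" for i in range(a.shape[1])], axis=1),
         b.set_axis([f"b{i}" for i in range(b.shape[1])], axis=1)],
        axis=1,
    )
    labels = ["a"] * a.shape[1] + ["b"] * b.shape[1]
    return permutation_fdr(mat, labels, s0=s0, n_rand=n_rand, seed=seed, tiers=tiers)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NaN pass-through."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def volcano_table(
    differential: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("down", "up"),
    sig_tiers: tuple[str, ...] = ("fdr01", "fdr05"),
) -> pd.DataFrame:
    """Classify significant features by the sign of their difference.

    Features in a significant tier get ``labels[1]`` for positive
    differences and ``labels[0]`` for negative ones (e.g. fast/slow
    turnover); non-significant rows are left unlabeled. Optional
    ``annotations`` (indexed by feature_id) are joined in.
    """
    out = differential.copy()
    sig = out["tier"].isin(sig_tiers)
    out["classification"] = ""
    out.loc[sig & (out["difference"] > 0), "classification"] = labels[1]
    out.loc[sig & (out["difference"] < 0), "classification"] = labels[0]
    if annotations is not None:
        out = out.join(annotations, on="feature_id")
    return out
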