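"""Turnover stage: RIA, filters, decay fits, Kdil, normalization, shift model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteoturn import simdata, turnover
from proteoturn.simdata import SimConfig

LN2 = math.log(2)


class TestComputeRia:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.5), (3.0, 0.75), (0.0, 0.0)])
    def test_ratio_form(self, ratio, expected):
        assert turnover.compute_ria(ratio) == pytest.approx(expected)

    def test_intensity_form_handles_zero_light(self):
        assert turnover.compute_ria(intensity_h=5.0, intensity_l=0.0) == 1.0

    def test_forms_agree_where_both_defined(self):
        h, light = 7.0, 3.0
        assert turnover.compute_ria(h / light) == pytest.approx(
            turnover.compute_ria(intensity_h=h, intensity_l=light)
        )

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            turnover.compute_ria(-0.5)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_bounded(self, r):
        v = turnover.compute_ria(r)
        assert 0.0 <= v <= 1.0
        assert turnover.compute_ria(r + 1.0) > v


def _series_df(pid, n_pep, rias, strain="WT", rep=1):
    times = [0.5, 1, 2, 3, 4.5, 6][: len(rias)]
    return pd.DataFrame(
        {
            "protein_id": pid, "strain": strain, "replicate": rep,
            "time_h": times, "ria": rias, "n_unique_peptides": n_pep,
        }
    )


class TestFilterPsilac:
    def test_rejection_rules_and_enumeration(self):
        """5 hand-built series: survivor count matches the hand count."""
        frames = [
            _series_df("A", 1, [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]),  # 1 peptide -> out
            _series_df("B", 3, [0.9, 0.8, 0.7]),                 # 3 timepoints -> out
            _series_df("C", 2, [0.9, 0.8, 0.7, 0.6]),            # kept
            _series_df("D", 5, [0.9, np.nan, np.nan, 0.6, 0.5]), # 3 valid -> out
            _series_df("E", 4, [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]),  # kept
        ]
        kept, log = turnover.filter_psilac(pd.concat(frames, ignore_index=True))
        assert set(kept["protein_id"]) == {"C", "E"}
        reasons = log.set_index("protein_id")["reason"]
        assert reasons["A"] == "unique_peptides"
        assert reasons["B"] == "timepoints"
        assert reasons["D"] == "timepoints"


class TestFitDecay:
    def test_noiseless_exponential_round_trip(self):
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        fit = turnover.fit_decay(t, np.exp(-0.5 * t))
        assert fit.k == pytest.approx(0.5, abs=1e-12)
        assert fit.half_life_h == pytest.approx(LN2 / 0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.passed_qc

    @pytest.mark.parametrize("k", [0.01, 0.1, 0.5, 1.0, 5.0])
    def test_recovers_k_to_1e10_across_range(self, k):
        t = np.array([0.5, 1, 2, 3, 4.5, 6])
        fit = turnover.fit_decay(t, np.exp(-k * t))
        assert fit.k == pytest.approx(k, abs=1e-10)
        assert fit.half_life_h * fit.k == pytest.approx(LN2, abs=1e-12)

    def test_constant_ria_gives_infinite_half_life_and_fails_qc(self):
        fit = turnover.fit_decay([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0])
        assert fit.k == 0.0
        assert math.isinf(fit.half_life_h)
        assert not fit.passed_qc

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(42)
        t = np.array([0.5, 1, 2, 3, 4.5, 6])
        y = np.exp(-0.4 * t + rng.normal(0, 0.1, t.size))
        fit = turnover.fit_decay(t, y)
        ly = np.log(y)
        slope = np.sum((t - t.mean()) * (ly - ly.mean())) / np.sum((t - t.mean()) ** 2)
        assert fit.k == pytest.approx(abs(slope), abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(turnover.FitError):
            turnover.fit_decay([1.0], [0.5])
        with pytest.raises(turnover.FitError):
            turnover.fit_decay([1, 2, 3], [0.0, 0.0, 0.0])

    def test_points_beyond_max_time_excluded(self):
        t = np.array([1, 2, 3, 4, 5, 6, 12.0])
        y = np.exp(-0.3 * t)
        y[-1] = 0.9  # corrupt a late point outside the window
        fit = turnover.fit_decay(t, y, max_time_h=6.0)
        assert fit.n_points_used == 6
        assert fit.k == pytest.approx(0.3, abs=1e-10)


class TestEstimateKdil:
    def test_noiseless_pure_dilution_recovers_printed_doubling_time(
        self, noiseless_config
    ):
        """kdeg=0, kdil=0.3648 -> kdil estimate 0.3648, Tdil 1.9 h."""
        data, _ = simdata.simulate_psilac(noiseless_config)
        g = turnover.estimate_kdil(data)["WT"]
        assert g.kdil == pytest.approx(0.3648, abs=1e-6)
        assert g.tdil_h == pytest.approx(1.9, abs=1e-3)
        assert g.tdil_h * g.kdil == pytest.approx(LN2, abs=1e-12)

    def test_mad_rule_excludes_deviant_replicate(self):
        """Replicate kdils {0.36, 0.37, 0.80}: only 0.80 excluded."""
        frames = []
        t = np.array([0.5, 1, 2, 3, 4.5, 6])
        for rep, k in enumerate([0.36, 0.37, 0.80], start=1):
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": "P1", "strain": "WT", "replicate": rep,
                        "time_h": t, "ria": np.exp(-k * t),
                        "n_unique_peptides": 5,
                    }
                )
            )
        g = turnover.estimate_kdil(pd.concat(frames, ignore_index=True))["WT"]
        assert g.outlier_mask == (False, False, True)
        assert g.kdil == pytest.approx((0.36 + 0.37) / 2, abs=1e-9)

    def test_two_strain_ratio_recovered(self):
        """Generator kdil ratio 0.72 is recovered on degradation-free data."""
        cfg = SimConfig(
            seed=13, n_proteins=200, n_replicates=2, ratio_noise_sd=0.1,
            kdeg_logmean=np.log(1e-12), kdeg_logsd=1e-12,
            kdil_per_strain={"WT": 0.365, "KO": 0.365 * 0.72},
        )
        data, _ = simdata.simulate_psilac(cfg)
        g = turnover.estimate_kdil(data)
        ratio = g["KO"].kdil / g["WT"].kdil
        assert ratio == pytest.approx(0.72, abs=0.02)

    def test_too_few_timepoints_raises(self):
        df = _series_df("A", 3, [0.9])
        with pytest.raises(turnover.FitError):
            turnover.estimate_kdil(df)


class TestNormalizeTurnover:
    def _growth(self, kdil):
        return {"WT": turnover.GrowthEstimate("WT", kdil, LN2 / kdil)}

    def test_pure_dilution_gives_theta_zero(self):
        fits = pd.DataFrame({"protein_id": ["A"], "strain": ["WT"], "k": [0.3]})
        out = turnover.normalize_turnover(fits, self._growth(0.3))
        assert out["theta"].iloc[0] == 0.0

    def test_double_dilution_gives_theta_one(self):
        fits = pd.DataFrame({"protein_id": ["A"], "strain": ["WT"], "k": [0.6]})
        out = turnover.normalize_turnover(fits, self._growth(0.3))
        assert out["theta"].iloc[0] == pytest.approx(1.0)

    def test_k_below_kdil_clipped_at_zero(self):
        fits = pd.DataFrame({"protein_id": ["A"], "strain": ["WT"], "k": [0.1]})
        out = turnover.normalize_turnover(fits, self._growth(0.3))
        assert out["kdeg"].iloc[0] == 0.0

    def test_divide_mode(self):
        fits = pd.DataFrame({"protein_id": ["A"], "strain": ["WT"], "k": [0.6]})
        out = turnover.normalize_turnover(fits, self._growth(0.3), mode="divide")
        assert out["theta"].iloc[0] == pytest.approx(2.0)

    def test_high_kdeg_subset_ranks_above_background(self):
        """Median theta of an injected fast subset exceeds the background."""
        cfg = SimConfig(
            seed=17, n_proteins=120, ratio_noise_sd=0.05,
            kdil_per_strain={"WT": 0.365, "KO": 0.365},
            effect_spec={"fast": simdata.EffectSpec(n_affected=30, kdeg_multiplier=4.0)},
        )
        data, truth = simdata.simulate_psilac(cfg)
        fits = turnover.fit_decay_table(data[data["strain"] == "KO"])
        growth = turnover.estimate_kdil(data[data["strain"] == "KO"])
        norm = turnover.normalize_turnover(combine(fits), growth)
        t = truth[truth["strain"] == "KO"].set_index("protein_id")
        norm = norm.set_index("protein_id").join(t["effect"])
        assert (
            norm.loc[norm["effect"] == "fast", "theta"].median()
            > norm.loc[norm["effect"] == "", "theta"].median()
        )


def combine(fits):
    out = turnover.combine_replicates(fits)
    return out


class TestModelHalflifeShift:
    def test_identity_when_kdil_unchanged(self):
        # t_half within the model-consistent range (t_half <= ln2/kdil)
        assert turnover.model_halflife_shift(1.5, 0.36, 0.36) == pytest.approx(1.5)

    def test_halflife_beyond_dilution_cap_clips_kdeg(self):
        """t_half > ln2/kdil implies negative kdeg; clipped to 0 by design."""
        out = turnover.model_halflife_shift(3.0, 0.36, 0.36)
        assert out == pytest.approx(LN2 / 0.36)

    def test_short_lived_unaffected(self):
        t = 0.05  # kdeg >> kdil
        out = turnover.model_halflife_shift(t, 0.365, 0.26)
        assert out == pytest.approx(t, rel=0.01)

    def test_pure_dilution_closed_form(self):
        """t1/2 = 1.9 h at kdil ln2/1.9 (kdeg=0) under kdil 0.26 -> ln2/0.26."""
        out = turnover.model_halflife_shift(1.9, LN2 / 1.9, 0.26)
        assert out == pytest.approx(LN2 / 0.26, abs=1e-12)
        assert out == pytest.approx(2.666, abs=5e-3)

    @given(
        st.floats(min_value=0.05, max_value=1.85),
        st.floats(min_value=0.05, max_value=1.85),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_halflife_and_lengthening_law(self, t1, t2):
        """Strictly increasing in t_half; kdil_alt < kdil_wt never shortens.

        Sampled within the model-consistent domain t_half <= ln2/kdil_wt
        (~1.9 h here); beyond it kdeg clips to 0 and the curve plateaus.
        """
        kdil_wt, kdil_alt = 0.365, 0.26
        lo, hi = sorted([t1, t2])
        f_lo = turnover.model_halflife_shift(lo, kdil_wt, kdil_alt)
        f_hi = turnover.model_halflife_shift(hi, kdil_wt, kdil_alt)
        if lo < hi:
            assert f_lo < f_hi
        assert f_lo >= lo * (1 - 1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            turnover.model_halflife_shift(-1.0, 0.3, 0.3)
        with pytest.raises(ValueError):
            turnover.model_halflife_shift(1.0, 0.0, 0.3)


class TestCompareTurnover:
    def test_identical_inputs_yield_no_significant(self):
        rng = np.random.default_rng(0)
        theta = pd.DataFrame(
            rng.normal(1.0, 0.2, size=(40, 3)),
            index=[f"P{i}" for i in range(40)],
        )
        out = turnover.compare_turnover(theta, theta.copy(), n_rand=50, seed=1)
        assert (out["tier"] == "ns").all()
        assert (out["classification"] == "").all()

    def test_injected_fast_subset_enriched_in_fast_tier(self):
        rng = np.random.default_rng(5)
        n = 60
        ids = [f"P{i}" for i in range(n)]
        wt = pd.DataFrame(rng.normal(1.0, 0.05, size=(n, 3)), index=ids)
        ko = pd.DataFrame(rng.normal(1.0, 0.05, size=(n, 3)), index=ids)
        fast = ids[:12]
        ko.loc[fast] += 1.0
        out = turnover.compare_turnover(wt, ko, n_rand=100, seed=2).set_index(
            "feature_id"
        )
        called_fast = set(out.index[out["classification"] == "fast"])
        assert set(fast) <= called_fast
        # FDR control is nominal, not exact: allow a few background calls
        false_calls = called_fast - set(fast)
        assert len(false_calls) <= max(2, int(0.1 * len(called_fast)))

    def test_no_overlap_errors(self):
        a = pd.DataFrame(np.ones((3, 2)), index=["A", "B", "C"])
        b = pd.DataFrame(np.ones((3, 2)), index=["X", "Y", "Z"])
        with pytest.raises(ValueError):
            turnover.compare_turnover(a, b)
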