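"""Classical analysis arm: derived statistics, models, selection, correlation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from numstroop.cleaning import clean_practice, clean_tms
from numstroop.stats import (backward_regression, correlate_covariate,
                             derived_stats, distance_analysis, lmm_rt,
                             rm_anova_mixed, rtms_effect_percent,
                             summarize_conditions)


class TestDerivedStats:
    def test_printed_group_means_decompose(self):
        # incongruent 492, congruent 439, neutral 457 ms
        d = derived_stats({"congruent": 439.0, "incongruent": 492.0, "neutral": 457.0})
        assert d.sce_ms == pytest.approx(53.0)
        assert d.facilitation_ms == pytest.approx(18.0)
        assert d.interference_ms == pytest.approx(35.0)

    def test_equal_means_all_zero(self):
        d = derived_stats({"congruent": 450.0, "incongruent": 450.0, "neutral": 450.0})
        assert d.sce_ms == d.facilitation_ms == d.interference_ms == 0.0

    def test_neutral_optional(self):
        d = derived_stats({"congruent": 440.0, "incongruent": 490.0})
        assert d.sce_ms == pytest.approx(50.0)
        assert d.facilitation_ms is None and d.interference_ms is None

    def test_missing_required_mean_rejected(self):
        with pytest.raises(ValueError):
            derived_stats({"congruent": 440.0})

    @given(c=st.floats(200, 900), i=st.floats(200, 900), n=st.floats(200, 900))
    def test_sce_is_facilitation_plus_interference(self, c, i, n):
        d = derived_stats({"congruent": c, "incongruent": i, "neutral": n})
        assert d.sce_ms == pytest.approx(d.facilitation_ms + d.interference_ms, abs=1e-9)


class TestRtmsEffectPercent:
    @pytest.mark.parametrize("active,sham,expect", [
        (500.0, 500.0, 0.0), (400.0, 500.0, -20.0), (505.0, 500.0, 1.0)])
    def test_arithmetic(self, active, sham, expect):
        assert rtms_effect_percent(active, sham) == pytest.approx(expect)

    def test_nonpositive_sham_rejected(self):
        with pytest.raises(ValueError):
            rtms_effect_percent(400.0, 0.0)


class TestLmm:
    def test_congruency_gap_detected_in_practice_data(self, study):
        _, _, trials = study
        practice = trials[trials["session"] != "tms"]
        cleaned, _ = clean_practice(practice)
        cleaned = cleaned[cleaned["congruency"] != "neutral"].copy()
        cleaned["timepoint"] = cleaned["session"].where(
            cleaned["session"] != "mri", "mri" + cleaned["block"].astype(str))
        res = lmm_rt(cleaned, fixed=["congruency", "timepoint"],
                     posthoc_factors=["congruency"])
        assert res.terms["congruency"]["p"] < 0.01  # true drift gap => RT gap
        assert res.df_method is not None
        assert res.posthoc is not None and (res.posthoc["p_bonf"] >= res.posthoc["p"] - 1e-15).all()

    def test_single_participant_rejected(self, study):
        _, _, trials = study
        one = trials[trials["participant_id"] == "P01"]
        with pytest.raises(ValueError):
            lmm_rt(one.assign(rt_ms=one["rt_s"] * 1000), fixed=["congruency"])

    def test_missing_factor_rejected(self, tms_trials):
        with pytest.raises(ValueError):
            lmm_rt(tms_trials, fixed=["no_such_column"])


class TestMixedAnovaInterface:
    def test_sce_table_runs_and_reports_terms(self, tms_trials):
        cleaned, _ = clean_tms(tms_trials)
        cells = (cleaned.groupby(["participant_id", "order_group", "stimulation", "congruency"])
                 ["rt_s"].mean().mul(1000.0).rename("rt_ms").reset_index())
        piv = cells.pivot_table(index=["participant_id", "order_group", "stimulation"],
                                columns="congruency", values="rt_ms").reset_index()
        piv["sce"] = piv["incongruent"] - piv["congruent"]
        res = rm_anova_mixed(piv, dv="sce")
        assert set(res.terms) == {"order_group", "stimulation", "stimulation:order_group"}
        for t in res.terms.values():
            assert 0.0 <= t["p"] <= 1.0 and t["F"] >= 0.0


class TestDistance:
    def test_boundary_mapping_small_3_large_4(self, tms_trials):
        cleaned, _ = clean_tms(tms_trials)
        res = distance_analysis(cleaned)
        df = cleaned.copy()
        df["rt_ms"] = df["rt_s"] * 1000
        small = df[df["distance"] <= 3].groupby("participant_id")["rt_ms"].mean().mean()
        # the reported small-bin mean uses exactly distances 1-3
        cells = (df.assign(bin=np.where(df["distance"] <= 3, "small", "large"))
                 .groupby(["participant_id", "bin", "stimulation"])["rt_ms"].mean()
                 .reset_index())
        expect_small = cells[cells["bin"] == "small"]["rt_ms"].mean()
        assert res.extra["mean_rt_ms"]["small"] == pytest.approx(expect_small, rel=1e-9)

    def test_distance_effect_direction_recovered(self):
        # generative drift rises with distance => faster large-distance RTs;
        # dedicated sample with doubled blocks for a well-powered check
        from numstroop.design import DesignConfig, build_design
        from numstroop.simulate import default_truth, generate_dataset
        cfg = DesignConfig(n_participants=10, practice_trials_v1=2, mri_blocks=0,
                           practice_trials_v2=3, tms_block_trials=144, seed=23)
        sched = build_design(cfg)
        trials = generate_dataset(sched[sched["session"] == "tms"],
                                  default_truth(0.0), seed=29)
        cleaned, _ = clean_tms(trials)
        res = distance_analysis(cleaned)
        assert res.extra["mean_rt_ms"]["large"] < res.extra["mean_rt_ms"]["small"]
        assert res.terms["distance_bin"]["p"] < 0.05

    def test_out_of_range_distance_rejected(self, tms_trials):
        bad = tms_trials.copy()
        bad.loc[bad.index[0], "distance"] = 9
        with pytest.raises(ValueError):
            distance_analysis(bad)


class TestBackwardRegression:
    def _predictors(self, rng, n=15):
        return pd.DataFrame({
            "age": rng.normal(39, 14, n),
            "intensity": rng.normal(129, 22, n),
            "scalp_cortex": rng.normal(14, 2, n),
            "activation": rng.normal(3, 1, n),
            "dist_ref": rng.normal(15, 6, n),
            "days": rng.normal(20, 10, n),
        })

    def test_true_predictor_retained(self, rng):
        X = self._predictors(rng)
        y = 0.8 * X["intensity"] + rng.normal(0, 5, len(X))
        res = backward_regression(y, X)
        assert "intensity" in res.extra["retained"]
        assert res.terms["intensity"]["p"] < 0.05

    def test_pure_noise_rarely_retains_any_given_predictor(self, rng):
        # under the null each predictor's false-inclusion rate stays near
        # the removal criterion, and the empty model is the modal outcome
        from collections import Counter
        kept_counts = Counter()
        sizes = Counter()
        n_rep = 60
        for rep in range(n_rep):
            X = self._predictors(rng, n=15)
            y = pd.Series(rng.normal(0, 1, 15))
            res = backward_regression(y, X)
            kept_counts.update(res.extra["retained"])
            sizes[len(res.extra["retained"])] += 1
        for col, cnt in kept_counts.items():
            assert cnt / n_rep < 0.3, f"{col} retained too often under the null"
        assert sizes.most_common(1)[0][0] == 0  # empty model is the mode

    def test_p_out_one_keeps_full_model(self, rng):
        X = self._predictors(rng)
        y = pd.Series(rng.normal(0, 1, 15))
        res = backward_regression(y, X, p_out=1.0000001)
        assert set(res.extra["retained"]) == set(X.columns)

    def test_p_out_zero_keeps_nothing(self, rng):
        X = self._predictors(rng)
        y = 0.8 * X["intensity"] + rng.normal(0, 1, len(X))
        res = backward_regression(y, X, p_out=0.0)
        assert res.extra["retained"] == []

    def test_collinear_duplicate_dropped_with_warning(self, rng):
        X = self._predictors(rng)[["intensity"]]
        X["intensity_copy"] = X["intensity"]
        y = 0.8 * X["intensity"] + rng.normal(0, 1, len(X))
        with pytest.warns(UserWarning, match="collinear"):
            res = backward_regression(y, X)
        assert "intensity_copy" in res.extra["pre_dropped"]

    def test_constant_predictor_dropped_with_warning(self, rng):
        X = self._predictors(rng)
        X["const_col"] = 1.0
        y = pd.Series(rng.normal(0, 1, 15))
        with pytest.warns(UserWarning, match="constant"):
            res = backward_regression(y, X)
        assert "const_col" in res.extra["pre_dropped"]

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            backward_regression(pd.Series([1.0, 2.0]), self._predictors(rng, n=2))


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = correlate_covariate(x, x)
        assert r == pytest.approx(1.0)

    def test_matches_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        r, _ = correlate_covariate(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(correlate_covariate(x, y)[1])
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_covariate(np.ones(5), np.arange(5.0))


def test_condition_summaries_have_consistent_units(tms_trials):
    cleaned, _ = clean_tms(tms_trials)
    out = summarize_conditions(cleaned)
    assert len(out) == 6
    for s in out:
        assert 200 < s.mean_rt_ms < 1500  # ms scale, plausible RT range
        assert 0 <= s.accuracy <= 1 and s.sem_rt_ms >= 0
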