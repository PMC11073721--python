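"""Wiener first-passage machinery: series density, closed forms, sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.integrate import quad

from numstroop.wfpt import (DDMParams, absorption_probability, loglik_trials,
                            mean_decision_time, simulate_ddm, trial_loglik,
                            wfpt_density)


# --- independent oracle: brute-force series with a fixed large term count ---

def _density_bruteforce(t, correct, v, a, w, K=200):
    """Lower/upper-boundary defective density summed to K terms of the
    small-time expansion; independent of the adaptive implementation."""
    if correct:
        v, w = -v, 1.0 - w
    if t <= 0:
        return 0.0
    tau = t / a ** 2
    s = sum((w + 2 * k) * math.exp(-((w + 2 * k) ** 2) / (2 * tau))
            for k in range(-K, K + 1))
    f = s / math.sqrt(2 * math.pi * tau ** 3)
    return f / a ** 2 * math.exp(-v * a * w - v * v * t / 2.0)


def _density_bruteforce_large(t, correct, v, a, w, K=200):
    """Same density via the large-time expansion at fixed K."""
    if correct:
        v, w = -v, 1.0 - w
    if t <= 0:
        return 0.0
    tau = t / a ** 2
    s = sum(k * math.exp(-(k ** 2) * math.pi ** 2 * tau / 2.0) * math.sin(k * math.pi * w)
            for k in range(1, K + 1))
    return math.pi * s / a ** 2 * math.exp(-v * a * w - v * v * t / 2.0)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"v": 1.0, "a": -1.0, "t0": 0.2},
        {"v": 1.0, "a": 0.0, "t0": 0.2},
        {"v": 1.0, "a": 1.0, "t0": -0.1},
        {"v": 1.0, "a": 1.0, "t0": 0.2, "w": 0.0},
        {"v": 1.0, "a": 1.0, "t0": 0.2, "w": 1.0},
        {"v": 1.0, "a": 1.0, "t0": 0.2, "p_c": 1.0},
        {"v": np.nan, "a": 1.0, "t0": 0.2},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DDMParams(**kwargs)


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        assert wfpt_density(0.2, "correct", p) == 0.0
        assert wfpt_density(0.3, "error", p) == 0.0

    def test_driftless_unbiased_symmetry(self):
        p = DDMParams(v=0.0, a=1.4, t0=0.1, w=0.5)
        for t in (0.15, 0.3, 0.7, 1.5, 4.0):
            assert wfpt_density(t, "correct", p) == pytest.approx(
                wfpt_density(t, "error", p), rel=1e-10)

    @pytest.mark.parametrize("v,a,w", [(1.0, 1.5, 0.5), (-0.8, 0.8, 0.3),
                                       (2.0, 2.5, 0.7), (0.0, 1.0, 0.5)])
    def test_matches_bruteforce_series(self, v, a, w):
        p = DDMParams(v=v, a=a, t0=0.0, w=w)
        for t in (0.05, 0.2, 0.5, 1.0, 3.0):
            for b in ("correct", "error"):
                ref = _density_bruteforce(t, b == "correct", v, a, w)
                assert wfpt_density(t, b, p) == pytest.approx(ref, abs=1e-9)

    def test_small_and_large_time_expansions_agree(self):
        # both truncated series evaluated in their overlap region
        for v, a, w in [(1.0, 1.5, 0.5), (0.5, 1.0, 0.4)]:
            for t in np.linspace(0.1, 2.0, 15):
                small = _density_bruteforce(t, True, v, a, w)
                large = _density_bruteforce_large(t, True, v, a, w)
                assert small == pytest.approx(large, abs=1e-6)

    def test_normalization_subset(self):
        # full parameter grid runs in the acceptance suite
        for v, a, w in [(1.0, 1.5, 0.5), (-2.0, 0.5, 0.3), (0.0, 3.0, 0.7)]:
            p = DDMParams(v=v, a=a, t0=0.0, w=w)
            upper = 12.0 + 2 * a * a
            ic = quad(lambda t: wfpt_density(t, "correct", p), 0, upper, limit=300)[0]
            ie = quad(lambda t: wfpt_density(t, "error", p), 0, upper, limit=300)[0]
            assert ic + ie == pytest.approx(1.0, abs=1e-4)
            # each defective density integrates to its absorption probability
            assert ic == pytest.approx(absorption_probability(p), abs=1e-4)


class TestClosedForms:
    def test_absorption_driftless(self):
        assert absorption_probability(DDMParams(v=0.0, a=2.0, t0=0.0, w=0.5)) == 0.5
        assert absorption_probability(DDMParams(v=0.0, a=2.0, t0=0.0, w=0.3)) == pytest.approx(0.3)

    def test_absorption_closed_form_oracle(self):
        # independent closed form hard-coded here: P = 1/(1 + e^{-v a}) at w=0.5
        p = DDMParams(v=1.0, a=2.0, t0=0.0, w=0.5)
        assert absorption_probability(p) == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=1e-12)

    def test_driftless_mean_decision_time(self):
        # E[T] = a^2 w (1 - w) for v = 0
        p = DDMParams(v=0.0, a=2.0, t0=0.0, w=0.5)
        assert mean_decision_time(p) == pytest.approx(1.0)


class TestSimulator:
    def test_deterministic_under_seed(self):
        p = DDMParams(v=1.0, a=1.5, t0=0.2)
        out1 = simulate_ddm(p, 500, seed=42)
        out2 = simulate_ddm(p, 500, seed=42)
        assert np.array_equal(out1[0], out2[0]) and np.array_equal(out1[1], out2[1])

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_ddm(DDMParams(v=1.0, a=1.0, t0=0.1), 10, seed=0, dt=0.0)

    def test_accuracy_matches_absorption_probability(self):
        p = DDMParams(v=1.0, a=2.0, t0=0.3)
        c, _ = simulate_ddm(p, 50_000, seed=5, dt=1e-4)
        pa = absorption_probability(p)
        se = math.sqrt(pa * (1 - pa) / 50_000)
        assert abs(c.mean() - pa) < 3 * se + 0.003  # 0.003: Euler crossing bias allowance

    def test_driftless_mean_rt(self):
        p = DDMParams(v=0.0, a=2.0, t0=0.3, w=0.5)
        _, r = simulate_ddm(p, 50_000, seed=6, dt=1e-4)
        expect = mean_decision_time(p) + p.t0
        se = r.std(ddof=1) / math.sqrt(len(r))
        assert abs(r.mean() - expect) < 3 * se + 0.01  # Euler bias allowance

    def test_rt_distribution_matches_model_cdf(self):
        # one-sample KS of simulated RTs against the model's unconditional CDF
        p = DDMParams(v=1.0, a=1.5, t0=0.2)
        _, r = simulate_ddm(p, 10_000, seed=9, dt=1e-4)
        grid = np.linspace(0, 8, 1500)
        dens = wfpt_density(grid, "correct", p) + wfpt_density(grid, "error", p)
        cdf_grid = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf_grid /= cdf_grid[-1]
        stat = stats.kstest(r, lambda x: np.interp(x, grid, cdf_grid))
        assert stat.pvalue > 0.01


class TestTrialLoglik:
    def test_pure_diffusion_reduces_to_log_density(self):
        p = DDMParams(v=1.2, a=1.3, t0=0.25, p_c=0.0)
        ll = trial_loglik((True, 0.6), p, (0.2, 3.0))
        assert ll == pytest.approx(math.log(wfpt_density(0.6, "correct", p)), rel=1e-10)

    def test_pre_t0_rt_hits_contaminant_branch(self):
        p = DDMParams(v=1.2, a=1.3, t0=0.4, p_c=0.05)
        ll = trial_loglik((True, 0.3), p, (0.2, 3.0))
        assert ll == pytest.approx(math.log(0.05 * 0.5 / (3.0 - 0.2)), rel=1e-10)

    def test_mixture_matches_termwise_oracle(self):
        p = DDMParams(v=0.8, a=1.6, t0=0.2, p_c=0.05)
        window = (0.1, 2.5)
        for correct, rt in [(True, 0.5), (False, 0.9), (True, 1.8)]:
            f = _density_bruteforce(rt - p.t0, correct, p.v, p.a, p.w)
            ref = math.log((1 - p.p_c) * f + p.p_c * 0.5 / (window[1] - window[0]))
            assert trial_loglik((correct, rt), p, window) == pytest.approx(ref, rel=1e-9)

    def test_summed_loglik_consistent(self, rng):
        p = DDMParams(v=1.0, a=1.2, t0=0.2, p_c=0.05)
        rts = rng.uniform(0.3, 1.5, 50)
        corr = rng.random(50) < 0.8
        total = loglik_trials(rts, corr, p, (0.2, 3.0))
        assert total == pytest.approx(
            sum(trial_loglik((c, t), p, (0.2, 3.0)) for c, t in zip(corr, rts)), rel=1e-12)

    def test_empty_window_rejected(self):
        p = DDMParams(v=1.0, a=1.2, t0=0.2, p_c=0.05)
        with pytest.raises(ValueError):
            trial_loglik((True, 0.5), p, (1.0, 1.0))

    def test_floor_prevents_minus_infinity(self):
        p = DDMParams(v=1.0, a=1.2, t0=0.5, p_c=0.0)
        ll = trial_loglik((True, 0.1), p, (0.2, 3.0))  # zero density, no contaminant
        assert np.isfinite(ll)


@given(v=st.floats(-2, 2), a=st.floats(0.5, 3), w=st.floats(0.3, 0.7))
def test_absorption_probabilities_sum_to_one(v, a, w):
    """P(correct) of the process and of its mirror image sum to 1."""
    p = DDMParams(v=v, a=a, t0=0.0, w=w)
    mirrored = DDMParams(v=-v, a=a, t0=0.0, w=1.0 - w)
    assert absorption_probability(p) + absorption_probability(mirrored) == pytest.approx(1.0, abs=1e-12)
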