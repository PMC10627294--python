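import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb, expit

from patdet import (
    CONDITIONS,
    GeneratorParams,
    ObserverSpec,
    build_session,
    dominant_feature,
    exact_feature_distribution,
    exact_performance,
    feature_matrix,
    generate_dms_batch,
    glm_fit,
    simulate_observer,
    single_feature_classifier,
    standardize_menard,
)
from patdet.features import signed_feature_batch

LD = CONDITIONS["LD"]


class TestExactFeatureDistribution:
    def test_f3_random_is_binomial(self):
        # the 19 adjacent-pair indicators of a fair iid sequence are
        # independent fair coins, so f3 ~ Binomial(19, 1/2)
        dist = exact_feature_distribution(3, LD)
        assert np.array_equal(dist.support, np.arange(20))
        expected = comb(19, dist.support) * 0.5**19
        assert np.allclose(dist.p_random, expected, atol=1e-12)

    def test_f4_random_balanced_mass(self):
        dist = exact_feature_distribution(4, LD)
        p0 = dist.p_random[dist.support == 0][0]
        assert p0 == pytest.approx(comb(20, 10) * 0.5**20, rel=1e-12)

    @pytest.mark.parametrize("fid", [1, 2, 3, 4])
    def test_distributions_normalized(self, fid):
        params = GeneratorParams(0.9, 0.2, 12)
        dist = exact_feature_distribution(fid, params)
        assert dist.p_random.sum() == pytest.approx(1.0, abs=1e-10)
        assert dist.p_dms.sum() == pytest.approx(1.0, abs=1e-10)

    def test_f1_matches_sampling_histogram(self):
        params = GeneratorParams(0.9, 0.1, 10)
        dist = exact_feature_distribution(1, params)
        rng = np.random.default_rng(0)
        n_draws = 100_000
        vals = signed_feature_batch(1, generate_dms_batch(params, n_draws, rng))
        for v, p in zip(dist.support, dist.p_dms):
            emp = (vals == v).mean()
            se = math.sqrt(max(p * (1 - p), 1e-12) / n_draws)
            assert abs(emp - p) < max(4 * se, 1e-4)


class TestSingleFeatureClassifier:
    def test_f3_rule_is_upper_threshold(self):
        dist = exact_feature_distribution(3, LD)
        lr = dist.p_dms / dist.p_random
        assert np.all(np.diff(lr) > 0)  # monotone likelihood ratio
        decision = single_feature_classifier(dist).decision
        assert np.all(np.diff(decision.astype(int)) >= 0)  # one switch, upward

    def test_half_disruption_always_random(self):
        params = GeneratorParams(0.9, 0.5, 12)
        clf = single_feature_classifier(exact_feature_distribution(3, params))
        assert not clf.decision.any()
        assert clf.exact_performance().d_prime == 0.0

    def test_feature_rule_below_full_model(self):
        params = GeneratorParams(0.9, 0.1, 12)
        full = exact_performance(params).d_prime
        clf = single_feature_classifier(exact_feature_distribution(3, params))
        assert clf.exact_performance().d_prime <= full

    def test_out_of_support_value_rejected(self):
        clf = single_feature_classifier(
            exact_feature_distribution(3, GeneratorParams(0.9, 0.1, 12))
        )
        with pytest.raises(ValueError, match="support"):
            clf.decide_batch(np.ones((1, 30), dtype=np.uint8))


def _observer_data(spec, n_trials, sess_seed, resp_seed, condition="LD"):
    session = build_session(condition, n_trials=n_trials, seed=sess_seed)
    responses = simulate_observer(spec, session, np.random.default_rng(resp_seed))
    return feature_matrix(session.sequences()), responses["response"]


class TestGLMFit:
    def test_null_model_recovers_base_rate(self):
        # responses independent of the stimuli: slopes ~ 0, intercept ~ logit(rate)
        rng = np.random.default_rng(5)
        session = build_session("LD", n_trials=2000, seed=6)
        X = feature_matrix(session.sequences())
        y = rng.random(2000) < 0.6
        fit = glm_fit(X, y, (1, 2, 3, 4))
        assert np.all(np.abs(fit.beta / fit.beta_se[1:]) < 4)
        base = math.log(0.6 / 0.4)
        eta_mean = fit.beta0 + X.to_numpy(float) @ fit.beta
        assert np.mean(expit(eta_mean)) == pytest.approx(0.6, abs=0.05)
        assert abs(base) < 10  # sanity on scale

    def test_parameter_recovery(self):
        spec = ObserverSpec(beta0=-6.0, betas=(0.25, 0.0, 0.35, 0.0), lapse=0.0)
        X, y = _observer_data(spec, 10_000, sess_seed=3, resp_seed=7)
        fit = glm_fit(X, y, (1, 3))
        truth = np.array([0.25, 0.35])
        assert not fit.separation
        assert np.all(np.abs(fit.beta - truth) < 4 * fit.beta_se[1:])
        assert abs(fit.beta0 - (-6.0)) < 4 * fit.beta_se[0]

    def test_loglik_matches_direct_bernoulli_evaluation(self):
        spec = ObserverSpec(beta0=-4.0, betas=(0.0, 0.0, 0.3, 0.0), lapse=0.1)
        X, y = _observer_data(spec, 300, sess_seed=8, resp_seed=9)
        fit = glm_fit(X, y, (2, 3))
        yb = (np.asarray(y) == "DMS").astype(float)
        p = expit(fit.beta0 + X[["f2_signed", "f3"]].to_numpy(float) @ fit.beta)
        direct = float(np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
        assert fit.loglik == pytest.approx(direct, rel=1e-10)

    def test_complete_separation_flagged_and_capped(self):
        session = build_session("LD", n_trials=100, seed=10)
        X = feature_matrix(session.sequences())
        y = X["f3"].to_numpy() > X["f3"].median()  # deterministic split
        fit = glm_fit(X, y, (3,))
        assert fit.separation
        assert np.all(np.isfinite(fit.beta))
        assert np.isfinite(fit.loglik) and np.isfinite(fit.aicc)

    def test_constant_feature_rejected(self):
        X = pd.DataFrame({"f3": np.full(50, 7), "f4": np.arange(50) % 5})
        y = np.arange(50) % 2 == 0
        with pytest.raises(ValueError, match="constant"):
            glm_fit(X, y, (3,))

    def test_one_class_rejected(self):
        session = build_session("LD", n_trials=10, seed=11)
        X = feature_matrix(session.sequences())
        with pytest.raises(ValueError, match="response class"):
            glm_fit(X, np.ones(10, dtype=bool), (3,))

    def test_nested_loglik_non_decreasing(self):
        spec = ObserverSpec(beta0=-5.0, betas=(0.2, 0.0, 0.25, 0.0), lapse=0.05)
        X, y = _observer_data(spec, 200, sess_seed=12, resp_seed=13)
        smaller = glm_fit(X, y, (3,)).loglik
        larger = glm_fit(X, y, (1, 3)).loglik
        assert larger >= smaller - 1e-9


class TestMenardStandardization:
    def test_scale_invariance(self):
        spec = ObserverSpec(beta0=-5.0, betas=(0.0, 0.0, 0.4, 0.0), lapse=0.05)
        X, y = _observer_data(spec, 400, sess_seed=14, resp_seed=15)
        fit = glm_fit(X, y, (3,))
        X_scaled = X.copy()
        X_scaled["f3"] = X_scaled["f3"] * 7.0
        fit_scaled = glm_fit(X_scaled, y, (3,))
        assert fit_scaled.beta_std[0] == pytest.approx(fit.beta_std[0], rel=1e-6)

    def test_monotone_in_generative_weight(self):
        stds = []
        for strength in (0.1, 0.5, 1.0):
            spec = ObserverSpec(
                beta0=-strength * 9.5 / 3.0,
                betas=(0.0, 0.0, strength / 3.0, 0.0),
                lapse=0.0,
            )
            X, y = _observer_data(spec, 4000, sess_seed=16, resp_seed=17)
            stds.append(glm_fit(X, y, (3,)).beta_std[0])
        assert stds[0] < stds[1] < stds[2]

    def test_null_association_near_zero(self):
        rng = np.random.default_rng(18)
        session = build_session("LD", n_trials=4000, seed=19)
        X = feature_matrix(session.sequences())
        y = rng.random(4000) < 0.5
        fit = glm_fit(X, y, (1, 2, 3, 4))
        assert np.all(np.abs(fit.beta_std) < 0.1)

    def test_explicit_call_matches_fit(self):
        spec = ObserverSpec(beta0=-5.0, betas=(0.0, 0.0, 0.4, 0.0), lapse=0.05)
        X, y = _observer_data(spec, 300, sess_seed=20, resp_seed=21)
        fit = glm_fit(X, y, (1, 3))
        again = standardize_menard(fit, X, y)
        assert np.allclose(again, fit.beta_std)


class TestDominantFeature:
    def test_recovers_f3_only_observer(self):
        spec = ObserverSpec(beta0=-0.65 * 12.0, betas=(0.0, 0.0, 0.65, 0.0), lapse=0.02)
        X, y = _observer_data(spec, 1000, sess_seed=22, resp_seed=23)
        dom = dominant_feature(glm_fit(X, y, (1, 2, 3, 4)))
        assert dom.feature_id == 3
        assert dom.reliable

    def test_exact_tie_breaks_to_lowest_index(self):
        spec = ObserverSpec(beta0=-5.0, betas=(0.3, 0.0, 0.3, 0.0), lapse=0.0)
        X, y = _observer_data(spec, 500, sess_seed=24, resp_seed=25)
        fit = glm_fit(X, y, (1, 2, 3, 4))
        fit.beta_std = np.array([0.5, 0.1, 0.5, 0.2])  # constructed exact tie
        dom = dominant_feature(fit)
        assert dom.feature_id == 1
        assert dom.tied

    def test_guessing_observer_flagged_unreliable(self):
        spec = ObserverSpec(beta0=0.0, betas=(0.0, 0.0, 0.0, 0.0), lapse=1.0)
        X, y = _observer_data(spec, 4000, sess_seed=26, resp_seed=27)
        dom = dominant_feature(glm_fit(X, y, (1, 2, 3, 4)))
        assert not dom.reliable

    def test_requires_all_features_fit(self):
        spec = ObserverSpec(beta0=-5.0, betas=(0.0, 0.0, 0.4, 0.0), lapse=0.05)
        X, y = _observer_data(spec, 200, sess_seed=28, resp_seed=29)
        with pytest.raises(ValueError, match="all-features"):
            dominant_feature(glm_fit(X, y, (1, 3)))
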