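import math

import numpy as np
import pytest

from oracles import brute_force_dms_probability
from patdet import (
    CONDITIONS,
    FullBayesClassifier,
    GeneratorParams,
    enumerate_sequences,
    exact_performance,
    generate_random_batch,
    likelihood_dms,
    likelihood_dms_batch,
    likelihood_random,
    mc_performance,
    posterior_odds,
)
from patdet.sdt import dprime_se

LD = CONDITIONS["LD"]


class TestLikelihoodRandom:
    def test_single_token(self):
        assert likelihood_random("1") == pytest.approx(math.log(0.5))

    def test_twenty_tokens(self):
        assert likelihood_random("0" * 20) == pytest.approx(20 * math.log(0.5))

    def test_uniform_over_sequences(self, rng):
        a, b = rng.integers(0, 2, (2, 15))
        assert likelihood_random(a) == likelihood_random(b)


class TestLikelihoodDMS:
    def test_matches_brute_force_marginalization(self, rng):
        params = GeneratorParams(0.9, 0.2, 10)
        seqs = rng.integers(0, 2, (64, 10), dtype=np.uint8)
        oracle = brute_force_dms_probability(seqs, params.p_r, params.p_d)
        batch = np.exp(likelihood_dms_batch(seqs, params))
        scalar = np.exp([likelihood_dms(s, params) for s in seqs])
        assert np.max(np.abs(batch / oracle - 1)) < 1e-10
        assert np.max(np.abs(scalar / oracle - 1)) < 1e-10

    def test_uninformative_emissions_at_half_disruption(self, rng):
        params = GeneratorParams(0.9, 0.5, 20)
        seq = rng.integers(0, 2, 20)
        assert likelihood_dms(seq, params) == pytest.approx(20 * math.log(0.5))

    def test_markov_closed_form_without_disruption(self, rng):
        params = GeneratorParams(0.9, 0.0, 20)
        seq = rng.integers(0, 2, 20)
        reps = int((seq[1:] == seq[:-1]).sum())
        closed = math.log(0.5) + reps * math.log(0.9) + (19 - reps) * math.log(0.1)
        assert likelihood_dms(seq, params) == pytest.approx(closed, rel=1e-12)

    def test_normalization(self):
        for n in (1, 5, 10):
            params = GeneratorParams(0.9, 0.2, n)
            total = np.exp(likelihood_dms_batch(enumerate_sequences(n), params)).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_complement_and_reversal_invariance(self, rng):
        seqs = generate_random_batch(200, 20, rng)
        ll = likelihood_dms_batch(seqs, LD)
        assert np.array_equal(ll, likelihood_dms_batch(1 - seqs, LD))
        assert np.allclose(ll, likelihood_dms_batch(seqs[:, ::-1], LD), rtol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            likelihood_dms("", LD)

    def test_degenerate_impossible_sequence(self):
        # p_r=1, p_d=0: only monochromatic sequences have positive probability
        params = GeneratorParams(1.0, 0.0, 5)
        assert likelihood_dms("11111", params) == pytest.approx(math.log(0.5))
        assert likelihood_dms("11011", params) == -np.inf
        batch = likelihood_dms_batch(np.array([[1, 1, 0, 1, 1]]), params)
        assert batch[0] == -np.inf


class TestPosteriorOdds:
    def test_prior_odds_are_one(self, rng):
        seq = rng.integers(0, 2, 20)
        res = posterior_odds(seq, LD)
        assert res.lam == pytest.approx(
            math.exp(res.log_p_dms - res.log_p_random), rel=1e-12
        )

    def test_half_disruption_always_random(self, rng):
        params = GeneratorParams(0.9, 0.5, 20)
        for _ in range(5):
            res = posterior_odds(rng.integers(0, 2, 20), params)
            assert res.lam == pytest.approx(1.0, abs=1e-12)
            assert res.decision == "RANDOM"

    def test_maximal_pattern_is_dms(self):
        assert posterior_odds("1" * 20, LD).decision == "DMS"

    def test_decision_is_monotone_threshold_on_repetitions_without_disruption(self):
        # p_d=0: lambda depends only on the repetition count R and is
        # monotone in R, so the decision is an upper threshold on R
        params = GeneratorParams(0.9, 0.0, 20)
        decisions = []
        for reps in range(20):
            # build a sequence with exactly `reps` adjacent equal pairs
            seq = [0]
            for t in range(19):
                seq.append(seq[-1] if t < reps else 1 - seq[-1])
            assert sum(a == b for a, b in zip(seq, seq[1:])) == reps
            decisions.append(posterior_odds(seq, params).decision == "DMS")
        flips = sum(a != b for a, b in zip(decisions, decisions[1:]))
        assert flips == 1 and decisions[-1] and not decisions[0]

    def test_tie_resolves_to_random(self, rng):
        params = GeneratorParams(0.9, 0.5, 20)
        assert posterior_odds(rng.integers(0, 2, 20), params).decision == "RANDOM"

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            posterior_odds("11", GeneratorParams(0.9, 0.1, 2), threshold=0.0)


class TestExactPerformance:
    def test_half_disruption_collapse(self):
        est = exact_performance(GeneratorParams(0.9, 0.5, 20))
        assert est.d_prime == 0.0
        assert est.hit_rate == est.fa_rate

    def test_hit_rate_dominates_fa_rate(self):
        for cond in ("LD", "MD", "HD"):
            est = exact_performance(CONDITIONS[cond])
            assert 0.0 <= est.fa_rate < est.hit_rate <= 1.0

    def test_matches_trial_simulation(self):
        # exact enumeration at n=8 vs a large Monte-Carlo simulation
        params = GeneratorParams(0.9, 0.1, 8)
        exact = exact_performance(params)
        mc = mc_performance(
            FullBayesClassifier(params), params, n_reps=200_000,
            rng=np.random.default_rng(0),
        )
        se_h = np.sqrt(exact.hit_rate * (1 - exact.hit_rate) / 200_000)
        se_f = np.sqrt(exact.fa_rate * (1 - exact.fa_rate) / 200_000)
        assert abs(mc.hit_rate - exact.hit_rate) < 4 * se_h
        assert abs(mc.fa_rate - exact.fa_rate) < 4 * se_f

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="cap"):
            exact_performance(GeneratorParams(0.9, 0.1, 25))


class TestMonteCarloPerformance:
    def test_consistent_with_exact(self):
        params = CONDITIONS["LD"]
        exact = exact_performance(params)
        mc = mc_performance(
            FullBayesClassifier(params), params, n_reps=5000,
            rng=np.random.default_rng(1),
        )
        assert abs(mc.d_prime - exact.d_prime) < 4 * dprime_se(mc)

    def test_half_disruption_near_zero(self):
        params = GeneratorParams(0.9, 0.5, 20)
        mc = mc_performance(
            FullBayesClassifier(params), params, n_reps=2000,
            rng=np.random.default_rng(2),
        )
        assert mc.d_prime == 0.0  # lambda = 1 everywhere, never responds DMS

    def test_deterministic_given_seed(self):
        params = CONDITIONS["MD"]
        clf = FullBayesClassifier(params)
        a = mc_performance(clf, params, 500, np.random.default_rng(3))
        b = mc_performance(clf, params, 500, np.random.default_rng(3))
        assert a == b
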