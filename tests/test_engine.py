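"""Posterior updating, MPWKL selection and the variable-length session loop."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cdcat
from cdcat import (
    PosteriorState,
    TerminationRule,
    class_prob_table,
    init_posterior,
    kl_matrices,
    latent_classes,
    mpwkl_index,
    run_session,
    run_sessions_batch,
    sample_true_bank,
    select_item,
    update_posterior,
)
from conftest import random_bank


class TestPosterior:
    def test_uniform_prior(self):
        state = init_posterior(5)
        np.testing.assert_allclose(state.pi, 1 / 32)
        assert state.administered == [] and state.responses == []
        np.testing.assert_allclose(init_posterior(1).pi, [0.5, 0.5])
        assert state.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_item_leaves_posterior_unchanged(self):
        state = init_posterior(2)
        table = np.full((4, 1), 0.6)
        new = update_posterior(state, 0, 1, table)
        np.testing.assert_allclose(new.pi, state.pi)
        assert new.administered == [0] and new.responses == [1]

    def test_k1_bayes_example(self):
        state = init_posterior(1)
        table = np.array([[0.2], [0.9]])
        new = update_posterior(state, 0, 1, table)
        np.testing.assert_allclose(new.pi, [0.2 / 1.1, 0.9 / 1.1])

    def test_repeat_administration_rejected(self):
        state = init_posterior(1)
        table = np.array([[0.2], [0.9]])
        state = update_posterior(state, 0, 1, table)
        with pytest.raises(ValueError):
            update_posterior(state, 0, 0, table)

    @given(seed=st.integers(0, 5000))
    def test_sequential_updates_equal_joint_likelihood(self, seed):
        """Oracle: Bayes updating item by item equals one joint-likelihood update,
        in any order."""
        rng = np.random.default_rng(seed)
        C, J = 8, 6
        table = rng.uniform(0.05, 0.95, size=(C, J))
        items = rng.permutation(J)[:4]
        responses = rng.integers(0, 2, size=4)
        state = init_posterior(3)
        for j, x in zip(items, responses):
            state = update_posterior(state, int(j), int(x), table)
        lik = np.ones(C)
        for j, x in zip(items, responses):
            lik *= table[:, j] if x else 1 - table[:, j]
        expected = lik / C
        expected /= expected.sum()
        np.testing.assert_allclose(state.pi, expected, atol=1e-12)
        assert abs(state.pi.sum() - 1) < 1e-10


def mpwkl_triple_loop(item, pi, table):
    """Literal triple-nested sum over (d, c, x), the definition of the index."""
    C = table.shape[0]
    total = 0.0
    for d in range(C):
        inner = 0.0
        for c in range(C):
            for x in (0, 1):
                pd = table[d, item] if x else 1 - table[d, item]
                pc = table[c, item] if x else 1 - table[c, item]
                inner += math.log(pd / pc) * pd * pi[c]
        total += inner * pi[d]
    return total


class TestMPWKL:
    def test_uninformative_item_scores_zero(self):
        table = np.full((4, 1), 0.37)
        state = init_posterior(2)
        assert mpwkl_index(0, state, table) == pytest.approx(0.0, abs=1e-15)

    def test_point_mass_posterior_scores_zero(self):
        pi = np.zeros(4)
        pi[2] = 1.0
        state = PosteriorState(pi=pi)
        table = np.random.default_rng(0).uniform(0.1, 0.9, size=(4, 3))
        for j in range(3):
            assert mpwkl_index(j, state, table) == pytest.approx(0.0, abs=1e-12)

    def test_k2_dina_item_matches_triple_loop(self):
        bank = cdcat.ItemBank("DINA", np.array([[1, 0]]), {"s": [0.1], "g": [0.2]})
        table = class_prob_table(bank)
        state = init_posterior(2)
        assert mpwkl_index(0, state, table) == pytest.approx(
            mpwkl_triple_loop(0, state.pi, table), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_vectorized_index_matches_triple_loop_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.integers(1, 4)
        C, J = 2**K, 5
        table = rng.uniform(0.02, 0.98, size=(C, J))
        pi = rng.dirichlet(np.ones(C))
        state = PosteriorState(pi=pi)
        A = kl_matrices(table)
        for j in range(J):
            expected = mpwkl_triple_loop(j, pi, table)
            assert mpwkl_index(j, state, table, A) == pytest.approx(expected, abs=1e-12)
            assert expected >= -1e-12

    def test_precomputed_kl_matrices_equal_on_the_fly(self):
        rng = np.random.default_rng(3)
        table = rng.uniform(0.05, 0.95, size=(8, 10))
        A = kl_matrices(table)
        state = PosteriorState(pi=rng.dirichlet(np.ones(8)))
        for j in range(10):
            assert mpwkl_index(j, state, table, A) == pytest.approx(
                mpwkl_index(j, state, table), abs=1e-14
            )


class TestSelection:
    def test_single_available_item_is_selected(self):
        table = np.random.default_rng(0).uniform(0.1, 0.9, size=(4, 6))
        state = init_posterior(2)
        assert select_item(state, table, np.array([3])) == 3

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            select_item(init_posterior(2), np.ones((4, 2)) * 0.5, np.array([], dtype=int))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_argmax_on_random_pools(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.uniform(0.05, 0.95, size=(8, 20))
        pi = rng.dirichlet(np.ones(8))
        state = PosteriorState(pi=pi)
        pool = rng.permutation(20)[:12]
        pool.sort()
        scores = [mpwkl_triple_loop(j, pi, table) for j in pool]
        assert select_item(state, table, pool) == pool[int(np.argmax(scores))]


class TestSession:
    def make_banks(self, q5, sd=0.2, model="DINA", quality="low", seed=0):
        true = sample_true_bank(model, quality, q5, np.random.default_rng(seed))
        est = cdcat.inject_calibration_error(true, sd, np.random.default_rng(seed + 1))
        return true, est

    def test_threshold_termination_and_record_invariants(self, q5):
        true, est = self.make_banks(q5, sd=0.0, model="DINA", quality="high")
        rule = TerminationRule(epsilon=0.7, max_length=30)
        rec = run_session(np.array([1, 0, 1, 1, 0]), true, est, rule, np.random.default_rng(2))
        assert rec.test_length == len(rec.administered) <= 30
        assert len(set(rec.administered)) == rec.test_length
        if rec.terminated_by == "threshold":
            assert rec.posterior.max() >= 0.7
        assert rec.map_estimate.tolist() == latent_classes(5)[rec.map_class].tolist()

    def test_unreachable_threshold_runs_to_max_length(self, q5):
        true, est = self.make_banks(q5, sd=0.0, model="DINA", quality="low")
        rule = TerminationRule(epsilon=0.9999999, max_length=12)
        rec = run_session(np.array([1, 1, 0, 0, 1]), true, est, rule, np.random.default_rng(3))
        assert rec.test_length == 12
        assert rec.terminated_by == "max_length"

    def test_session_deterministic_given_seed(self, q5):
        true, est = self.make_banks(q5, sd=0.2)
        rule = TerminationRule()
        recs = [
            run_session(np.array([0, 1, 1, 0, 1]), true, est, rule, np.random.default_rng(77))
            for _ in range(2)
        ]
        assert recs[0].administered == recs[1].administered
        assert recs[0].responses == recs[1].responses
        np.testing.assert_array_equal(recs[0].posterior, recs[1].posterior)

    def test_mismatched_banks_rejected(self, q5, q3):
        true = sample_true_bank("DINA", "low", q5, np.random.default_rng(0))
        other = sample_true_bank("DINA", "low", q3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            run_session(np.array([1, 0, 1, 0, 1]), true, other, TerminationRule(), np.random.default_rng(0))

    @pytest.mark.parametrize("model", ["DINA", "RRUM", "CRUM"])
    def test_batch_runner_matches_single_session_loop(self, model, q5):
        """Contract: the lockstep vectorized runner reproduces the scalar
        reference session-by-session when fed the same uniform variates."""
        true, est = self.make_banks(q5, sd=0.2, model=model)
        rule = TerminationRule(epsilon=0.8, max_length=15)
        N = 8
        profiles = cdcat.generate_examinees(N, 5, np.random.default_rng(6))
        uniforms = np.random.default_rng(7).random((N, rule.max_length))
        batch = run_sessions_batch(profiles, true, est, rule, uniforms)
        for i in range(N):
            rng = _SequenceRNG(uniforms[i])
            rec = run_session(profiles[i], true, est, rule, rng)
            assert rec.test_length == batch.lengths[i]
            assert rec.terminated_by == batch.terminated_by[i]
            assert rec.administered == [j for j in batch.items[i] if j >= 0]
            assert rec.map_class == batch.map_class[i]
            np.testing.assert_allclose(rec.posterior, batch.posterior[i], atol=1e-12)

    def test_stricter_threshold_never_shortens_a_paired_session(self, q5):
        """First-crossing monotonicity: on shared response variates, eps=0.8
        sessions are at least as long as eps=0.7 sessions, examinee by examinee."""
        true, est = self.make_banks(q5, sd=0.1, model="RRUM", quality="mix")
        N = 40
        profiles = cdcat.generate_examinees(N, 5, np.random.default_rng(8))
        uniforms = np.random.default_rng(9).random((N, 30))
        lo = run_sessions_batch(profiles, true, est, TerminationRule(0.7, 30), uniforms)
        hi = run_sessions_batch(profiles, true, est, TerminationRule(0.8, 30), uniforms)
        assert (hi.lengths >= lo.lengths).all()

    def test_posterior_normalized_after_every_update(self, q5):
        true, est = self.make_banks(q5, sd=0.3)
        N = 20
        profiles = cdcat.generate_examinees(N, 5, np.random.default_rng(10))
        uniforms = np.random.default_rng(11).random((N, 30))
        batch = run_sessions_batch(profiles, true, est, TerminationRule(), uniforms)
        np.testing.assert_allclose(batch.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert (batch.posterior >= 0).all()


class _SequenceRNG:
    """Replays a fixed uniform sequence through the Generator.random() call."""

    def __init__(self, values):
        self._values = iter(values)

    def random(self):
        return next(self._values)
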