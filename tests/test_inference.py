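import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actinf.core_model import Policy, ln, normalise, softmax
from actinf.inference import (
    InferenceConfig,
    MDPProcess,
    TrialRecord,
    bayesian_model_average,
    expected_free_energy,
    free_energy,
    gradient_update,
    init_beliefs,
    policy_posterior,
    run_level_trial,
    select_action,
    state_error,
    update_precision,
)
from .conftest import enumerate_posterior, make_single_factor_level, random_level


def _beliefs(level, **kw):
    return init_beliefs(level, InferenceConfig(**kw))


# ---------------------------------------------------------------------------
# state errors and gradient descent
# ---------------------------------------------------------------------------

class TestStateError:
    def test_symmetric_model_gives_zero_error(self):
        """Uniform A, B, D and uniform beliefs sit at the fixed point."""
        n = 3
        level = make_single_factor_level(
            np.full((n, n), 1 / n), np.full((n, n), 1 / n), np.full(n, 1 / n), T=2)
        beliefs = _beliefs(level)
        errs = state_error(level, 0, 0, beliefs, [[0], [0]])
        assert np.allclose(errs[0], 0.0, atol=1e-12)

    def test_error_vanishes_at_message_sum(self):
        """When nu already equals the message sum, expected states cease to
        change."""
        rng = np.random.default_rng(3)
        level, A, B, D = random_level(rng, n_states=3, T=2)
        obs = [[1], [2]]
        beliefs = _beliefs(level)
        post, _ = enumerate_posterior(A, B, D, [1, 2])
        beliefs.nu[0][0] = np.log(post)
        errs0 = state_error(level, 0, 0, beliefs, obs)
        errs1 = state_error(level, 0, 1, beliefs, obs)
        assert np.allclose(errs0[0], 0.0, atol=1e-9)
        assert np.allclose(errs1[0], 0.0, atol=1e-9)

    def test_two_state_toy_matches_hand_computed_messages(self):
        """Identity B, A=((.8,.2),(.2,.8)), outcome 0 at t=0: the message sum
        is the enumeration posterior, so eps = ln q* - ln(uniform)."""
        A = np.array([[0.8, 0.2], [0.2, 0.8]])
        level = make_single_factor_level(A, np.eye(2), np.full(2, 0.5), T=2)
        beliefs = _beliefs(level)
        obs = [[0], None]
        post, _ = enumerate_posterior(A, np.eye(2), np.full(2, 0.5), [0, None])
        expected = np.log(post[0]) - np.log(np.full(2, 0.5))
        expected -= expected.mean()  # errors are defined on normalised logs
        got = state_error(level, 0, 0, beliefs, obs)[0]
        assert np.allclose(got - got.mean(), expected, atol=1e-9)

    def test_time_outside_horizon_rejected(self):
        level, *_ = random_level(np.random.default_rng(0), n_states=2, T=2)
        with pytest.raises(ValueError):
            state_error(level, 0, 5, _beliefs(level), [[0], [0]])


class TestGradientUpdate:
    def test_converged_beliefs_do_not_move(self):
        rng = np.random.default_rng(5)
        level, A, B, D = random_level(rng, n_states=3, T=2)
        obs = [[0], [1]]
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, obs, n_iter=400)
        rec = TrialRecord(level_name="t", T=2)
        gradient_update(beliefs, level, obs, n_iter=1, record=rec, t_now=0)
        assert np.allclose(rec.nu_dot_log[0][0], 0.0, atol=1e-10)

    @pytest.mark.parametrize("n,T,seed", [(2, 2, 0), (3, 2, 1), (4, 3, 2), (2, 3, 3)])
    def test_converged_posterior_equals_enumeration(self, n, T, seed):
        """Converged per-policy posteriors match the brute-force enumeration
        over all state sequences to well below 1e-4."""
        rng = np.random.default_rng(seed)
        level, A, B, D = random_level(rng, n_states=n, T=T)
        obs_idx = [int(rng.integers(n)) for _ in range(T)]
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, [[o] for o in obs_idx], n_iter=300)
        post, _ = enumerate_posterior(A, B, D, obs_idx)
        assert np.abs(beliefs.s_bar[0][0] - post).max() < 1e-6

    def test_inflated_component_receives_negative_feedback(self):
        """A belief component pushed above its fixed point gets a negative
        nu_dot (the negative-feedback property of the error units)."""
        rng = np.random.default_rng(11)
        level, A, B, D = random_level(rng, n_states=3, T=2)
        obs = [[0], [1]]
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, obs, n_iter=400)
        beliefs.nu[0][0, 0, 1] += 2.0  # inflate one component
        rec = TrialRecord(level_name="t", T=2)
        gradient_update(beliefs, level, obs, n_iter=1, record=rec, t_now=0)
        assert rec.nu_dot_log[0][0][0, 0, 1] < 0

    def test_invalid_settings_rejected(self):
        level, *_ = random_level(np.random.default_rng(0), n_states=2, T=2)
        beliefs = _beliefs(level)
        with pytest.raises(ValueError):
            gradient_update(beliefs, level, [[0], [0]], n_iter=0)
        with pytest.raises(ValueError):
            gradient_update(beliefs, level, [[0], [0]], step_size=1.5)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

class TestFreeEnergy:
    def _toy(self, seed=9, n=3, T=2):
        rng = np.random.default_rng(seed)
        level, A, B, D = random_level(rng, n_states=n, T=T)
        obs_idx = [int(rng.integers(n)) for _ in range(T)]
        return level, A, B, D, obs_idx

    def test_bound_saturates_at_exact_posterior(self):
        """With Q set to the exact posterior marginals, F equals the negative
        log evidence: the bound is tight."""
        level, A, B, D, obs_idx = self._toy()
        post, logZ = enumerate_posterior(A, B, D, obs_idx)
        beliefs = _beliefs(level)
        beliefs.nu[0][0] = np.log(post)
        beliefs.s_bar[0] = softmax(beliefs.nu[0], axis=-1)
        F = free_energy(level, 0, beliefs, [[o] for o in obs_idx])
        assert F == pytest.approx(-logZ, abs=1e-8)

    def test_any_perturbed_posterior_raises_free_energy(self):
        """Jensen's inequality: F > -ln P(o|pi) strictly away from the
        optimum."""
        level, A, B, D, obs_idx = self._toy(seed=10)
        post, logZ = enumerate_posterior(A, B, D, obs_idx)
        for eps in (0.3, -0.2):
            beliefs = _beliefs(level)
            q = post.copy()
            q[0] = normalise(q[0] + np.array([eps % 0.5] + [0] * (q.shape[1] - 1)), axis=0)
            beliefs.nu[0][0] = ln(q)
            beliefs.s_bar[0] = softmax(beliefs.nu[0], axis=-1)
            F = free_energy(level, 0, beliefs, [[o] for o in obs_idx])
            assert F > -logZ + 1e-10

    def test_matches_term_by_term_enumeration_oracle(self):
        """F recomputed termwise from the enumeration oracle:
        -ln Z + sum_t KL(q_t || posterior marginal)."""
        level, A, B, D, obs_idx = self._toy(seed=12, n=3, T=2)
        rng = np.random.default_rng(1)
        beliefs = _beliefs(level)
        q = normalise(rng.random((level.T, 3)) + 0.2, axis=1)
        beliefs.nu[0][0] = np.log(q)
        beliefs.s_bar[0] = softmax(beliefs.nu[0], axis=-1)
        post, logZ = enumerate_posterior(A, B, D, obs_idx)
        expected = -logZ + float(
            sum((q[t] * (np.log(q[t]) - np.log(post[t]))).sum()
                for t in range(level.T)))
        F = free_energy(level, 0, beliefs, [[o] for o in obs_idx])
        assert F == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# expected free energy
# ---------------------------------------------------------------------------

class TestExpectedFreeEnergy:
    def test_delta_belief_with_deterministic_likelihood_has_zero_epistemic(self):
        """Nothing left to learn: a known state under a noiseless mapping."""
        level = make_single_factor_level(np.eye(3), np.eye(3),
                                         np.array([1.0, 0, 0]), T=3)
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, [[0], None, None], n_iter=64)
        _, _, epistemic = expected_free_energy(level, 0, beliefs, 2)
        assert epistemic == pytest.approx(0.0, abs=1e-6)

    def test_uniform_preferences_equalise_pragmatic_value(self):
        """With flat C the pragmatic part cannot distinguish policies."""
        n = 3
        B = np.stack([np.roll(np.eye(n), k, axis=0) for k in range(n)], axis=2)
        level = make_single_factor_level(
            np.eye(n), np.eye(n), np.full(n, 1 / n), T=2,
            policies=[Policy(actions=((k,),)) for k in range(n)])
        level.B = [B]
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, [[0], None], n_iter=16)
        prag = [expected_free_energy(level, p, beliefs, 1)[1] for p in range(n)]
        assert np.allclose(prag, prag[0], atol=1e-9)

    def test_epistemic_part_equals_mutual_information(self):
        """2-state toy: Q=(.5,.5), A=((.9,.1),(.1,.9)): epistemic = -I(s;o)
        by brute-force double summation."""
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        level = make_single_factor_level(A, np.eye(2), np.full(2, 0.5), T=2)
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, [None, None], n_iter=1)
        _, _, epistemic = expected_free_energy(level, 0, beliefs, 1)
        q = np.full(2, 0.5)
        mi = 0.0
        for s, o in itertools.product(range(2), range(2)):
            p_so = A[o, s] * q[s]
            p_o = sum(A[o, s2] * q[s2] for s2 in range(2))
            mi += p_so * np.log(p_so / (p_o * q[s]))
        assert epistemic == pytest.approx(-mi, abs=1e-12)

    def test_epistemic_matches_mi_oracle_on_random_likelihoods(self, rng):
        """Randomised 4x4 likelihoods against the double-sum oracle (1e-8)."""
        for _ in range(25):
            A = normalise(rng.random((4, 4)) + 0.05, axis=0)
            D = normalise(rng.random(4) + 0.05, axis=0)
            level = make_single_factor_level(A, np.eye(4), D, T=2)
            beliefs = _beliefs(level)
            gradient_update(beliefs, level, [None, None], n_iter=1)
            _, _, epistemic = expected_free_energy(level, 0, beliefs, 1)
            q = beliefs.joint_pred[0, 1]
            mi = 0.0
            for s, o in itertools.product(range(4), range(4)):
                p_so = A[o, s] * q[s]
                if p_so > 0:
                    p_o = float(A[o] @ q)
                    mi += p_so * np.log(p_so / (p_o * q[s]))
            assert epistemic == pytest.approx(-mi, abs=1e-8)

    def test_future_time_required(self):
        level, *_ = random_level(np.random.default_rng(0), n_states=2, T=2)
        beliefs = _beliefs(level)
        gradient_update(beliefs, level, [[0], None], n_iter=1)
        with pytest.raises(ValueError):
            expected_free_energy(level, 0, beliefs, 7)


# ---------------------------------------------------------------------------
# policy posterior, BMA, precision, action
# ---------------------------------------------------------------------------

class TestPolicyPosterior:
    def test_vanishing_precision_gives_uniform_posterior(self):
        q = policy_posterior([0.3, 0.3, 0.3], [1.0, 5.0, 9.0], gamma=1e-9)
        assert np.allclose(q, 1 / 3, atol=1e-6)

    def test_high_precision_concentrates_on_argmin(self):
        q = policy_posterior([0.0, 0.0], [2.0, 1.0], gamma=1e3)
        assert q[1] > 1 - 1e-12

    def test_two_policy_softmax_value(self):
        """sigma(-1, -2) = (0.7311, 0.2689)."""
        q = policy_posterior([0.0, 0.0], [1.0, 2.0], gamma=1.0)
        assert np.allclose(q, [0.7310585786300049, 0.2689414213699951], atol=1e-12)

    def test_limits_on_randomised_G(self, rng):
        for _ in range(20):
            G = rng.random(5) * 10
            F = rng.random(5)
            lo = policy_posterior(F - F.mean(), G, gamma=1e-10)
            assert np.abs(lo - softmax(-(F - F.mean()))).max() < 1e-6
            hi = policy_posterior(np.zeros(5), G, gamma=1e6)
            assert hi[np.argmin(G)] > 1 - 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior([0.0], [1.0, 2.0], gamma=1.0)


class TestBayesianModelAverage:
    def test_single_policy_returns_conditional(self):
        sb = [np.array([[[0.2, 0.8]]])]
        out = bayesian_model_average(np.array([1.0]), sb, 0)
        assert np.allclose(out[0], [0.2, 0.8])

    def test_identical_conditionals_are_invariant_to_weights(self):
        sb = [np.tile(np.array([[0.3, 0.7]]), (4, 1, 1))]
        out = bayesian_model_average(np.array([0.1, 0.2, 0.3, 0.4]), sb, 0)
        assert np.allclose(out[0], [0.3, 0.7], atol=1e-12)

    def test_weighted_mixture(self):
        sb = [np.stack([np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])])]
        out = bayesian_model_average(np.array([0.75, 0.25]), sb, 0)
        assert np.allclose(out[0], [0.75, 0.25])

    def test_cardinality_mismatch_rejected(self):
        sb = [np.zeros((3, 1, 2))]
        with pytest.raises(ValueError):
            bayesian_model_average(np.array([0.5, 0.5]), sb, 0)


class TestUpdatePrecision:
    def test_no_divergence_leaves_beta_at_prior(self):
        """Equal F: posterior equals prior, beta stays put."""
        beta, traj, conv = update_precision(1.5, [0.2, 0.2], [1.0, 3.0])
        assert beta == pytest.approx(1.5, abs=1e-9)
        assert conv

    def test_posterior_favouring_low_G_lowers_beta(self):
        """Evidence for the low-G policy shifts Q(pi) below P(pi) there,
        so beta falls (gamma rises)."""
        beta, _, _ = update_precision(1.0, [0.0, 5.0], [1.0, 2.0])
        assert beta < 1.0

    def test_posterior_favouring_high_G_raises_beta(self):
        beta, _, _ = update_precision(1.0, [5.0, 0.0], [1.0, 2.0])
        assert beta > 1.0

    def test_trajectory_matches_scalar_oracle(self):
        """Independently coded scalar fixed-point iteration."""
        F = np.array([0.0, 3.0])
        G = np.array([2.0, 1.0])
        beta0, n_iter = 2.0, 6
        b = beta0
        oracle = []
        for _ in range(n_iter):
            g = 1.0 / b
            qu = np.exp(-g * G - F) / np.exp(-g * G - F).sum()
            pu = np.exp(-g * G) / np.exp(-g * G).sum()
            err = (b - beta0) - float((qu - pu) @ G)
            b = max(b - err / 2.0, 1e-3)
            oracle.append(1.0 / b)
        _, traj, _ = update_precision(beta0, F, G, n_iter=n_iter, tol=0.0)
        assert np.allclose(traj, oracle, atol=1e-12)

    def test_beta_stays_positive(self):
        beta, traj, _ = update_precision(0.01, [0.0, 50.0], [5.0, 0.0],
                                         n_iter=50)
        assert beta > 0
        assert np.all(np.isfinite(traj))


class TestSelectAction:
    def _pols(self, *actions):
        return [Policy(actions=((a,),)) for a in actions]

    def test_unanimous_policies(self):
        assert select_action(np.array([0.5, 0.5]), self._pols(2, 2), 0) == (2,)

    def test_dominant_policy_wins(self):
        assert select_action(np.array([0.9, 0.1]), self._pols(1, 3), 0) == (1,)

    def test_exact_tie_breaks_to_lowest_action(self):
        assert select_action(np.array([0.5, 0.5]), self._pols(3, 1), 0) == (1,)

    def test_sampling_mode_is_seeded(self):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        pols = self._pols(0, 1, 2, 3)
        q = np.array([0.4, 0.3, 0.2, 0.1])
        a1 = [select_action(q, pols, 0, mode="sample", rng=rng1) for _ in range(10)]
        a2 = [select_action(q, pols, 0, mode="sample", rng=rng2) for _ in range(10)]
        assert a1 == a2


# ---------------------------------------------------------------------------
# full trials
# ---------------------------------------------------------------------------

class TestRunLevelTrial:
    def test_deterministic_single_state_model_keeps_delta_beliefs(self):
        level = make_single_factor_level(np.eye(2), np.eye(2),
                                         np.array([1.0, 0.0]), T=3)
        proc = MDPProcess(A=level.A, B=level.B, init_states=[0],
                          rng=np.random.default_rng(0))
        rec = run_level_trial(level, proc, InferenceConfig(n_iter=64,
                                                           update_precision=False))
        for t in range(3):
            assert rec.bma_step[t][0][t][0] > 1 - 1e-6

    def test_fixed_seed_reproduces_record_bit_identically(self):
        def run():
            rng = np.random.default_rng(42)
            level, *_ = random_level(np.random.default_rng(2), n_states=3, T=3)
            proc = MDPProcess(A=level.A, B=level.B, init_states=[0], rng=rng)
            return run_level_trial(level, proc, InferenceConfig(n_iter=8))

        r1, r2 = run(), run()
        assert r1.observations == r2.observations
        assert r1.actions == r2.actions
        for a, b in zip(r1.nu_log, r2.nu_log):
            for x, y in zip(a, b):
                assert np.array_equal(x, y)
        for a, b in zip(r1.q_pi_step, r2.q_pi_step):
            assert np.array_equal(a, b)

    def test_final_bma_matches_forward_filtering_oracle(self):
        """2-state hidden Markov toy: final beliefs against an independent
        forward-algorithm oracle (max abs deviation < 1e-3)."""
        rng = np.random.default_rng(8)
        A = normalise(rng.random((2, 2)) + 0.2, axis=0)
        B = normalise(rng.random((2, 2)) + 0.2, axis=0)
        D = np.array([0.6, 0.4])
        level = make_single_factor_level(A, B, D, T=4)
        proc = MDPProcess(A=level.A, B=level.B, init_states=[0],
                          rng=np.random.default_rng(21))
        rec = run_level_trial(level, proc, InferenceConfig(n_iter=64,
                                                           update_precision=False))
        obs = [o[0] for o in rec.observations]
        # independent forward filter
        f = D * A[obs[0]]
        f = f / f.sum()
        for o in obs[1:]:
            f = A[o] * (B @ f)
            f = f / f.sum()
        assert np.abs(rec.final_bma()[0][rec.steps_executed - 1] - f).max() < 1e-3

    def test_free_energy_nonincreasing_within_each_step(self):
        rng = np.random.default_rng(13)
        level, *_ = random_level(np.random.default_rng(4), n_states=4, T=3)
        proc = MDPProcess(A=level.A, B=level.B, init_states=[1], rng=rng)
        rec = run_level_trial(level, proc, InferenceConfig(n_iter=16))
        for t in range(rec.steps_executed):
            lo, hi = rec.step_window(t)
            F = np.array([rec.F_iter[i] for i in range(lo, hi)])
            assert np.all(np.diff(F, axis=0) <= 1e-6)

    def test_beliefs_stay_normalised(self):
        rng = np.random.default_rng(14)
        level, *_ = random_level(np.random.default_rng(6), n_states=3, T=3)
        proc = MDPProcess(A=level.A, B=level.B, init_states=[0], rng=rng)
        rec = run_level_trial(level, proc, InferenceConfig(n_iter=8))
        for nus in rec.nu_log:
            for nu_f in nus:
                assert np.allclose(softmax(nu_f, axis=-1).sum(axis=-1), 1.0,
                                   atol=1e-8)
        for bmas in rec.bma_step:
            for b in bmas:
                assert np.allclose(b.sum(axis=-1), 1.0, atol=1e-8)
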