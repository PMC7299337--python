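"""Learner dynamics, choice rules, and the likelihood engine."""

import numpy as np
import pytest

from replaynav import agents as ag
from replaynav import fitting, task_env as te
from replaynav.task_env import Move

FACE = 1


def mf_params(**kw):
    base = dict(eta_mf1=0.5, eta_mf2=0.5, tau_mf=1.0, tau_prime_mf=1.0,
                theta=0.0, beta1_mf1=1.0, beta2_mf1=1.0, beta2_mf2=1.0)
    base.update(kw)
    return ag.MFParams(**base)


def mb_params(**kw):
    base = dict(eta_mb=0.5, tau_mb=1.0, tau_prime_mb=1.0, rho=0.5, omega=1.0,
                beta_mb=1.0, kappa=1.0)
    base.update(kw)
    return ag.MBParams(**base)


class TestDecay:
    @pytest.mark.parametrize("tau,expected", [(1.0, 10.0), (0.0, 0.0),
                                              (0.5, 5.0)])
    def test_mf_decay_arithmetic(self, tau, expected):
        st = ag.MFState.initial(0.0)
        st.Q1[:] = 10.0
        st.Q2[:] = 10.0
        out = ag.mf_decay(st, tau, 0.0)
        assert np.allclose(out.Q1, expected) and np.allclose(out.Q2, expected)

    def test_mb_decay_limits_and_stochasticity(self):
        st = ag.MBState.initial()
        st.T[0, 0, 1] = 0.9
        st.T[0, 0, 2:] = 0.1 / 6
        uniform = ag.mb_decay(st, 0.0)
        assert np.allclose(uniform.T[0, 0, 1:], 1 / 7)
        same = ag.mb_decay(st, 1.0)
        assert np.allclose(same.T, st.T)
        half = ag.mb_decay(st, 0.5)
        assert np.allclose(half.T.sum(axis=2), 1.0)
        assert np.allclose(half.T[np.arange(8), :, np.arange(8)], 0.0)


class TestMFUpdate:
    def test_repeated_single_move_updates(self, canonical_map):
        st = ag.MFState.initial(0.0)
        R = np.zeros(8)
        R[3] = 9.0
        p = mf_params()
        st, pe = ag.mf_update(st, (0, [int(Move.RIGHT)], [3]), p, R)
        assert st.Q1[0, Move.RIGHT] == pytest.approx(4.5)
        assert pe.delta_mf1 == pytest.approx(9.0)
        st, _ = ag.mf_update(st, (0, [int(Move.RIGHT)], [3]), p, R)
        assert st.Q1[0, Move.RIGHT] == pytest.approx(6.75)

    def test_zero_rate_is_identity(self):
        st = ag.MFState.initial(2.0)
        p = mf_params(eta_mf1=0.0, eta_mf2=0.0)
        out, _ = ag.mf_update(st, (0, [0], [3]), p, np.arange(8.0))
        assert np.allclose(out.Q1, 2.0) and np.allclose(out.Q2, 2.0)

    def test_pair_update_uses_total_outcome_points(self):
        # outcome rewards 5 and 9: the pair value converges to their sum
        st = ag.MFState.initial(0.0)
        R = np.zeros(8)
        R[2], R[4] = 5.0, 9.0
        p = mf_params(eta_mf2=1.0)
        st, pe = ag.mf_update(st, (0, [int(Move.LEFT), int(Move.UP)], [2, 4]),
                              p, R)
        k = ag.ALLOWED2[Move.LEFT].index(Move.UP)
        assert st.Q2[0, Move.LEFT, k] == pytest.approx(14.0)
        assert pe.delta_mf2 == pytest.approx(14.0)

    def test_backtracking_pair_rejected(self):
        st = ag.MFState.initial(0.0)
        with pytest.raises(ValueError):
            ag.mf_update(st, (0, [int(Move.LEFT), int(Move.RIGHT)], [2, 0]),
                         mf_params(), np.zeros(8))


class TestMBUpdate:
    def test_renormalization_from_uniform(self):
        # observed entry pulled to 1 then row renormalised: 7/13 vs 1/13
        st = ag.MBState.initial()
        p = mb_params(eta_mb=1.0, rho=0.0)
        out, pe = ag.mb_update(st, (0, int(Move.LEFT), 3), p)
        assert out.T[0, Move.LEFT, 3] == pytest.approx(7 / 13)
        other = [s for s in range(8) if s not in (0, 3)]
        assert np.allclose(out.T[0, Move.LEFT, other], 1 / 13)
        assert pe.delta_mb == pytest.approx(6 / 7)

    def test_zero_rate_identity_and_row_invariants(self):
        st = ag.MBState.initial()
        out, _ = ag.mb_update(st, (0, 0, 3), mb_params(eta_mb=0.0, rho=1.0))
        assert np.allclose(out.T, st.T)
        out2, _ = ag.mb_update(st, (0, 0, 3), mb_params(eta_mb=0.7, rho=0.9))
        assert np.allclose(out2.T.sum(axis=2), 1.0)
        assert np.allclose(out2.T[np.arange(8), :, np.arange(8)], 0.0)

    def test_reverse_inference_scaled_by_rho(self):
        st = ag.MBState.initial()
        full, _ = ag.mb_update(st, (0, int(Move.LEFT), 3),
                               mb_params(eta_mb=0.5, rho=1.0))
        none, _ = ag.mb_update(st, (0, int(Move.LEFT), 3),
                               mb_params(eta_mb=0.5, rho=0.0))
        assert full.T[3, Move.RIGHT, 0] > none.T[3, Move.RIGHT, 0]
        assert np.allclose(none.T[3, Move.RIGHT], st.T[3, Move.RIGHT])


class TestRearrange:
    def test_omega_one_permutes_both_state_roles(self, canonical_map):
        st = ag.MBState.initial()
        st.T[0, 0, :] = 0.0
        st.T[0, 0, 3] = 1.0
        p = mb_params(omega=1.0, tau_prime_mb=1.0)
        out = ag.mb_rearrange(st, canonical_map.switch_pairs, p)
        # pairs (5,3) and (2,0): state 0 <-> 2, outcome 3 <-> 5
        assert out.T[2, 0, 5] == pytest.approx(1.0)

    def test_omega_zero_reduces_to_decay(self, canonical_map):
        st = ag.MBState.initial()
        st.T[0, 0, 3] = 0.9
        st.T[0, 0, np.r_[1, 2, 4:8]] = 0.1 / 6
        p = mb_params(omega=0.0, tau_prime_mb=0.5)
        out = ag.mb_rearrange(st, canonical_map.switch_pairs, p)
        ref = ag.mb_decay(st, 0.5)
        assert np.allclose(out.T, ref.T)

    def test_rows_remain_stochastic_for_any_omega(self, canonical_map, rng):
        st = ag.MBState.initial()
        row = np.zeros(8)
        row[[s for s in range(8) if s != 1]] = rng.dirichlet(np.ones(7))
        st.T[1, 2, :] = row   # valid row: zero self-transition
        for omega in (0.0, 0.3, 1.0):
            out = ag.mb_rearrange(st, canonical_map.switch_pairs,
                                  mb_params(omega=omega))
            assert np.allclose(out.T.sum(axis=2), 1.0)


class TestMBValues:
    def test_accurate_model_reproduces_oracle_value(self, canonical_map):
        # deterministic true transitions, kappa=1: two-move value of RIGHT
        # from the face equals the oracle's 15 points
        succ = te.transition_matrix(canonical_map)
        st = ag.MBState.initial()
        st.T[:] = 0.0
        for s in range(8):
            for m in range(4):
                st.T[s, m, succ[s, m]] = 1.0
        R = np.asarray(canonical_map.rewards[0], float)
        v = ag.mb_values(st, R, FACE, 2, mb_params(kappa=1.0))
        assert v[Move.RIGHT] == pytest.approx(15.0)

    def test_kappa_zero_reduces_to_one_move_values(self, rng):
        st = ag.MBState.initial()
        R = rng.uniform(0, 10, 8)
        v2 = ag.mb_values(st, R, 0, 2, mb_params(kappa=0.0))
        v1 = ag.mb_values(st, R, 0, 1, mb_params())
        assert np.allclose(v2, v1)

    def test_uniform_model_gives_mean_nonself_reward(self, rng):
        st = ag.MBState.initial()
        R = rng.uniform(0, 10, 8)
        for s in range(8):
            v = ag.mb_values(st, R, s, 1, mb_params())
            expected = (R.sum() - R[s]) / 7
            assert np.allclose(v, expected)


class TestChoiceProbs:
    def test_flat_values_give_uniform_policies(self):
        mf = ag.MFState.initial(3.0)
        p = mf_params()
        first = ag.mf_choice_probs(mf, p, (0, 1, 1, None, None))
        assert np.allclose(first, 0.25)
        second = ag.mf_choice_probs(mf, p, (0, 2, 2, int(Move.LEFT), 4))
        assert np.allclose(second, 1 / 3)

    def test_large_beta_concentrates_on_argmax(self):
        mf = ag.MFState.initial(0.0)
        mf.Q1[0, Move.UP] = 5.0
        p = mf_params(beta1_mf1=50.0)
        probs = ag.mf_choice_probs(mf, p, (0, 1, 1, None, None))
        assert probs[Move.UP] > 0.999

    def test_two_move_first_choice_matches_hand_softmax(self, rng):
        # independent oracle: direct evaluation of the marginalised values
        mf = ag.MFState(Q1=rng.uniform(0, 9, (8, 4)),
                        Q2=rng.uniform(0, 14, (8, 4, 3)))
        p = mf_params(beta2_mf1=1.0, beta2_mf2=1.0,
                      gamma=(0.1, -0.2, 0.3, -0.2))
        s1 = 2
        g = np.asarray(p.gamma)
        q1bar = mf.Q1.mean(axis=0)
        logits = np.empty(4)
        for m1 in Move:
            w = np.array([g[m] + q1bar[m] + mf.Q2[s1, m1, k]
                          for k, m in enumerate(ag.ALLOWED2[m1])])
            w = np.exp(w - w.max())
            w /= w.sum()
            logits[m1] = g[m1] + mf.Q1[s1, m1] + w @ mf.Q2[s1, m1]
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        got = ag.mf_choice_probs(mf, p, (s1, 2, 1, None, None))
        assert np.allclose(got, expected)

    def test_hybrid_reduces_to_components(self, rng):
        mf = ag.MFState(Q1=rng.uniform(0, 9, (8, 4)),
                        Q2=rng.uniform(0, 14, (8, 4, 3)))
        mb = ag.MBState.initial()
        mb.T[0, 0, 1:] = rng.dirichlet(np.ones(7))
        R = rng.uniform(0, 10, 8)
        pm = mf_params()
        pb = mb_params(beta_mb=0.0)
        hyb = ag.HybridParams(mf=pm, mb=pb)
        ctx = (0, 2, 1, None, None)
        assert np.allclose(ag.hybrid_choice_probs(mf, mb, hyb, ctx, R),
                           ag.mf_choice_probs(mf, pm, ctx))
        pm0 = mf_params(beta1_mf1=0.0, beta2_mf1=0.0, beta2_mf2=0.0)
        pb1 = mb_params(beta_mb=1.3)
        hyb2 = ag.HybridParams(mf=pm0, mb=pb1)
        assert np.allclose(ag.hybrid_choice_probs(mf, mb, hyb2, ctx, R),
                           ag.mb_choice_probs(mb, pb1, ctx, R))

    def test_all_policies_normalise_without_backtracking_mass(self, rng):
        mf = ag.MFState(Q1=rng.uniform(0, 9, (8, 4)),
                        Q2=rng.uniform(0, 14, (8, 4, 3)))
        mb = ag.MBState.initial()
        R = rng.uniform(0, 10, 8)
        hyb = ag.HybridParams(mf=mf_params(), mb=mb_params())
        for first in Move:
            ctx = (0, 2, 2, int(first), None)
            for probs in (ag.mf_choice_probs(mf, mf_params(), ctx),
                          ag.mb_choice_probs(mb, mb_params(), ctx, R),
                          ag.hybrid_choice_probs(mf, mb, hyb, ctx, R)):
                assert probs.shape == (3,)
                assert np.isclose(probs.sum(), 1.0)


class TestRunAgent:
    def test_uniform_policy_loglik_closed_form(self, schedule, canonical_map,
                                               rng):
        p = mf_params(beta1_mf1=0, beta2_mf1=0, beta2_mf2=0)
        log, ll = ag.run_agent(p, "mf", schedule, canonical_map, rng=rng)
        n1 = len(schedule.trials)
        n2 = sum(t.n_moves == 2 for t in schedule.trials)
        assert ll == pytest.approx(n1 * np.log(1 / 4) + n2 * np.log(1 / 3))
        # points recorded follow the trial's reward phase
        assert (log["points"] >= 0).all()

    def test_simulation_is_reproducible(self, schedule, canonical_map):
        p = ag.HybridParams(mf=mf_params(), mb=mb_params())
        log1, ll1 = ag.run_agent(p, "hybrid", schedule, canonical_map,
                                 rng=np.random.default_rng(5))
        log2, ll2 = ag.run_agent(p, "hybrid", schedule, canonical_map,
                                 rng=np.random.default_rng(5))
        assert ll1 == ll2 and log1.equals(log2)

    def test_loglik_mode_reproduces_simulation_loglik(self, schedule,
                                                      canonical_map, rng):
        p = ag.HybridParams(mf=mf_params(), mb=mb_params())
        log, ll = ag.run_agent(p, "hybrid", schedule, canonical_map, rng=rng)
        _, ll2 = ag.run_agent(p, "hybrid", schedule, canonical_map,
                              mode="loglik", choices=log)
        assert ll2 == pytest.approx(ll)

    def test_generating_parameters_beat_perturbed_ones(self, schedule,
                                                       canonical_map):
        gen = dict(eta_mf1=.4, eta_mf2=.4, tau_mf=.9, tau_prime_mf=.5,
                   theta=3., beta1_mf1=1., beta2_mf1=1., beta2_mf2=.5,
                   gamma_left=0., gamma_right=0., gamma_up=0., gamma_down=0.)
        perturbed = dict(gen, eta_mf1=.05, beta1_mf1=4., beta2_mf1=.05,
                         theta=-2.)
        diffs = []
        for seed in range(5):
            log, _ = ag.run_agent(gen, "mf", schedule, canonical_map,
                                  rng=np.random.default_rng(seed))
            _, ll_gen = ag.run_agent(gen, "mf", schedule, canonical_map,
                                     mode="loglik", choices=log)
            _, ll_bad = ag.run_agent(perturbed, "mf", schedule, canonical_map,
                                     mode="loglik", choices=log)
            diffs.append(ll_gen - ll_bad)
        assert np.mean(diffs) > 0


class TestBatchEngine:
    @pytest.mark.parametrize("model", ["mf", "mb", "hybrid"])
    def test_backends_agree_with_single_run(self, model, schedule,
                                            canonical_map):
        rng = np.random.default_rng(3)
        prior = fitting.default_group_prior(model)
        P = fitting.sample_prior(prior, 16, rng)
        gen = fitting.sample_generating_params(model, 1, rng)[0]
        log, _ = ag.run_agent(gen, model, schedule, canonical_map,
                              rng=np.random.default_rng(0))
        ll_numba = ag.batch_loglik(model, P, log, canonical_map, schedule)
        ll_numpy = ag.batch_loglik(model, P, log, canonical_map, schedule,
                                   backend="numpy")
        assert np.allclose(ll_numba, ll_numpy, rtol=1e-10, atol=1e-8)
        single = {k: np.array([v[4]]) for k, v in P.items()}
        _, ll_one = ag.run_agent({k: float(v[0]) for k, v in single.items()},
                                 model, schedule, canonical_map,
                                 mode="loglik", choices=log)
        assert ll_numba[4] == pytest.approx(ll_one)
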