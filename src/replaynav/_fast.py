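"""Numba kernel for the batched choice-likelihood inner loop.

Transliterates the trial loop of :mod:`.agents` into per-setting scalar code
(small fixed-size arrays, cache-friendly), looping over parameter settings.
The numpy engine in :mod:`.agents` is the reference implementation; the two
are held equal (to float tolerance) by a dedicated test.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter column order in the kernel's matrix
KERNEL_PARAMS = ("eta_mf1", "eta_mf2", "tau_mf", "tau_prime_mf", "theta",
                 "beta1_mf1", "beta2_mf1", "beta2_mf2",
                 "eta_mb", "tau_mb", "tau_prime_mb", "rho", "omega",
                 "beta_mb", "kappa",
                 "gamma_left", "gamma_right", "gamma_up", "gamma_down")

(I_ETA1, I_ETA2, I_TAU, I_TAUP, I_THETA, I_B1, I_B21, I_B22,
 I_ETAMB, I_TAUMB, I_TAUPMB, I_RHO, I_OMEGA, I_BMB, I_KAPPA,
 I_GL, I_GR, I_GU, I_GD) = range(19)


@njit(cache=True)
def _softmax_inplace(logits):
    mx = logits.max()
    s = 0.0
    for i in range(logits.shape[0]):
        logits[i] = np.exp(logits[i] - mx)
        s += logits[i]
    for i in range(logits.shape[0]):
        logits[i] /= s


@njit(cache=True)
def _v16_full(T, R, out):
    for s in range(8):
        for m in range(4):
            acc = 0.0
            for sp in range(8):
                acc += T[s, m, sp] * R[sp]
            out[s, m] = acc


@njit(cache=True)
def _update_T(T, s1, m, s2, eta):
    T[s1, m, s2] += eta * (1.0 - T[s1, m, s2])
    tot = 0.0
    for sp in range(8):
        tot += T[s1, m, sp]
    for sp in range(8):
        T[s1, m, sp] /= tot


@njit(cache=True)
def loglik_kernel(params, has_mf, has_mb, is_pure_mb,
                  n_moves, start, feedback, phase, switched, event,
                  m1_arr, m2_arr, succ_pre, succ_post, R_all,
                  allowed2, opp, perm, min_prob):
    """Per-setting replay of the schedule; returns (S,) log-likelihoods."""
    S = params.shape[0]
    T_trials = n_moves.shape[0]
    out = np.zeros(S)
    for si in range(S):
        p = params[si]
        gamma = np.empty(4)
        gamma[0], gamma[1], gamma[2], gamma[3] = p[I_GL], p[I_GR], p[I_GU], p[I_GD]
        gm = (gamma[0] + gamma[1] + gamma[2] + gamma[3]) / 4.0
        for i in range(4):
            gamma[i] -= gm
        Q1 = np.full((8, 4), p[I_THETA])
        Q2 = np.full((8, 4, 3), p[I_THETA])
        T = np.full((8, 4, 8), 1.0 / 7.0)
        for s in range(8):
            for m in range(4):
                T[s, m, s] = 0.0
        V16 = np.empty((8, 4))
        ll = 0.0
        for t in range(T_trials):
            # instructed-change events before this trial
            if event[t] > 0:
                if has_mb and event[t] == 2:   # position switch: rearrange
                    om = p[I_OMEGA]
                    T_new = np.empty((8, 4, 8))
                    for s in range(8):
                        for m in range(4):
                            for sp in range(8):
                                T_new[s, m, sp] = ((1.0 - om) * T[s, m, sp]
                                                   + om * T[perm[s], m, perm[sp]])
                    T = T_new
                if has_mf:
                    tp, th = p[I_TAUP], p[I_THETA]
                    for s in range(8):
                        for m in range(4):
                            Q1[s, m] = tp * Q1[s, m] + (1 - tp) * th
                            for k in range(3):
                                Q2[s, m, k] = tp * Q2[s, m, k] + (1 - tp) * th
                if has_mb:
                    tp = p[I_TAUPMB]
                    for s in range(8):
                        for m in range(4):
                            for sp in range(8):
                                if sp != s:
                                    T[s, m, sp] = (tp * T[s, m, sp]
                                                   + (1 - tp) / 7.0)
            # per-trial decay
            if has_mf:
                tau, th = p[I_TAU], p[I_THETA]
                for s in range(8):
                    for m in range(4):
                        Q1[s, m] = tau * Q1[s, m] + (1 - tau) * th
                        for k in range(3):
                            Q2[s, m, k] = tau * Q2[s, m, k] + (1 - tau) * th
            if has_mb:
                tau = p[I_TAUMB]
                for s in range(8):
                    for m in range(4):
                        for sp in range(8):
                            if sp != s:
                                T[s, m, sp] = tau * T[s, m, sp] + (1 - tau) / 7.0
            R = R_all[phase[t] - 1]
            succ = succ_post if switched[t] else succ_pre
            s1 = start[t]
            m1 = m1_arr[t]
            nm = n_moves[t]
            if has_mb:
                _v16_full(T, R, V16)
            # ---- first move ----
            logits = np.empty(4)
            for m in range(4):
                logits[m] = gamma[m]
            if has_mf:
                if nm == 1:
                    for m in range(4):
                        logits[m] += p[I_B1] * Q1[s1, m]
                else:
                    # Q1 averaged over states (intermediate state unknown)
                    q1bar = np.zeros(4)
                    for m in range(4):
                        for s in range(8):
                            q1bar[m] += Q1[s, m]
                        q1bar[m] /= 8.0
                    for m in range(4):
                        logits[m] += p[I_B21] * Q1[s1, m]
                        # move-pair values integrated over second move
                        w = np.empty(3)
                        for k in range(3):
                            mk = allowed2[m, k]
                            w[k] = (gamma[mk] + p[I_B21] * q1bar[mk]
                                    + p[I_B22] * Q2[s1, m, k])
                        _softmax_inplace(w)
                        acc = 0.0
                        for k in range(3):
                            acc += w[k] * Q2[s1, m, k]
                        logits[m] += p[I_B22] * acc
            if has_mb:
                if nm == 1:
                    for m in range(4):
                        logits[m] += p[I_BMB] * V16[s1, m]
                else:
                    inner = np.empty(8)
                    for s in range(8):
                        mx = V16[s, 0]
                        for m in range(1, 4):
                            if V16[s, m] > mx:
                                mx = V16[s, m]
                        inner[s] = R[s] + p[I_KAPPA] * mx
                    for m in range(4):
                        acc = 0.0
                        for sp in range(8):
                            acc += T[s1, m, sp] * inner[sp]
                        logits[m] += p[I_BMB] * acc
            _softmax_inplace(logits)
            pr = logits[m1]
            if pr < min_prob:
                pr = min_prob
            ll += np.log(pr)
            s2 = succ[s1, m1]
            # ---- second move ----
            if nm == 2:
                m2 = m2_arr[t]
                k2 = 0
                for k in range(3):
                    if allowed2[m1, k] == m2:
                        k2 = k
                seen = feedback[t]
                if is_pure_mb and not seen:
                    # integrate the policy over the expected intermediate state
                    probs = np.zeros(3)
                    for s in range(8):
                        wgt = T[s1, m1, s]
                        if wgt == 0.0:
                            continue
                        lg = np.empty(3)
                        for k in range(3):
                            mk = allowed2[m1, k]
                            lg[k] = gamma[mk] + p[I_BMB] * V16[s, mk]
                        _softmax_inplace(lg)
                        for k in range(3):
                            probs[k] += wgt * lg[k]
                    tot = probs[0] + probs[1] + probs[2]
                    for k in range(3):
                        probs[k] /= tot
                    pr2 = probs[k2]
                else:
                    lg = np.empty(3)
                    for k in range(3):
                        mk = allowed2[m1, k]
                        lg[k] = gamma[mk]
                        if has_mf:
                            if seen:
                                lg[k] += p[I_B21] * Q1[s2, mk]
                            else:
                                acc = 0.0
                                for s in range(8):
                                    acc += Q1[s, mk]
                                lg[k] += p[I_B21] * acc / 8.0
                            lg[k] += p[I_B22] * Q2[s1, m1, k]
                        if has_mb:
                            if seen:
                                lg[k] += p[I_BMB] * V16[s2, mk]
                            else:
                                acc = 0.0
                                for s in range(8):
                                    acc += T[s1, m1, s] * V16[s, mk]
                                lg[k] += p[I_BMB] * acc
                    _softmax_inplace(lg)
                    pr2 = lg[k2]
                if pr2 < min_prob:
                    pr2 = min_prob
                ll += np.log(pr2)
            # ---- learning (feedback trials only) ----
            if feedback[t]:
                s3 = succ[s2, m2_arr[t]] if nm == 2 else 0
                if has_mf:
                    e1 = p[I_ETA1]
                    Q1[s1, m1] += e1 * (R[s2] - Q1[s1, m1])
                    if nm == 2:
                        m2 = m2_arr[t]
                        Q1[s2, m2] += e1 * (R[s3] - Q1[s2, m2])
                        k2 = 0
                        for k in range(3):
                            if allowed2[m1, k] == m2:
                                k2 = k
                        Q2[s1, m1, k2] += p[I_ETA2] * (R[s2] + R[s3]
                                                       - Q2[s1, m1, k2])
                if has_mb:
                    eta, rho = p[I_ETAMB], p[I_RHO]
                    _update_T(T, s1, m1, s2, eta)
                    _update_T(T, s2, opp[m1], s1, rho * eta)
                    if nm == 2:
                        m2 = m2_arr[t]
                        _update_T(T, s2, m2, s3, eta)
                        _update_T(T, s3, opp[m2], s2, rho * eta)
        out[si] = ll
    return out
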