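"""Model-free, model-based and hybrid reinforcement-learning agents.

Three learners generate (or assign likelihood to) choices on the torus task:

* **MF** — caches action values.  ``Q1`` holds the expected points of each
  single move from each state, updated by reward prediction errors with rate
  ``eta_mf1``; a second table ``Q2`` holds the expected *total* points of each
  non-backtracking move pair, updated with its own rate ``eta_mf2``.  All
  values decay toward their initial value ``theta`` at retention ``tau_mf``
  before every trial (one extra decay with ``tau_prime_mf`` at instructed
  changes).  Choices are softmax in the Q values with per-trial-type inverse
  temperatures and a fixed per-move bias ``gamma``.
* **MB** — learns a transition model ``T[s, m, s']`` from state prediction
  errors (``1 - T`` for the observed transition), renormalising each row after
  every update; the opposite transition is updated too, scaled by ``rho``.
  ``T`` decays toward uniform (retention ``tau_mb``), and instructed position
  switches rearrange it with success ``omega``.  Action values are computed
  prospectively from ``T`` and the known image rewards, with the second-step
  term weighted by ``kappa`` on 2-move trials.
* **hybrid** — a single softmax combining the MF and MB value terms, with one
  shared bias vector.

On no-feedback trials the agents never observe outcomes: no learning occurs,
and the value terms that would require the unobserved intermediate state are
averaged over states (MF) or marginalised over ``T`` (MB).

The internal engine carries a leading "settings" axis so that the likelihood
of one subject's choices can be evaluated for thousands of parameter settings
in a single pass (the hierarchical fitting's inner loop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .task_env import (MOVES, Move, N_STATES, StateSpaceMap, ExperimentSchedule,
                   TrialSpec, allowed_second_moves, transition_matrix,
                   LOG_COLUMNS, REVALUATION_BEFORE_BLOCK, SWITCH_BEFORE_BLOCK)

N_UNIFORM = 1.0 / 7.0  # initial non-self transition probability

# second-move index tables: ALLOWED2[m1] lists the 3 permitted second moves
ALLOWED2 = tuple(allowed_second_moves(m) for m in MOVES)

#: free parameters per model, in canonical order (gamma split into 4 biases)
GAMMA_NAMES = ("gamma_left", "gamma_right", "gamma_up", "gamma_down")
MF_PARAM_NAMES = ("eta_mf1", "eta_mf2", "tau_mf", "tau_prime_mf", "theta",
                  "beta1_mf1", "beta2_mf1", "beta2_mf2") + GAMMA_NAMES
MB_PARAM_NAMES = ("eta_mb", "tau_mb", "tau_prime_mb", "rho", "omega",
                  "beta_mb", "kappa") + GAMMA_NAMES
HYBRID_PARAM_NAMES = MF_PARAM_NAMES[:8] + MB_PARAM_NAMES[:7] + GAMMA_NAMES

MODEL_PARAM_NAMES = {"mf": MF_PARAM_NAMES, "mb": MB_PARAM_NAMES,
                     "hybrid": HYBRID_PARAM_NAMES}

#: parameters with Beta group priors (unit interval)
FRACTIONAL_PARAMS = ("eta_mf1", "eta_mf2", "tau_mf", "tau_prime_mf",
                     "eta_mb", "tau_mb", "tau_prime_mb", "rho", "omega", "kappa")
#: parameters with Gamma group priors (non-negative)
POSITIVE_PARAMS = ("beta1_mf1", "beta2_mf1", "beta2_mf2", "beta_mb")
#: parameters with Normal group priors (real line)
REAL_PARAMS = ("theta",) + GAMMA_NAMES


def _check_unit(name, v):
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _check_nonneg(name, v):
    if v < 0:
        raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class MFParams:
    eta_mf1: float
    eta_mf2: float
    tau_mf: float
    tau_prime_mf: float
    theta: float
    beta1_mf1: float
    beta2_mf1: float
    beta2_mf2: float
    gamma: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        for n in ("eta_mf1", "eta_mf2", "tau_mf", "tau_prime_mf"):
            _check_unit(n, getattr(self, n))
        for n in ("beta1_mf1", "beta2_mf1", "beta2_mf2"):
            _check_nonneg(n, getattr(self, n))
        g = np.asarray(self.gamma, float)
        object.__setattr__(self, "gamma", tuple(g - g.mean()))  # sum-zero convention

    def to_dict(self) -> dict[str, float]:
        d = {n: getattr(self, n) for n in MF_PARAM_NAMES[:8]}
        d.update(dict(zip(GAMMA_NAMES, self.gamma)))
        return d


@dataclass(frozen=True)
class MBParams:
    eta_mb: float
    tau_mb: float
    tau_prime_mb: float
    rho: float
    omega: float
    beta_mb: float
    kappa: float
    gamma: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        for n in ("eta_mb", "tau_mb", "tau_prime_mb", "rho", "omega", "kappa"):
            _check_unit(n, getattr(self, n))
        _check_nonneg("beta_mb", self.beta_mb)
        g = np.asarray(self.gamma, float)
        object.__setattr__(self, "gamma", tuple(g - g.mean()))

    def to_dict(self) -> dict[str, float]:
        d = {n: getattr(self, n) for n in MB_PARAM_NAMES[:7]}
        d.update(dict(zip(GAMMA_NAMES, self.gamma)))
        return d


@dataclass(frozen=True)
class HybridParams:
    """Union of the MF and MB parameter sets with a single shared bias."""
    mf: MFParams
    mb: MBParams

    def to_dict(self) -> dict[str, float]:
        d = self.mf.to_dict()
        d.update(self.mb.to_dict())  # shared gamma: MB's copy wins, both centred
        return d


def params_from_dict(model: str, d: Mapping[str, float]):
    gamma = tuple(d.get(n, 0.0) for n in GAMMA_NAMES)
    if model == "mf":
        return MFParams(**{n: d[n] for n in MF_PARAM_NAMES[:8]}, gamma=gamma)
    if model == "mb":
        return MBParams(**{n: d[n] for n in MB_PARAM_NAMES[:7]}, gamma=gamma)
    if model == "hybrid":
        return HybridParams(
            mf=MFParams(**{n: d[n] for n in MF_PARAM_NAMES[:8]}, gamma=gamma),
            mb=MBParams(**{n: d[n] for n in MB_PARAM_NAMES[:7]}, gamma=gamma))
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Single-setting states and the elementary operations
# ---------------------------------------------------------------------------

@dataclass
class MFState:
    """Cached values: Q1 (8 states x 4 moves), Q2 (8 x 4 first x 3 second)."""
    Q1: np.ndarray
    Q2: np.ndarray

    @classmethod
    def initial(cls, theta: float) -> "MFState":
        return cls(Q1=np.full((N_STATES, 4), float(theta)),
                   Q2=np.full((N_STATES, 4, 3), float(theta)))


@dataclass
class MBState:
    """Transition model T (8 start states x 4 moves x 8 outcomes).

    Self-transitions are impossible: their entries are 0 and every
    (state, move) row over outcomes sums to 1.
    """
    T: np.ndarray

    @classmethod
    def initial(cls) -> "MBState":
        T = np.full((N_STATES, 4, N_STATES), N_UNIFORM)
        for s in range(N_STATES):
            T[s, :, s] = 0.0
        return cls(T=T)


@dataclass(frozen=True)
class PredictionErrors:
    delta_mf1: float | None = None
    delta_mf2: float | None = None
    delta_mb: float | None = None
    delta_mb_prime: float | None = None


_SELF_MASK = np.eye(N_STATES, dtype=bool)[:, None, :]  # (8,1,8) self entries


def mf_decay(state: MFState, tau: float, theta: float) -> MFState:
    """Q <- tau*Q + (1-tau)*theta, for both value tables."""
    _check_unit("tau", tau)
    return MFState(Q1=tau * state.Q1 + (1 - tau) * theta,
                   Q2=tau * state.Q2 + (1 - tau) * theta)


def mb_decay(state: MBState, tau: float) -> MBState:
    """Non-self entries decay toward uniform 1/7; self entries stay 0."""
    _check_unit("tau", tau)
    T = tau * state.T + (1 - tau) * N_UNIFORM
    T[np.broadcast_to(_SELF_MASK, T.shape)] = 0.0
    return MBState(T=T)


def mf_update(state: MFState, trial, params: MFParams, rewards: np.ndarray
              ) -> tuple[MFState, PredictionErrors]:
    """Value update for one (observed) trial.

    ``trial`` is ``(start, moves, outcomes)`` with one or two moves and the
    matching outcome states; ``rewards`` is the 8-vector of the current
    mapping.  Decay is *not* applied here (the trial loop applies it first).
    """
    start, moves, outcomes = trial
    Q1, Q2 = state.Q1.copy(), state.Q2.copy()
    if len(moves) == 2 and moves[1] == Move(moves[0]).opposite:
        raise ValueError("second move may not backtrack the first")
    d1 = rewards[outcomes[0]] - Q1[start, moves[0]]
    Q1[start, moves[0]] += params.eta_mf1 * d1
    d2 = None
    if len(moves) == 2:
        dd = rewards[outcomes[1]] - Q1[outcomes[0], moves[1]]
        Q1[outcomes[0], moves[1]] += params.eta_mf1 * dd
        k = ALLOWED2[moves[0]].index(moves[1])
        total = rewards[outcomes[0]] + rewards[outcomes[1]]
        d2 = total - Q2[start, moves[0], k]
        Q2[start, moves[0], k] += params.eta_mf2 * d2
    return MFState(Q1, Q2), PredictionErrors(delta_mf1=float(d1),
                                             delta_mf2=None if d2 is None else float(d2))


def mb_update(state: MBState, observed, params: MBParams
              ) -> tuple[MBState, PredictionErrors]:
    """Forward (and ``rho``-scaled reverse) transition update with
    renormalisation; returns the pre-update prediction errors."""
    s1, m, s2 = observed
    T = state.T.copy()
    d = 1.0 - T[s1, m, s2]
    T[s1, m, s2] += params.eta_mb * d
    T[s1, m] /= T[s1, m].sum()
    mo = Move(m).opposite
    dp = 1.0 - T[s2, mo, s1]
    T[s2, mo, s1] += params.rho * params.eta_mb * dp
    T[s2, mo] /= T[s2, mo].sum()
    return MBState(T), PredictionErrors(delta_mb=float(d), delta_mb_prime=float(dp))


def mb_rearrange(state: MBState, switch_pairs, params: MBParams) -> MBState:
    """T <- (1-omega)*T + omega*T_rearranged, permuting the switched images
    in both state roles, followed by a single tau_prime_mb decay."""
    perm = np.arange(N_STATES)
    for a, b in switch_pairs:
        perm[a], perm[b] = perm[b], perm[a]
    T_re = state.T[perm][:, :, perm]
    T = (1 - params.omega) * state.T + params.omega * T_re
    return mb_decay(MBState(T), params.tau_prime_mb)


def mb_values(state: MBState, rewards: np.ndarray, start: int, n_moves: int,
              params: MBParams) -> np.ndarray:
    """Prospective value of each of the 4 first moves from ``start``.

    One-move value is the reward expectation under ``T``; the two-move value
    adds ``kappa`` times the best second-step expectation at each candidate
    intermediate state.
    """
    V16 = state.T @ rewards          # (8,4): one-move values at every state
    if n_moves == 1:
        return V16[start].copy()
    inner = rewards + params.kappa * V16.max(axis=1)   # (8,)
    return state.T[start] @ inner


def _softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def mf_choice_probs(state: MFState, params: MFParams, context) -> np.ndarray:
    """Choice probabilities of the pure MF policy.

    ``context`` is ``(start, n_moves, move_index, first_move, s2)`` where
    ``s2`` is the observed intermediate state or ``None`` when it was not
    shown.  Returns probabilities over the 4 moves (first move) or over the
    3 non-backtracking second moves, in the order of ``ALLOWED2[first]``.
    """
    start, n_moves, move_index, first, s2 = context
    g = np.asarray(params.gamma)
    if move_index == 1:
        if n_moves == 1:
            return _softmax(g + params.beta1_mf1 * state.Q1[start])
        q2bar = _mf_q2_marginal(state, params, start)
        return _softmax(g + params.beta2_mf1 * state.Q1[start]
                        + params.beta2_mf2 * q2bar)
    allowed = ALLOWED2[first]
    q1 = state.Q1[s2] if s2 is not None else state.Q1.mean(axis=0)
    logits = np.array([g[m] + params.beta2_mf1 * q1[m]
                       + params.beta2_mf2 * state.Q2[start, first, k]
                       for k, m in enumerate(allowed)])
    return _softmax(logits)


def _mf_q2_marginal(state: MFState, params: MFParams, start: int) -> np.ndarray:
    """Move-pair values integrated over the second move, weighted by the
    anticipated second-move policy (intermediate state unknown, so Q1 is
    averaged over all states)."""
    g = np.asarray(params.gamma)
    q1bar = state.Q1.mean(axis=0)
    out = np.empty(4)
    for m1 in MOVES:
        allowed = ALLOWED2[m1]
        logits = np.array([g[m] + params.beta2_mf1 * q1bar[m]
                           + params.beta2_mf2 * state.Q2[start, m1, k]
                           for k, m in enumerate(allowed)])
        w = _softmax(logits)
        out[m1] = w @ state.Q2[start, m1]
    return out


def hybrid_choice_probs(mf: MFState, mb: MBState, params: HybridParams,
                        context, rewards: np.ndarray) -> np.ndarray:
    """Choice probabilities of the hybrid policy (shared bias, MF + MB terms)."""
    start, n_moves, move_index, first, s2 = context
    pm, pb = params.mf, params.mb
    g = np.asarray(pb.gamma)
    if move_index == 1:
        if n_moves == 1:
            return _softmax(g + pm.beta1_mf1 * mf.Q1[start]
                            + pb.beta_mb * mb_values(mb, rewards, start, 1, pb))
        q2bar = _mf_q2_marginal(mf, pm, start)
        return _softmax(g + pm.beta2_mf1 * mf.Q1[start] + pm.beta2_mf2 * q2bar
                        + pb.beta_mb * mb_values(mb, rewards, start, 2, pb))
    allowed = ALLOWED2[first]
    V16 = mb.T @ rewards
    if s2 is not None:
        q1, qmb = mf.Q1[s2], V16[s2]
    else:  # MF averaged over images, MB marginalised over T
        q1 = mf.Q1.mean(axis=0)
        qmb = mb.T[start, first] @ V16
    logits = np.array([g[m] + pm.beta2_mf1 * q1[m]
                       + pm.beta2_mf2 * mf.Q2[start, first, k]
                       + pb.beta_mb * qmb[m]
                       for k, m in enumerate(allowed)])
    return _softmax(logits)


def mb_choice_probs(state: MBState, params: MBParams, context,
                    rewards: np.ndarray) -> np.ndarray:
    """Choice probabilities of the pure MB policy."""
    start, n_moves, move_index, first, s2 = context
    g = np.asarray(params.gamma)
    if move_index == 1:
        return _softmax(g + params.beta_mb
                        * mb_values(state, rewards, start, n_moves, params))
    allowed = ALLOWED2[first]
    V16 = state.T @ rewards
    if s2 is not None:
        logits = np.array([g[m] + params.beta_mb * V16[s2, m] for m in allowed])
        return _softmax(logits)
    # intermediate state unseen: integrate the policy over expected states
    probs = np.zeros(3)
    for s in range(N_STATES):
        w = state.T[start, first, s]
        if w == 0:
            continue
        logits = np.array([g[m] + params.beta_mb * V16[s, m] for m in allowed])
        probs += w * _softmax(logits)
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# Batched trial-loop engine
# ---------------------------------------------------------------------------

def _as_batch(params: Mapping[str, float | np.ndarray], model: str
              ) -> dict[str, np.ndarray]:
    names = MODEL_PARAM_NAMES[model]
    out = {}
    size = None
    for n in names:
        a = np.atleast_1d(np.asarray(params[n], dtype=float))
        size = len(a) if size is None else size
        if len(a) != size:
            raise ValueError("parameter arrays must share a common length")
        out[n] = a
    return out


class _Engine:
    """Sequential pass over the schedule for a batch of parameter settings.

    In ``loglik`` mode the realised moves are shared by all settings; in
    ``simulate`` mode the batch must have size 1 and moves are sampled.
    """

    def __init__(self, model: str, P: dict[str, np.ndarray],
                 smap: StateSpaceMap, schedule: ExperimentSchedule,
                 min_prob: float = 1e-12):
        self.model, self.P, self.min_prob = model, P, min_prob
        self.S = len(P[MODEL_PARAM_NAMES[model][0]])
        self.has_mf = model in ("mf", "hybrid")
        self.has_mb = model in ("mb", "hybrid")
        self.gamma = np.stack([P[n] for n in GAMMA_NAMES], axis=1)
        self.gamma = self.gamma - self.gamma.mean(axis=1, keepdims=True)
        self.smap, self.schedule = smap, schedule
        self.succ = {False: transition_matrix(smap),
                     True: transition_matrix(smap.apply_switch())}
        self.R = np.asarray(smap.rewards, dtype=float)
        if self.has_mf:
            th = P["theta"][:, None, None]
            self.Q1 = np.broadcast_to(th, (self.S, N_STATES, 4)).copy()
            self.Q2 = np.broadcast_to(th[..., None],
                                      (self.S, N_STATES, 4, 3)).copy()
        if self.has_mb:
            base = np.full((N_STATES, 4, N_STATES), N_UNIFORM)
            for s in range(N_STATES):
                base[s, :, s] = 0.0
            self.T = np.broadcast_to(base, (self.S,) + base.shape).copy()
            self._T_base = base  # decay target; zero on self-transitions
        self._v16_cache: np.ndarray | None = None

    # -- state dynamics ---------------------------------------------------
    def _decay(self, tau_name: str):
        self._v16_cache = None
        if self.has_mf:
            tau = self.P["tau_mf" if tau_name == "tau" else "tau_prime_mf"]
            t, th = tau[:, None, None], self.P["theta"][:, None, None]
            self.Q1 *= t
            self.Q1 += (1 - t) * th
            self.Q2 *= t[..., None]
            self.Q2 += ((1 - t) * th)[..., None]
        if self.has_mb:
            tau = self.P["tau_mb" if tau_name == "tau" else "tau_prime_mb"]
            t = tau[:, None, None, None]
            # self-transition entries stay 0: both T and the target are 0 there
            self.T *= t
            self.T += (1 - t) * self._T_base

    def _rearrange(self):
        self._v16_cache = None
        perm = np.arange(N_STATES)
        for a, b in self.smap.switch_pairs:
            perm[a], perm[b] = perm[b], perm[a]
        T_re = self.T[:, perm][:, :, :, perm]
        om = self.P["omega"][:, None, None, None]
        self.T = (1 - om) * self.T + om * T_re

    def _update_T(self, s1: int, m: int, s2: int, eta: np.ndarray):
        self._v16_cache = None
        row = self.T[:, s1, m]
        row[:, s2] += eta * (1.0 - row[:, s2])
        row /= row.sum(axis=1, keepdims=True)

    # -- value terms ------------------------------------------------------
    def _v16(self, R: np.ndarray) -> np.ndarray:
        # valid within a trial between decay and the post-choice updates
        if self._v16_cache is None:
            self._v16_cache = self.T @ R
        return self._v16_cache

    def _mb_first(self, s1: int, n_moves: int, R: np.ndarray) -> np.ndarray:
        V16 = self._v16(R)
        if n_moves == 1:
            return V16[:, s1]
        inner = R[None, :] + self.P["kappa"][:, None] * V16.max(axis=2)
        return np.einsum('smk,sk->sm', self.T[:, s1], inner)

    def _mf_q2_marginal(self, s1: int) -> np.ndarray:
        """(S,4): Q2 integrated over the anticipated second move."""
        q1bar = self.Q1.mean(axis=1)  # (S,4)
        b1 = self.P["beta2_mf1"][:, None]
        b2 = self.P["beta2_mf2"][:, None]
        out = np.empty((self.S, 4))
        for m1 in MOVES:
            allowed = ALLOWED2[m1]
            idx = [int(m) for m in allowed]
            logits = (self.gamma[:, idx] + b1 * q1bar[:, idx]
                      + b2 * self.Q2[:, s1, m1, :])
            w = _softmax(logits, axis=1)
            out[:, m1] = (w * self.Q2[:, s1, m1, :]).sum(axis=1)
        return out

    # -- choice probabilities --------------------------------------------
    def first_move_probs(self, s1: int, n_moves: int, R: np.ndarray
                         ) -> np.ndarray:
        logits = self.gamma.copy()
        if self.has_mf:
            if n_moves == 1:
                logits = logits + self.P["beta1_mf1"][:, None] * self.Q1[:, s1]
            else:
                logits = logits + self.P["beta2_mf1"][:, None] * self.Q1[:, s1]
                logits = logits + self.P["beta2_mf2"][:, None] \
                    * self._mf_q2_marginal(s1)
        if self.has_mb:
            logits = logits + self.P["beta_mb"][:, None] \
                * self._mb_first(s1, n_moves, R)
        return _softmax(logits, axis=1)

    def second_move_probs(self, s1: int, m1: int, s2: int | None,
                          R: np.ndarray) -> np.ndarray:
        allowed = ALLOWED2[Move(m1)]
        idx = [int(m) for m in allowed]
        if self.model == "mb" and s2 is None:
            # integrate the policy over the expected intermediate state
            V16 = self._v16(R)
            logits = (self.gamma[:, None, idx]
                      + self.P["beta_mb"][:, None, None] * V16[:, :, idx])
            pol = _softmax(logits, axis=2)               # (S,8,3)
            w = self.T[:, s1, m1, :]                     # (S,8)
            probs = np.einsum('sk,skm->sm', w, pol)
            return probs / probs.sum(axis=1, keepdims=True)
        logits = self.gamma[:, idx].copy()
        if self.has_mf:
            q1 = self.Q1[:, s2, :] if s2 is not None else self.Q1.mean(axis=1)
            logits += self.P["beta2_mf1"][:, None] * q1[:, idx]
            logits += self.P["beta2_mf2"][:, None] * self.Q2[:, s1, m1, :]
        if self.has_mb:
            V16 = self._v16(R)
            if s2 is not None:
                qmb = V16[:, s2, :]
            else:
                qmb = np.einsum('sk,skm->sm', self.T[:, s1, m1, :], V16)
            logits += self.P["beta_mb"][:, None] * qmb[:, idx]
        return _softmax(logits, axis=1)

    # -- learning ---------------------------------------------------------
    def observe(self, spec: TrialSpec, moves, outcomes, R: np.ndarray
                ) -> dict[str, float]:
        """Apply the trial's updates (feedback trials only) and return the
        scalar prediction errors of the first setting (for logging)."""
        pes: dict[str, float] = {}
        s1 = spec.start
        if self.has_mf:
            e1 = self.P["eta_mf1"]
            d1 = R[outcomes[0]] - self.Q1[:, s1, moves[0]]
            pes["rpe"] = float(d1[0])
            self.Q1[:, s1, moves[0]] += e1 * d1
            if len(moves) == 2:
                dd = R[outcomes[1]] - self.Q1[:, outcomes[0], moves[1]]
                self.Q1[:, outcomes[0], moves[1]] += e1 * dd
                k = ALLOWED2[Move(moves[0])].index(Move(moves[1]))
                tot = R[outcomes[0]] + R[outcomes[1]]
                d2 = tot - self.Q2[:, s1, moves[0], k]
                self.Q2[:, s1, moves[0], k] += self.P["eta_mf2"] * d2
                pes["rpe2"] = float(d2[0])
        if self.has_mb:
            eta = self.P["eta_mb"]
            pes["spe"] = float(1.0 - self.T[0, s1, moves[0], outcomes[0]])
            self._update_T(s1, moves[0], outcomes[0], eta)
            self._update_T(outcomes[0], int(Move(moves[0]).opposite), s1,
                           self.P["rho"] * eta)
            if len(moves) == 2:
                pes["spe2"] = float(
                    1.0 - self.T[0, outcomes[0], moves[1], outcomes[1]])
                self._update_T(outcomes[0], moves[1], outcomes[1], eta)
                self._update_T(outcomes[1], int(Move(moves[1]).opposite),
                               outcomes[0], self.P["rho"] * eta)
        return pes


def run_agent(params, model: str, schedule: ExperimentSchedule,
              smap: StateSpaceMap, rng=None, mode: str = "simulate",
              choices: pd.DataFrame | None = None, min_prob: float = 1e-12
              ) -> tuple[pd.DataFrame, float]:
    """Run one agent over the schedule.

    In ``simulate`` mode, moves are sampled from the agent's policy (``rng``
    required); in ``loglik`` mode the moves are read from ``choices`` (an
    episode log) and only their probabilities are accumulated.  Returns the
    episode log (with per-move choice probabilities and prediction errors)
    and the total log-likelihood of the realised moves.
    """
    if isinstance(params, (MFParams, MBParams, HybridParams)):
        params = params.to_dict()
    P = _as_batch(params, model)
    if P[MODEL_PARAM_NAMES[model][0]].shape != (1,):
        raise ValueError("run_agent takes a single parameter setting")
    if mode == "simulate" and rng is None:
        raise ValueError("simulate mode requires an rng")
    given = None
    if mode == "loglik":
        if choices is None:
            raise ValueError("loglik mode requires choices")
        given = _moves_from_log(choices, schedule)
    eng = _Engine(model, P, smap, schedule, min_prob)
    rows: list[list] = []
    loglik = 0.0
    prev_block = 0
    for spec in schedule.trials:
        if spec.block == REVALUATION_BEFORE_BLOCK and prev_block == REVALUATION_BEFORE_BLOCK - 1:
            eng._decay("tau_prime")
        if spec.block == SWITCH_BEFORE_BLOCK and prev_block == SWITCH_BEFORE_BLOCK - 1:
            if eng.has_mb:
                eng._rearrange()
            eng._decay("tau_prime")
        prev_block = spec.block
        eng._decay("tau")
        succ = eng.succ[spec.switched]
        R = eng.R[spec.phase - 1]
        # first move
        p = eng.first_move_probs(spec.start, spec.n_moves, R)[0]
        if mode == "simulate":
            m1 = int(rng.choice(4, p=p))
        else:
            m1 = given[spec.index][0]
        s2 = int(succ[spec.start, m1])
        prob1 = max(float(p[m1]), min_prob)
        loglik += np.log(prob1)
        moves, outcomes = [m1], [s2]
        if spec.n_moves == 2:
            s2_seen = s2 if spec.feedback else None
            p2 = eng.second_move_probs(spec.start, m1, s2_seen, R)[0]
            allowed = ALLOWED2[Move(m1)]
            if mode == "simulate":
                k = int(rng.choice(3, p=p2))
                m2 = int(allowed[k])
            else:
                m2 = given[spec.index][1]
                k = allowed.index(Move(m2))
            s3 = int(succ[s2, m2])
            prob2 = max(float(p2[k]), min_prob)
            loglik += np.log(prob2)
            moves.append(m2)
            outcomes.append(s3)
        pes = eng.observe(spec, moves, outcomes, R) if spec.feedback else {}
        states = [spec.start, s2]
        probs = [prob1] + ([prob2] if spec.n_moves == 2 else [])
        for j, m in enumerate(moves):
            rows.append([spec.index, spec.block, spec.n_moves, j + 1,
                         spec.feedback, spec.phase, spec.switched,
                         states[j], m, outcomes[j], float(R[outcomes[j]]),
                         probs[j],
                         pes.get("rpe" if j == 0 else "rpe2", np.nan),
                         pes.get("spe" if j == 0 else "spe2", np.nan)])
    log = pd.DataFrame(rows, columns=LOG_COLUMNS + ["rpe", "spe"])
    return log, float(loglik)


def _moves_from_log(log: pd.DataFrame, schedule: ExperimentSchedule
                    ) -> dict[int, list[int]]:
    df = log.sort_values(["trial", "move_index"])
    out: dict[int, list[int]] = {}
    for t, m in zip(df["trial"].to_numpy(), df["move"].to_numpy()):
        out.setdefault(int(t), []).append(int(m))
    n_expected = {s.index: s.n_moves for s in schedule.trials}
    for t, ms in out.items():
        if len(ms) != n_expected.get(t, -1):
            raise ValueError(f"trial {t}: choices do not match the schedule")
    return out


def _kernel_inputs(model: str, P: dict[str, np.ndarray], smap: StateSpaceMap,
                   schedule: ExperimentSchedule, given: dict[int, list[int]]):
    from ._fast import KERNEL_PARAMS

    S = len(P[MODEL_PARAM_NAMES[model][0]])
    params = np.zeros((S, len(KERNEL_PARAMS)))
    for j, name in enumerate(KERNEL_PARAMS):
        if name in P:
            params[:, j] = P[name]
    trials = schedule.trials
    Tn = len(trials)
    n_moves = np.empty(Tn, np.int64)
    start = np.empty(Tn, np.int64)
    feedback = np.empty(Tn, np.int64)
    phase = np.empty(Tn, np.int64)
    switched = np.empty(Tn, np.int64)
    event = np.zeros(Tn, np.int64)
    m1 = np.empty(Tn, np.int64)
    m2 = np.zeros(Tn, np.int64)
    prev_block = 0
    for t, spec in enumerate(trials):
        n_moves[t], start[t] = spec.n_moves, spec.start
        feedback[t], phase[t] = int(spec.feedback), spec.phase
        switched[t] = int(spec.switched)
        if spec.block == REVALUATION_BEFORE_BLOCK \
                and prev_block == REVALUATION_BEFORE_BLOCK - 1:
            event[t] = 1
        if spec.block == SWITCH_BEFORE_BLOCK \
                and prev_block == SWITCH_BEFORE_BLOCK - 1:
            event[t] = 2
        prev_block = spec.block
        ms = given[spec.index]
        m1[t] = ms[0]
        if spec.n_moves == 2:
            m2[t] = ms[1]
    succ_pre = transition_matrix(smap)
    succ_post = transition_matrix(smap.apply_switch())
    R_all = np.asarray(smap.rewards, dtype=float)
    allowed2 = np.array([[int(m) for m in ALLOWED2[m1_]] for m1_ in MOVES],
                        dtype=np.int64)
    opp = np.array([int(Move(m).opposite) for m in MOVES], dtype=np.int64)
    perm = np.arange(N_STATES)
    for a, b in smap.switch_pairs:
        perm[a], perm[b] = perm[b], perm[a]
    return (params, model in ("mf", "hybrid"), model in ("mb", "hybrid"),
            model == "mb", n_moves, start, feedback, phase, switched, event,
            m1, m2, succ_pre, succ_post, R_all, allowed2, opp, perm)


def batch_loglik(model: str, params: Mapping[str, np.ndarray],
                 log: pd.DataFrame | dict[int, list[int]],
                 smap: StateSpaceMap, schedule: ExperimentSchedule,
                 min_prob: float = 1e-12, backend: str = "numba"
                 ) -> np.ndarray:
    """Log-likelihood of one subject's realised moves for a whole batch of
    parameter settings (vectorised inner loop of the hierarchical fit).

    ``log`` may be an episode log or a pre-extracted ``{trial: moves}``
    mapping (reusable across repeated calls on the same subject).  The
    default backend is a compiled per-setting kernel; ``backend="numpy"``
    runs the reference vectorised engine (both give identical results).
    """
    P = _as_batch(params, model)
    given = log if isinstance(log, dict) else _moves_from_log(log, schedule)
    if backend == "numba":
        from ._fast import loglik_kernel
        args = _kernel_inputs(model, P, smap, schedule, given)
        return loglik_kernel(*args, min_prob)
    eng = _Engine(model, P, smap, schedule, min_prob)
    loglik = np.zeros(eng.S)
    prev_block = 0
    for spec in schedule.trials:
        if spec.block == REVALUATION_BEFORE_BLOCK and prev_block == REVALUATION_BEFORE_BLOCK - 1:
            eng._decay("tau_prime")
        if spec.block == SWITCH_BEFORE_BLOCK and prev_block == SWITCH_BEFORE_BLOCK - 1:
            if eng.has_mb:
                eng._rearrange()
            eng._decay("tau_prime")
        prev_block = spec.block
        eng._decay("tau")
        succ = eng.succ[spec.switched]
        R = eng.R[spec.phase - 1]
        m1 = given[spec.index][0]
        p = eng.first_move_probs(spec.start, spec.n_moves, R)
        loglik += np.log(np.maximum(p[:, m1], min_prob))
        s2 = int(succ[spec.start, m1])
        moves, outcomes = [m1], [s2]
        if spec.n_moves == 2:
            m2 = given[spec.index][1]
            k = ALLOWED2[Move(m1)].index(Move(m2))
            p2 = eng.second_move_probs(spec.start, m1,
                                       s2 if spec.feedback else None, R)
            loglik += np.log(np.maximum(p2[:, k], min_prob))
            moves.append(m2)
            outcomes.append(int(succ[s2, m2]))
        if spec.feedback:
            eng.observe(spec, moves, outcomes, R)
    return loglik


def simulate_cohort_logs(model: str, subject_params: Iterable[Mapping[str, float]],
                         smap: StateSpaceMap, schedule: ExperimentSchedule,
                         seed: int) -> list[pd.DataFrame]:
    """Simulate one episode log per subject parameter setting."""
    rng = np.random.default_rng(seed)
    logs = []
    for pd_i in subject_params:
        sub_rng = np.random.default_rng(rng.integers(2**31))
        log, _ = run_agent(pd_i, model, schedule, smap, rng=sub_rng,
                           mode="simulate")
        logs.append(log)
    return logs
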