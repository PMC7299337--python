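"""Behavioural metrics and nonparametric statistics on episode logs.

The central quantity is the flexibility index (IF): the proportion of first
moves that were optimal for the trial's actual number of allotted moves,
minus the proportion that would have been optimal had the trial allowed the
other number of moves.  Positive IF means a subject advantageously adjusts
first moves to the trial type; it indexes reliance on model-based planning.
Both components are computed within trial type and averaged across the two
types (the design has twice as many 2-move as 1-move trials), and a move
counts as optimal when it lies in the (possibly tied) optimal set of the
brute-force planner, with UP and DOWN equivalent.  Chance level of each
component is 1/3.

Also provided: instructed-change performance drops (corrected across a
cohort for pre-change performance), the probability of changing policy on
revisiting a state, and the study's nonparametric statistics (BCa bootstrap,
pairing permutation tests, partial and rank correlations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_env import (ExperimentSchedule, Move, StateSpaceMap, current_map,
                   optimal_first_moves, score_episode)

CHANCE_OPTIMAL = 1.0 / 3.0   # three effective moves (UP and DOWN coincide)


@dataclass(frozen=True)
class FlexibilityIndex:
    if_value: float
    prop_optimal_actual: float
    prop_optimal_counterfactual: float


def _first_moves(log: pd.DataFrame) -> pd.DataFrame:
    return log[log["move_index"] == 1]


def flexibility_index(log: pd.DataFrame, smap: StateSpaceMap) -> FlexibilityIndex:
    """IF = P(first move optimal | actual trial type) - P(optimal | other type).

    Each component is computed within trial type, then averaged over the two
    types.  Optimality is membership of the oracle's optimal set for the
    trial's reward phase and map version.
    """
    fm = _first_moves(log)
    acc: dict[tuple[int, str], list[float]] = {}
    for row in fm.itertuples():
        cur = current_map(smap, bool(row.switched))
        mv = Move(int(row.move))
        for kind, n_moves in (("actual", int(row.n_moves)),
                              ("counter", 3 - int(row.n_moves))):
            opt, _ = optimal_first_moves(cur, int(row.phase), int(row.state),
                                         n_moves)
            acc.setdefault((int(row.n_moves), kind), []).append(mv in opt)
    for kind in ("actual", "counter"):
        for nm in (1, 2):
            if (nm, kind) not in acc:
                raise ValueError("log must contain both trial types")
    p_act = np.mean([np.mean(acc[(1, "actual")]), np.mean(acc[(2, "actual")])])
    p_ctr = np.mean([np.mean(acc[(1, "counter")]), np.mean(acc[(2, "counter")])])
    return FlexibilityIndex(if_value=float(p_act - p_ctr),
                            prop_optimal_actual=float(p_act),
                            prop_optimal_counterfactual=float(p_ctr))


def change_performance_drop(logs: list[pd.DataFrame], smap: StateSpaceMap,
                            schedule: ExperimentSchedule,
                            change: str = "reward") -> pd.DataFrame:
    """Per-subject post-change performance drops, cohort-corrected.

    The raw drop is the mean pre-change 18-trial bin score minus the first
    post-change bin score; the corrected drop is the residual of the raw
    drop regressed, across subjects, on the pre-change score.  ``change``
    selects the reward revaluation (before block 3) or the position switch
    (before block 5).
    """
    if len(logs) < 2:
        raise ValueError("the correction is cohort-level: need >= 2 subjects")
    change_block = {"reward": 3, "position": 5}[change]
    first_post_bin = (change_block - 1) * 3   # 3 bins of 18 trials per block
    rows = []
    for log in logs:
        scores = score_episode(log, smap, schedule)
        pre = float(np.mean(scores[:first_post_bin]))
        rows.append({"pre_score": pre,
                     "raw_drop": pre - float(scores[first_post_bin])})
    df = pd.DataFrame(rows)
    slope, intercept = np.polyfit(df["pre_score"], df["raw_drop"], 1)
    df["corrected_drop"] = df["raw_drop"] - (slope * df["pre_score"] + intercept)
    return df


def policy_change_probability(log: pd.DataFrame, smap: StateSpaceMap | None = None,
                              conditioning: np.ndarray | None = None
                              ) -> float | tuple[float, float]:
    """Probability of choosing a different first move on the next visit to
    the same state (same trial type); UP and DOWN count as the same policy.

    Evaluated at the first occurrence of each chosen (state, trial type,
    move) trajectory.  With ``conditioning`` (one scalar per trial, e.g. a
    replay measure at that trial's outcome), returns the probabilities for
    events above and below the conditioning mean.
    """
    fm = _first_moves(log).sort_values("trial")
    states = fm["state"].to_numpy()
    nmoves = fm["n_moves"].to_numpy()
    moves = fm["move"].to_numpy()
    trials = fm["trial"].to_numpy()
    eff = np.where(np.isin(moves, (int(Move.UP), int(Move.DOWN))), 2, moves)
    events: list[tuple[int, bool]] = []   # (trial, changed on next visit)
    seen: set[tuple[int, int, int]] = set()
    for i in range(len(fm)):
        key = (int(states[i]), int(nmoves[i]), int(eff[i]))
        if key in seen:
            continue
        seen.add(key)
        for j in range(i + 1, len(fm)):
            if states[j] == states[i] and nmoves[j] == nmoves[i]:
                events.append((int(trials[i]), eff[j] != eff[i]))
                break
    if not events:
        raise ValueError("no repeated (state, trial type) visits in the log")
    if conditioning is None:
        return float(np.mean([c for _, c in events]))
    cond = np.asarray([conditioning[t] for t, _ in events], dtype=float)
    changed = np.asarray([c for _, c in events], dtype=bool)
    hi, lo = cond > np.nanmean(cond), cond <= np.nanmean(cond)
    return (float(changed[hi].mean()) if hi.any() else np.nan,
            float(changed[lo].mean()) if lo.any() else np.nan)


# ---------------------------------------------------------------------------
# Nonparametric statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n_resamples: int


def bca_bootstrap(samples, statistic, n: int = 10_000,
                  rng: np.random.Generator | None = None,
                  confidence_level: float = 0.95) -> StatResult:
    """Bias-corrected and accelerated bootstrap CI of a 1-sample statistic,
    with a two-tailed sign test of the statistic against zero derived from
    the bootstrap distribution."""
    samples = np.asarray(samples, dtype=float)
    rng = rng or np.random.default_rng()
    res = stats.bootstrap((samples,), statistic, n_resamples=n, method="BCa",
                          confidence_level=confidence_level, random_state=rng,
                          vectorized=False)
    est = float(statistic(samples))
    boot = res.bootstrap_distribution
    frac = (1 + np.sum(boot <= 0) if est > 0 else 1 + np.sum(boot >= 0)) / (1 + len(boot))
    p = min(1.0, 2.0 * frac)
    return StatResult(estimate=est, ci_low=float(res.confidence_interval.low),
                      ci_high=float(res.confidence_interval.high),
                      p_value=float(p), n_resamples=n)


def permutation_test(x, y, statistic=None, n: int = 10_000,
                     rng: np.random.Generator | None = None) -> StatResult:
    """Two-tailed permutation test of the pairing between ``x`` and ``y``
    (default statistic: Pearson correlation); p = (1 + #extreme) / (1 + n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = rng or np.random.default_rng()
    if statistic is None:
        def statistic(a, b):
            return np.corrcoef(a, b)[0, 1]
    obs = float(statistic(x, y))
    null = np.empty(n)
    for i in range(n):
        null[i] = statistic(x, rng.permutation(y))
    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (1 + n)
    lo, hi = np.quantile(null, [0.025, 0.975])
    return StatResult(estimate=obs, ci_low=float(lo), ci_high=float(hi),
                      p_value=float(p), n_resamples=n)


def partial_correlation(x, y, z) -> float:
    """Pearson correlation of x and y after residualising both on z."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    Z = np.column_stack([np.ones(len(x)), np.asarray(z, float)])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    tol = 1e-10 * max(x.std(), y.std(), 1.0)
    if rx.std() <= tol or ry.std() <= tol:
        raise ValueError("constant residuals: partial correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def metrics_table(logs: list[pd.DataFrame], smap: StateSpaceMap,
                  schedule: ExperimentSchedule) -> pd.DataFrame:
    """Per-subject summary table: IF with its components, raw/corrected
    drops after both instructed changes, and the policy-change rate."""
    rows = []
    for log in logs:
        fi = flexibility_index(log, smap)
        rows.append({"if_value": fi.if_value,
                     "prop_optimal_actual": fi.prop_optimal_actual,
                     "prop_optimal_counterfactual": fi.prop_optimal_counterfactual,
                     "policy_change": policy_change_probability(log)})
    df = pd.DataFrame(rows)
    for change in ("reward", "position"):
        drops = change_performance_drop(logs, smap, schedule, change)
        df[f"{change}_raw_drop"] = drops["raw_drop"]
        df[f"{change}_corrected_drop"] = drops["corrected_drop"]
    return df
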