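"""Replay detection via cross-correlation asymmetry ("sequenceness").

Given two decodability time series — moment-by-moment probabilities that two
images are being neurally represented — sequenceness at lag ``d`` is the
difference between the lagged cross-correlations in the two directions,

    seq(d) = corr(x_t, y_{t+d}) - corr(y_t, x_{t+d}),

computed on z-scored series within sliding windows and averaged over lags of
10-200 ms.  Because it contrasts the two directions, the measure is blind to
simultaneous (zero-lag) covariation and to autocorrelation common to both
series; a positive value means x tends to precede y (forward replay of the
transition x -> y), a negative value the reverse.  Exact antisymmetry under
argument exchange holds at every lag by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .task_env import IMAGES

DEFAULT_FS = 100.0


@dataclass(frozen=True)
class SeqConfig:
    """Lag grid and windowing for the sequenceness estimator.

    Lags span 10-200 ms in sampling steps.  The window default is 400 ms for
    epoch-level estimates and 600 ms for sliding time courses (both appear
    in the source analyses; see the methods note).
    """

    fs: float = DEFAULT_FS
    min_lag_ms: float = 10.0
    max_lag_ms: float = 200.0
    window_ms: float = 400.0
    window_step: int = 1          # samples between window starts

    @property
    def lags(self) -> np.ndarray:
        """Lags in samples."""
        step_ms = 1000.0 / self.fs
        return np.arange(max(1, round(self.min_lag_ms / step_ms)),
                         round(self.max_lag_ms / step_ms) + 1)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    @property
    def window(self) -> int:
        w = int(round(self.window_ms * self.fs / 1000.0))
        if self.lags.max() >= w:
            raise ValueError("max lag must be shorter than the window")
        return w


@dataclass
class SeqResult:
    lags_ms: np.ndarray
    c_fwd: np.ndarray            # per-lag forward cross-correlation
    c_bwd: np.ndarray
    n_windows: int
    n_excluded: int              # zero-variance windows dropped
    per_window: np.ndarray | None = None   # (n_windows, n_lags) seq values

    @property
    def seq(self) -> np.ndarray:
        return self.c_fwd - self.c_bwd

    @property
    def lag_mean(self) -> float:
        """Sequenceness averaged over the lag grid."""
        return float(np.mean(self.seq))


@dataclass(frozen=True)
class DecodabilitySeries:
    """Decoded per-image probability time series with event markers.

    ``probs`` is (time x 8); ``events`` has one row per outcome with columns
    ``time`` (s), ``trial``, ``move_index``, ``prev_image``, ``image`` (and
    for 2-move trials the trial's starting image in ``first_image``).
    """

    probs: np.ndarray
    fs: float = DEFAULT_FS
    events: pd.DataFrame | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.probs)):
            raise ValueError("probabilities must be finite")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    def channel(self, image: int) -> np.ndarray:
        return self.probs[:, image]

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.csv`` (time x image-label matrix) and a
        ``<prefix>.events.json`` sidecar (sampling rate, event times in
        seconds, image labels)."""
        prefix = Path(prefix)
        pd.DataFrame(self.probs, columns=list(IMAGES)).to_csv(
            prefix.with_suffix(".csv"), index=False)
        sidecar = {"fs_hz": self.fs, "image_labels": list(IMAGES),
                   "events": (self.events.to_dict(orient="records")
                              if self.events is not None else None)}
        prefix.with_suffix(".events.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "DecodabilitySeries":
        prefix = Path(prefix)
        probs = pd.read_csv(prefix.with_suffix(".csv")).to_numpy()
        sidecar = json.loads(prefix.with_suffix(".events.json").read_text())
        events = (pd.DataFrame(sidecar["events"])
                  if sidecar["events"] is not None else None)
        return cls(probs=probs, fs=float(sidecar["fs_hz"]), events=events)


def _window_xcorr(xw: np.ndarray, yw: np.ndarray, lags: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-lag cross-correlations of one window, or None if degenerate."""
    if xw.std() == 0 or yw.std() == 0:
        return None
    xz = (xw - xw.mean()) / xw.std()
    yz = (yw - yw.mean()) / yw.std()
    c_fwd = np.empty(len(lags))
    c_bwd = np.empty(len(lags))
    for i, d in enumerate(lags):
        c_fwd[i] = np.mean(xz[:-d] * yz[d:])
        c_bwd[i] = np.mean(yz[:-d] * xz[d:])
    return c_fwd, c_bwd


def sequenceness(x: np.ndarray, y: np.ndarray, cfg: SeqConfig | None = None,
                 keep_windows: bool = False) -> SeqResult:
    """Windowed sequenceness between two equally long series.

    Within each sliding window the series are z-scored and lagged
    cross-correlations computed with incomplete tail samples dropped;
    per-lag values are averaged over all non-degenerate windows.
    """
    cfg = cfg or SeqConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    W = cfg.window
    if len(x) < W:
        raise ValueError("series shorter than one window")
    lags = cfg.lags
    fwd, bwd, per_win = [], [], []
    n_excluded = 0
    for a in range(0, len(x) - W + 1, cfg.window_step):
        res = _window_xcorr(x[a:a + W], y[a:a + W], lags)
        if res is None:
            n_excluded += 1
            continue
        fwd.append(res[0])
        bwd.append(res[1])
        if keep_windows:
            per_win.append(res[0] - res[1])
    if not fwd:
        raise ValueError("all windows degenerate (zero variance)")
    return SeqResult(lags_ms=cfg.lags_ms,
                     c_fwd=np.mean(fwd, axis=0), c_bwd=np.mean(bwd, axis=0),
                     n_windows=len(fwd), n_excluded=n_excluded,
                     per_window=np.asarray(per_win) if keep_windows else None)


def seq_timecourse(x: np.ndarray, y: np.ndarray, anchors_s,
                   cfg: SeqConfig | None = None,
                   epoch_s: tuple[float, float] = (-0.3, 1.5)
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Anchor-aligned sliding-window sequenceness time courses.

    For each anchor time and each epoch timepoint, the lag-averaged
    sequenceness of the window centred at that timepoint.  Returns
    ``(times_s, values)`` with ``values`` of shape (n_anchors,
    n_timepoints); windows extending beyond the series are NaN.
    """
    cfg = cfg or SeqConfig(window_ms=600.0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    W = cfg.window
    half = W // 2
    lags = cfg.lags
    step = 1.0 / cfg.fs
    times = np.arange(round(epoch_s[0] / step), round(epoch_s[1] / step) + 1)
    out = np.full((len(list(anchors_s)), len(times)), np.nan)
    for i, t0 in enumerate(anchors_s):
        c0 = int(round(t0 * cfg.fs))
        for j, dt in enumerate(times):
            a = c0 + dt - half
            if a < 0 or a + W > len(x):
                continue
            res = _window_xcorr(x[a:a + W], y[a:a + W], lags)
            if res is not None:
                out[i, j] = np.mean(res[0] - res[1])
    return times * step, out


def estimate_lag(result: SeqResult) -> float | None:
    """Lag (ms) maximising |seq|; None when the profile is flat."""
    s = np.abs(result.seq)
    if np.allclose(s, s[0]):
        return None
    return float(result.lags_ms[int(np.argmax(s))])


def transition_sequenceness(log: pd.DataFrame, decoded: DecodabilitySeries,
                            which: str = "last",
                            cfg: SeqConfig | None = None,
                            epoch_s: tuple[float, float] = (-0.3, 1.5)
                            ) -> tuple[pd.DataFrame, SeqResult]:
    """Post-outcome sequenceness of the realised transitions.

    ``which="last"``: after every outcome, the transition that concluded at
    it (previous state -> outcome state).  ``which="penultimate"``: after
    second outcomes of 2-move trials only, the trial's first transition.
    Returns a per-event table (with lag-averaged sequenceness and estimated
    lag) and the per-lag profile averaged over events.
    """
    if decoded.events is None:
        raise ValueError("decoded series carries no event markers")
    cfg = cfg or SeqConfig()
    events = decoded.events
    rows = []
    profiles = []
    n0 = int(round(epoch_s[0] * decoded.fs))
    n1 = int(round(epoch_s[1] * decoded.fs))
    for ev in events.itertuples():
        if which == "last":
            a, b = int(ev.prev_image), int(ev.image)
        elif which == "penultimate":
            if int(ev.move_index) != 2:
                continue
            a, b = int(ev.first_image), int(ev.prev_image)
        else:
            raise ValueError(which)
        c = int(round(float(ev.time) * decoded.fs))
        lo, hi = c + n0, c + n1
        if lo < 0 or hi > decoded.n_samples:
            continue
        try:
            res = sequenceness(decoded.channel(a)[lo:hi],
                               decoded.channel(b)[lo:hi], cfg)
        except ValueError:
            continue
        profiles.append(res.seq)
        rows.append({"trial": int(ev.trial), "move_index": int(ev.move_index),
                     "time": float(ev.time), "from_image": a, "to_image": b,
                     "seq": res.lag_mean, "lag_ms": estimate_lag(res)})
    if not rows:
        raise ValueError("no scorable events (alignment missing?)")
    mean_profile = np.mean(profiles, axis=0)
    agg = SeqResult(lags_ms=cfg.lags_ms, c_fwd=mean_profile,
                    c_bwd=np.zeros_like(mean_profile),
                    n_windows=len(profiles), n_excluded=0)
    return pd.DataFrame(rows), agg


def rank_transitions(logs: list[pd.DataFrame]) -> pd.Series:
    """Frequency of realised image-to-image transitions over blocks of
    trials, keyed by (from_image, to_image); insertion order (first
    occurrence) breaks ties deterministically."""
    counts: dict[tuple[int, int], int] = {}
    for log in logs:
        for row in log.itertuples():
            key = (int(row.state), int(row.outcome))
            counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts)


def rest_sequenceness(decoded_rest: DecodabilitySeries,
                      logs: list[pd.DataFrame], k: int = 5,
                      cfg: SeqConfig | None = None
                      ) -> dict[str, SeqResult | list[tuple[int, int]]]:
    """Rest-period sequenceness of the top-k most frequently chosen
    transitions of the adjacent blocks, with the least frequent transitions
    from the same starting states as control."""
    cfg = cfg or SeqConfig()
    freq = rank_transitions(logs)
    if len(freq) < k:
        raise ValueError(f"fewer than {k} distinct transitions in the logs")
    order = freq.sort_values(ascending=False, kind="stable")
    top = list(order.index[:k])
    bottom = []
    for s, _ in top:
        cand = [(pair, n) for pair, n in freq.items()
                if pair[0] == s and pair not in top and pair not in bottom]
        if cand:
            bottom.append(min(cand, key=lambda c: c[1])[0])
    def _mean_seq(pairs):
        profs_f, profs_b = [], []
        for a, b in pairs:
            r = sequenceness(decoded_rest.channel(a), decoded_rest.channel(b),
                             cfg)
            profs_f.append(r.c_fwd)
            profs_b.append(r.c_bwd)
        return SeqResult(lags_ms=cfg.lags_ms, c_fwd=np.mean(profs_f, axis=0),
                         c_bwd=np.mean(profs_b, axis=0),
                         n_windows=len(pairs), n_excluded=0)
    return {"top_pairs": top, "bottom_pairs": bottom,
            "top": _mean_seq(top),
            "bottom": _mean_seq(bottom) if bottom else None}
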