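"""Synthetic decodability time series with planted replay sequences.

The generator emulates the statistical structure of decoded MEG
probabilities at 100 Hz: an autocorrelated AR(1) background per image
channel, raised-cosine activation pulses marking transient image
representations, and optional planted *sequences* — a pulse on one image
followed, at a controlled lag, by a pulse on a second image (reversed for
backward replay).  A simultaneous zero-lag common component across two
channels provides the null control that the sequenceness measure must
ignore.  Cohort simulation couples the planted amplitude to per-subject
flexibility and per-event surprise, which is the generative structure the
hierarchical Gaussian-process analysis assumes, and returns the ground
truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequenceness import DecodabilitySeries, DEFAULT_FS

N_IMAGES = 8


@dataclass(frozen=True)
class PlantSpec:
    """One planted pairwise sequence a -> b at a fixed lag."""
    pair: tuple[int, int]
    lag_ms: float
    event_times: tuple[float, ...]      # seconds
    amplitude: float = 1.0
    direction: str = "forward"          # or "backward"
    duration_ms: float = 100.0

    def __post_init__(self):
        if not 0 < self.lag_ms <= 200:
            raise ValueError("lag must lie in (0, 200] ms")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.direction not in ("forward", "backward"):
            raise ValueError(self.direction)


@dataclass(frozen=True)
class NoiseModel:
    ar_coef: float = 0.8     # AR(1) coefficient at 100 Hz
    sd: float = 1.0          # innovation scale


def _pulse(duration_ms: float, fs: float) -> np.ndarray:
    """Raised-cosine activation pulse."""
    n = max(int(round(duration_ms * fs / 1000.0)), 1)
    t = np.arange(n)
    return 0.5 * (1 - np.cos(2 * np.pi * (t + 1) / (n + 1)))


def _add_pulse(sig: np.ndarray, at: int, pulse: np.ndarray, amp: float):
    if at >= len(sig) or at + len(pulse) <= 0:
        return
    lo, hi = max(at, 0), min(at + len(pulse), len(sig))
    sig[lo:hi] += amp * pulse[lo - at:hi - at]


def simulate_decodability(duration_s: float, plants: list[PlantSpec] = (),
                          noise: NoiseModel = NoiseModel(),
                          fs: float = DEFAULT_FS,
                          rng: np.random.Generator | None = None,
                          common: list[PlantSpec] = (),
                          events: pd.DataFrame | None = None
                          ) -> DecodabilitySeries:
    """8-channel AR(1) background plus planted sequences.

    Each plant adds a pulse on its first image at every event time and a
    pulse on the second image one lag later (order reversed for backward
    plants).  ``common`` plants add the *same* pulse to both channels at
    zero lag — simultaneous covariation with no sequential structure.
    """
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * fs))
    innov = rng.normal(0.0, noise.sd, (n, N_IMAGES))
    probs = np.empty((n, N_IMAGES))
    probs[0] = innov[0]
    for t in range(1, n):
        probs[t] = noise.ar_coef * probs[t - 1] + innov[t]
    for plant in plants:
        a, b = plant.pair
        if plant.direction == "backward":
            a, b = b, a
        pulse = _pulse(plant.duration_ms, fs)
        lag = int(round(plant.lag_ms * fs / 1000.0))
        for t0 in plant.event_times:
            c = int(round(t0 * fs))
            _add_pulse(probs[:, a], c, pulse, plant.amplitude)
            _add_pulse(probs[:, b], c + lag, pulse, plant.amplitude)
    for plant in common:
        a, b = plant.pair
        pulse = _pulse(plant.duration_ms, fs)
        for t0 in plant.event_times:
            c = int(round(t0 * fs))
            _add_pulse(probs[:, a], c, pulse, plant.amplitude)
            _add_pulse(probs[:, b], c, pulse, plant.amplitude)
    return DecodabilitySeries(probs=probs, fs=fs, events=events)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of synthetic subjects with replay coupled to flexibility and
    surprise: planted amplitude = softplus-clipped linear predictor
    ``b0 + b_if*IF + b_s*S + b_int*IF*S`` with standardized IF and surprise
    coded +-1."""
    n_subjects: int = 8
    n_events_per_series: int = 12
    pair: tuple[int, int] = (1, 3)
    lag_ms: float = 130.0
    epoch_s: float = 2.0
    gap_s: float = 1.0
    base_amplitude: float = 1.0
    beta_if: float = 0.0
    beta_surprise: float = 0.0
    beta_interaction: float = 0.0
    noise: NoiseModel = NoiseModel()
    seed: int = 0


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[list[dict], pd.DataFrame]:
    """Per-subject decodability series for high/low-surprise outcome epochs.

    Returns ``(subjects, truth)``: per subject a dict with the standardized
    IF value, and for each surprise level a DecodabilitySeries whose
    outcome-anchored epochs carry plants of the subject's amplitude; and the
    ground-truth table of generating amplitudes.
    """
    rng = np.random.default_rng(spec.seed)
    if_values = rng.normal(0.0, 1.0, spec.n_subjects)
    if spec.n_subjects > 1:
        if_values = (if_values - if_values.mean()) / if_values.std()
    subjects, rows = [], []
    period = spec.epoch_s + spec.gap_s
    duration = spec.n_events_per_series * period + 1.0
    anchors = tuple(0.5 + i * period for i in range(spec.n_events_per_series))
    for i in range(spec.n_subjects):
        entry: dict = {"if_value": float(if_values[i]), "series": {}}
        for s_code, label in ((1.0, "high"), (-1.0, "low")):
            amp = (spec.base_amplitude + spec.beta_if * if_values[i]
                   + spec.beta_surprise * s_code
                   + spec.beta_interaction * if_values[i] * s_code)
            amp = max(float(amp), 0.0)
            plants = [PlantSpec(pair=spec.pair, lag_ms=spec.lag_ms,
                                event_times=anchors, amplitude=amp)]
            series = simulate_decodability(
                duration, plants, spec.noise, rng=np.random.default_rng(
                    rng.integers(2**31)))
            entry["series"][label] = (series, anchors)
            rows.append({"subject": i, "surprise": label,
                         "if_value": float(if_values[i]), "amplitude": amp})
        subjects.append(entry)
    return subjects, pd.DataFrame(rows)
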