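"""Sequenceness statistic and the synthetic decodability generator."""

import numpy as np
import pandas as pd
import pytest

import replaynav.sequenceness as sq
from replaynav import synth_decode as sd


def plant_series(lag_ms, amplitude=3.0, duration=40.0, seed=0,
                 direction="forward", pair=(0, 1)):
    events = tuple(np.arange(0.5, duration - 1.0, 1.0))
    plant = sd.PlantSpec(pair=pair, lag_ms=lag_ms, event_times=events,
                         amplitude=amplitude, direction=direction)
    return sd.simulate_decodability(duration, [plant],
                                    rng=np.random.default_rng(seed))


class TestSequenceness:
    def test_forward_plant_is_positive_with_peak_near_lag(self):
        cfg = sq.SeqConfig()
        means, profiles = [], []
        for s in range(6):
            d = plant_series(120.0, seed=s)
            r = sq.sequenceness(d.channel(0), d.channel(1), cfg)
            means.append(r.lag_mean)
            profiles.append(r.seq)
        assert np.mean(means) > 0
        peak = cfg.lags_ms[int(np.argmax(np.abs(np.mean(profiles, axis=0))))]
        assert abs(peak - 120.0) <= 20.0

    def test_antisymmetry_is_exact(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        cfg = sq.SeqConfig()
        r_xy = sq.sequenceness(x, y, cfg)
        r_yx = sq.sequenceness(y, x, cfg)
        assert np.array_equal(r_xy.c_fwd, r_yx.c_bwd)
        assert np.allclose(r_xy.seq, -r_yx.seq)
        assert sq.estimate_lag(r_xy) == sq.estimate_lag(r_yx)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        cfg = sq.SeqConfig()
        base = sq.sequenceness(x, y, cfg)
        scaled = sq.sequenceness(3.7 * x - 2.0, 0.2 * y + 11.0, cfg)
        assert np.allclose(base.seq, scaled.seq)

    def test_simultaneous_covariation_yields_null(self):
        # shared zero-lag component plus independent AR noise: the asymmetry
        # measure must not mistake correlation for sequence
        cfg = sq.SeqConfig()
        events = tuple(np.arange(0.5, 19.0, 1.0))
        common = sd.PlantSpec(pair=(0, 1), lag_ms=100.0, event_times=events,
                              amplitude=3.0)
        vals = []
        for s in range(40):
            d = sd.simulate_decodability(20.0, [], rng=np.random.default_rng(s),
                                         common=[common])
            vals.append(sq.sequenceness(d.channel(0), d.channel(1),
                                        cfg).lag_mean)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2.5 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_zero_variance_windows_are_excluded(self):
        cfg = sq.SeqConfig()
        x = np.zeros(200)
        y = np.zeros(200)
        x[100:] = np.sin(np.arange(100))
        y[100:] = np.cos(np.arange(100))
        r = sq.sequenceness(x, y, cfg)
        assert r.n_excluded > 0
        with pytest.raises(ValueError):
            sq.sequenceness(np.zeros(100), np.zeros(100), cfg)


class TestTimecourse:
    def test_localized_plant_shows_up_where_planted(self):
        # sequence planted 0-400 ms after each anchor, absent later
        fs = 100.0
        anchors = tuple(1.0 + 3.0 * i for i in range(12))
        plant = sd.PlantSpec(pair=(0, 1), lag_ms=120.0,
                             event_times=tuple(a + 0.05 for a in anchors),
                             amplitude=4.0)
        d = sd.simulate_decodability(40.0, [plant],
                                     rng=np.random.default_rng(1))
        cfg = sq.SeqConfig(window_ms=600.0)
        t, vals = sq.seq_timecourse(d.channel(0), d.channel(1), anchors, cfg,
                                    epoch_s=(0.0, 2.0))
        mean = np.nanmean(vals, axis=0)
        early = mean[(t >= 0.0) & (t <= 0.5)].mean()
        late = mean[(t >= 1.5)].mean()
        assert early > late
        assert early > 0

    def test_no_anchors_gives_empty_output(self, rng):
        x = rng.normal(size=500)
        t, vals = sq.seq_timecourse(x, x + 1.0, [], sq.SeqConfig())
        assert vals.shape[0] == 0

    def test_out_of_bounds_windows_flagged_as_nan(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        t, vals = sq.seq_timecourse(x, y, [0.1], sq.SeqConfig(window_ms=600.0),
                                    epoch_s=(-0.3, 1.5))
        assert np.isnan(vals[0, 0])


class TestEstimateLag:
    def test_flat_profile_flagged(self):
        r = sq.SeqResult(lags_ms=np.arange(10, 210, 10.0),
                         c_fwd=np.full(20, 0.3), c_bwd=np.full(20, 0.1),
                         n_windows=1, n_excluded=0)
        assert sq.estimate_lag(r) is None

    def test_group_profile_recovers_planted_lags(self):
        cfg = sq.SeqConfig()
        for lag in (130.0, 180.0):
            profs = []
            for s in range(12):
                d = plant_series(lag, seed=100 + s)
                profs.append(sq.sequenceness(d.channel(0), d.channel(1),
                                             cfg).seq)
            mean = np.mean(profs, axis=0)
            est = cfg.lags_ms[int(np.argmax(np.abs(mean)))]
            assert abs(est - lag) <= 10.0


class TestTransitionSequenceness:
    @staticmethod
    def _decoded_with_events(lag_ms=130.0, amplitude=4.0, reverse=False,
                             seed=0):
        n_ev = 14
        times = 1.0 + 2.5 * np.arange(n_ev)
        plants = [sd.PlantSpec(pair=(2, 5), lag_ms=lag_ms,
                               event_times=tuple(times), amplitude=amplitude,
                               direction="backward" if reverse else "forward")]
        events = pd.DataFrame({
            "time": times, "trial": np.arange(n_ev), "move_index": 1,
            "prev_image": 2, "image": 5, "first_image": 2})
        return sd.simulate_decodability(float(times[-1] + 3.0), plants,
                                        rng=np.random.default_rng(seed),
                                        events=events)

    def test_forward_plant_recovered_per_trial(self):
        d = self._decoded_with_events()
        table, agg = sq.transition_sequenceness(None, d, which="last")
        assert table["seq"].mean() > 0
        est = agg.lags_ms[int(np.argmax(np.abs(agg.c_fwd)))]
        assert abs(est - 130.0) <= 10.0

    def test_reversed_plant_is_negative(self):
        d = self._decoded_with_events(reverse=True)
        table, _ = sq.transition_sequenceness(None, d, which="last")
        assert table["seq"].mean() < 0

    def test_pure_noise_is_near_zero(self):
        means = []
        for s in range(8):
            d = self._decoded_with_events(amplitude=0.0, seed=s)
            table, _ = sq.transition_sequenceness(None, d, which="last")
            means.append(table["seq"].mean())
        assert abs(np.mean(means)) < 0.02

    def test_missing_events_rejected(self, rng):
        d = sd.DecodabilitySeries(probs=rng.normal(size=(100, 8)))
        with pytest.raises(ValueError):
            sq.transition_sequenceness(None, d, which="last")


class TestRestSequenceness:
    @staticmethod
    def _fake_logs(pairs, repeats):
        rows = []
        trial = 0
        for (a, b), n in zip(pairs, repeats):
            for _ in range(n):
                rows.append([trial, 1, 1, 1, True, 1, False, a, 0, b, 0.0, 1.0])
                trial += 1
        return [pd.DataFrame(rows, columns=[
            "trial", "block", "n_moves", "move_index", "feedback", "phase",
            "switched", "state", "move", "outcome", "points", "choice_prob"])]

    def test_planted_top_transitions_detected(self):
        top_pairs = [(0, 1), (2, 3), (4, 5), (6, 7), (1, 2)]
        rare_pairs = [(0, 2), (2, 4), (4, 6), (6, 0), (1, 3)]
        logs = self._fake_logs(top_pairs + rare_pairs,
                               [8] * 5 + [1] * 5)
        events = tuple(np.arange(0.5, 59.0, 0.7))
        plants = [sd.PlantSpec(pair=p, lag_ms=180.0, event_times=events,
                               amplitude=2.5) for p in top_pairs]
        rest = sd.simulate_decodability(60.0, plants,
                                        rng=np.random.default_rng(4))
        out = sq.rest_sequenceness(rest, logs, k=5)
        assert set(out["top_pairs"]) == set(top_pairs)
        assert out["top"].lag_mean > out["bottom"].lag_mean
        assert out["top"].lag_mean > 0
        est = out["top"].lags_ms[int(np.argmax(np.abs(out["top"].seq)))]
        assert abs(est - 180.0) <= 10.0

    def test_deterministic_tie_breaking(self):
        logs = self._fake_logs([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5),
                                (5, 6)], [2] * 6)
        rest = sd.simulate_decodability(10.0, [],
                                        rng=np.random.default_rng(0))
        a = sq.rest_sequenceness(rest, logs, k=5)
        b = sq.rest_sequenceness(rest, logs, k=5)
        assert a["top_pairs"] == b["top_pairs"]

    def test_too_few_transitions_rejected(self):
        logs = self._fake_logs([(0, 1), (1, 2)], [3, 3])
        rest = sd.simulate_decodability(10.0, [],
                                        rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            sq.rest_sequenceness(rest, logs, k=5)


class TestGenerator:
    def test_same_seed_reproduces_series(self):
        a = plant_series(100.0, seed=7)
        b = plant_series(100.0, seed=7)
        assert np.array_equal(a.probs, b.probs)

    def test_zero_amplitude_is_statistically_noise(self):
        cfg = sq.SeqConfig()
        vals = []
        for s in range(25):
            d = plant_series(100.0, amplitude=0.0, duration=20.0, seed=s)
            vals.append(sq.sequenceness(d.channel(0), d.channel(1),
                                        cfg).lag_mean)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2.5 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_sequenceness_increases_with_amplitude(self):
        # closed loop: regression of measured sequenceness on plant strength
        cfg = sq.SeqConfig()
        amps = [0.0, 1.0, 2.0, 3.0, 4.0]
        means = []
        for amp in amps:
            vals = [sq.sequenceness(
                (d := plant_series(120.0, amplitude=amp, duration=25.0,
                                   seed=10 * s + 1)).channel(0),
                d.channel(1), cfg).lag_mean for s in range(6)]
            means.append(np.mean(vals))
        slope = np.polyfit(amps, means, 1)[0]
        assert slope > 0
        assert means[-1] > means[0]

    def test_invalid_plants_rejected(self):
        with pytest.raises(ValueError):
            sd.PlantSpec(pair=(0, 1), lag_ms=250.0, event_times=(1.0,))
        with pytest.raises(ValueError):
            sd.PlantSpec(pair=(0, 1), lag_ms=100.0, event_times=(1.0,),
                         amplitude=-1.0)

    def test_cohort_single_subject_degenerate_ok(self):
        spec = sd.CohortSpec(n_subjects=1, n_events_per_series=2, seed=1)
        subs, truth = sd.simulate_cohort(spec)
        assert len(subs) == 1 and set(truth["surprise"]) == {"high", "low"}

    def test_cohort_amplitude_follows_linear_coupling(self):
        spec = sd.CohortSpec(n_subjects=6, beta_if=0.5, beta_surprise=0.25,
                             beta_interaction=0.1, seed=2)
        subs, truth = sd.simulate_cohort(spec)
        hi = truth[truth.surprise == "high"]
        expect = (spec.base_amplitude + spec.beta_if * hi.if_value
                  + spec.beta_surprise + spec.beta_interaction * hi.if_value)
        assert np.allclose(hi["amplitude"], np.maximum(expect, 0.0))


class TestSeriesIO:
    def test_csv_and_sidecar_roundtrip(self, rng, tmp_path):
        import pandas as pd
        events = pd.DataFrame({"time": [0.5], "trial": [0], "move_index": [1],
                               "prev_image": [2], "image": [5],
                               "first_image": [2]})
        d = sd.DecodabilitySeries(probs=rng.normal(size=(50, 8)), fs=100.0,
                                  events=events)
        d.save(tmp_path / "series")
        back = sd.DecodabilitySeries.load(tmp_path / "series")
        assert np.allclose(back.probs, d.probs)
        assert back.fs == d.fs
        assert back.events.equals(d.events)
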