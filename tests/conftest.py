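import numpy as np
import pytest

from replaynav import task_env as te


@pytest.fixture(scope="session")
def canonical_map():
    return te.CANONICAL_MAP


@pytest.fixture(scope="session")
def schedule(canonical_map):
    return te.generate_schedule(canonical_map, seed=0)


@pytest.fixture(scope="session")
def short_schedule(schedule):
    """First two blocks only (reduced-runtime fitting tests)."""
    trials = tuple(t for t in schedule.trials if t.block <= 2)
    return te.ExperimentSchedule(trials=trials,
                                 special_starts=schedule.special_starts)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_result(canonical_map, schedule):
    """One shared model/parameter-recovery run (the expensive harness)."""
    from replaynav import fitting

    return fitting.recovery_suite(canonical_map, schedule,
                                  n_datasets_per_model=5, n_subjects=8,
                                  stages=(400, 1600), max_iter=8, seed=21)


@pytest.fixture(scope="session")
def strong_gp_cohort_fit():
    """One shared high-SNR GP cohort fit (sign/CI recovery checks)."""
    from replaynav import gp_model as gp
    from replaynav import synth_decode as sd

    spec = sd.CohortSpec(n_subjects=10, n_events_per_series=20,
                         base_amplitude=2.0, beta_if=1.5, beta_surprise=0.8,
                         beta_interaction=0.4,
                         noise=sd.NoiseModel(ar_coef=0.8, sd=0.7), seed=3)
    subs, truth = sd.simulate_cohort(spec)
    ds = gp.dataset_from_cohort(subs, pair=spec.pair, epoch_s=(0.0, 1.0),
                                decimate=5)
    return gp.fit_mcmc(ds, iters=600, warmup=250, seed=0), truth
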