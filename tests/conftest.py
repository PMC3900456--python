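import numpy as np
import pytest

import kneeloads as kl


@pytest.fixture(scope="session")
def grid():
    return np.linspace(0.0, 100.0, 201)


@pytest.fixture(scope="session")
def walking_template():
    return kl.make_template("walking")


@pytest.fixture(scope="session")
def small_population():
    """3 subjects x 6 walking cycles, fixed seed; shared across tests."""
    config = kl.PopulationConfig(n_subjects=3, cycles_per_subject=6, seed=1234)
    trials, truth = kl.sample_population(config)
    return trials, truth


@pytest.fixture(scope="session")
def small_run(small_population):
    trials, truth = small_population
    result = kl.run_standardization(kl.RunConfig(), trials=trials)
    return result, truth


def make_trial(channels: dict, sample_rate: float = 100.0, side="right",
               activity="walking", subject_id="T01") -> kl.Trial:
    """Assemble a Trial from raw channel arrays, zero-filling the rest."""
    n = len(next(iter(channels.values())))
    full = {c: np.zeros(n) for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
    full.update({k: np.asarray(v, float) for k, v in channels.items()})
    meta = kl.SubjectMeta(
        subject_id=subject_id, sex="m", age=70, body_mass=90, height=175,
        side=side, tibiofemoral_angle=3.0, posterior_slope=7.0,
    )
    return kl.Trial(
        meta=meta, activity=activity, sample_rate=sample_rate,
        time=np.arange(n) / sample_rate, channels=full,
    )
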