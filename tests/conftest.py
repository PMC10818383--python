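import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tscs_tune as tt
from tscs_tune import features as feat_mod
from tscs_tune import labeling as label_mod

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_model(**kw) -> tt.MuscleResponseModel:
    """A quadriceps model with well-separated thresholds; noise off."""
    defaults = dict(
        muscle_id="Q_left", reflex_threshold=12.0, direct_threshold=27.0,
        latency_ms=8.0, emg_noise_sd=0.0, acc_noise_sd=0.0,
    )
    defaults.update(kw)
    return tt.MuscleResponseModel(**defaults)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Four healthy subjects, two positions, zero sensor noise."""
    spec = tt.demo_cohort_spec(n_healthy=4, positions=(-4.0, 0.0),
                               max_current=25.0, noise_scale=0.0)
    sessions, registry = tt.generate_cohort(spec, seed=11)
    events, report = tt.preprocess_cohort(sessions)
    labels = label_mod.label_events(events)
    return {"sessions": sessions, "registry": registry, "events": events,
            "report": report, "labels": labels}


@pytest.fixture(scope="session")
def low_noise_cohort():
    """Twelve healthy subjects, two positions, quarter-strength sensor
    noise, subject-specific maximum currents (discomfort termination)."""
    spec = tt.demo_cohort_spec(n_healthy=12, positions=(-4.0, 0.0),
                               max_current=None, noise_scale=0.25)
    sessions, registry = tt.generate_cohort(spec, seed=7)
    events, report = tt.preprocess_cohort(sessions)
    labels = label_mod.label_events(events)
    table = feat_mod.assemble_feature_table(events, labels)
    return {"sessions": sessions, "registry": registry, "events": events,
            "report": report, "labels": labels, "table": table}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
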