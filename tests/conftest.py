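import numpy as np
import pytest

from oculokit.synthio import DrugEffect, GeneratorConfig, SubjectParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_config():
    """Generator with every noise source and spread switched off."""
    return GeneratorConfig(
        V_group_sd=0.0,
        gain_sd=0.0,
        amplitude_gain_mean=1.0,
        amplitude_noise_cv=0.0,
        velocity_noise_cv=0.0,
        latency_between_sd_log=0.0,
        start_position_sd=0.0,
        error_propensity_sd=0.0,
        pupil_baseline_sd=0.0,
        pupil_noise_sd=0.0,
        pupil_drift_amplitude=0.0,
        blink_rate=0.0,
        seed=7,
    )


@pytest.fixture
def small_config():
    """Small noisy cohort for fast end-to-end tests."""
    return GeneratorConfig(n_patients=4, n_controls=4, seed=11)


def make_subject(V_true=130.0, gain=1.0, mu=4.70, sd=0.35, prop=-1.5, baseline=1500.0,
                 subject_id="s01", group="control"):
    return SubjectParams(
        subject_id=subject_id,
        group=group,
        V_true=V_true,
        latency_mu_log=mu,
        latency_sd_log=sd,
        gain=gain,
        error_propensity=prop,
        pupil_baseline=baseline,
    )
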