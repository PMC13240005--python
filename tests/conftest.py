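"""Shared fixtures: the default synthetic study (seed 0) processed through the
full demographic chain, and a noise-free configuration factory."""

from __future__ import annotations

import warnings

import pytest

from cohortenv import (
    SimulationConfig,
    build_env_matrix,
    build_generation_matrix,
    filter_generations,
    impute_missing,
    last_detection_years,
    sample_ages,
    simulate_cohorts,
    simulate_environment,
)
from cohortenv.demography import fit_all_generations


def noise_free_config(**overrides) -> SimulationConfig:
    """All stochastic terms off: deterministic environment, exact cohort
    truths, noise-free observation."""
    base = dict(
        env_noise_sd={"air_temp": 0.0, "water_temp": 0.0, "wind": 0.0, "wave": 0.0},
        env_shared_anomaly_sd=0.0,
        env_year_sd=0.0,
        noise_sd={"recruitment": 0.0, "mortality": 0.0},
        observation="exact",
        age1_detection=1.0,
        site_sd=0.0,
        biomass_noise_sd=0.0,
        annual_temp_noise_sd=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_config):
    """The default synthetic study, processed end to end (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        env = simulate_environment(default_config)
        truth = simulate_cohorts(env, default_config)
        samples = sample_ages(truth, config=default_config)
        gm = build_generation_matrix(samples)
        gm_f, report = filter_generations(gm)
        fits = fit_all_generations(gm_f)
        dm = impute_missing(gm_f, fits)
        last = last_detection_years(gm_f)
        env_matrix = build_env_matrix(
            env, [(int(b), int(last[b])) for b in gm_f.index]
        )
    return {
        "config": default_config,
        "env": env,
        "truth": truth,
        "samples": samples,
        "gm": gm,
        "gm_filtered": gm_f,
        "report": report,
        "fits": fits,
        "dm": dm,
        "env_matrix": env_matrix,
    }
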