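import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from catrace.extraction import process_cohort
from catrace.kinetics import extract_cell_metrics
from catrace.presets import load_presets
from catrace.protocol import AnalysisConfig, StimulusProtocol
from catrace.simulate import CohortPreset, generate_cohort

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def clean_preset():
    """Noise-free, responder-only preset with a comfortable gap between the
    receptor residual and the ionomycin amplitude (no feasibility clamping)."""
    return CohortPreset(
        group="control",
        stage="iPSC",
        stimulus="ATP",
        mu_peak=3.0,
        sd_peak_cell=0.5,
        mu_ttp=40.0,
        responder_frac=1.0,
        mu_iono_peak=4.0,
        sd_iono_cell=0.3,
        mu_iono_ttp=60.0,
        noise_sd=0.0,
        n_cells_per_replicate=10,
        n_replicates=2,
        n_lines=2,
    )


@pytest.fixture(scope="session")
def small_cohort(presets, protocol):
    """One noisy cohort (2 lines x 3 reps x 10 cells) of the pluripotent ASD condition."""
    from dataclasses import replace

    preset = replace(presets[("iPSC", "ATP", "ASD")], n_cells_per_replicate=10)
    return generate_cohort(preset, protocol, seed=42)


@pytest.fixture(scope="session")
def small_metrics(small_cohort, protocol, config):
    return extract_cell_metrics(
        process_cohort(small_cohort, protocol, config), protocol, config
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
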