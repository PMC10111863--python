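import pytest

from pioneerlink import PipelineConfig, StudyConfig, run_pipeline, simulate_study


def small_config(seed: int = 11) -> StudyConfig:
    """Scaled-down study used across unit tests: same densities and effect
    sizes as the defaults, smaller problem."""
    return StudyConfig(seed=seed, n_genes=60, n_tf_sites=400, n_background_peaks=200)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def small_report(tmp_path_factory):
    """A full pipeline run on the small study, shared by report-level tests."""
    out = tmp_path_factory.mktemp("report") / "run"
    run_pipeline(out, PipelineConfig(study=small_config()))
    return out
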