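import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A complete synthetic study on disk, at a reduced sampling rate.

    Signals use fs=400 Hz (duration stays 100 s so the 0.37 Hz slow wave
    still completes whole cycles and falls on an exact 0.01 Hz bin).
    """
    from phytostress.synth import default_study_config, generate_study

    out = tmp_path_factory.mktemp("study")
    config = default_study_config(master_seed=1, signal_fs=400.0)
    generate_study(config, out)
    return out


@pytest.fixture(scope="session")
def study_report(study_dir):
    from phytostress.pipeline import run_study

    return run_study(study_dir, strict=True)
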