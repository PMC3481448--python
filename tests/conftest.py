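import pytest

from pipesim.experiments import PipelineConfig, with_overrides
from pipesim.proteome import digest, generate_synthetic_proteome
from pipesim.synthetic_fixtures import make_toy_proteome


@pytest.fixture(scope="session")
def toy_catalog():
    """The 5-protein toy proteome, digested at defaults."""
    return digest(make_toy_proteome())


@pytest.fixture(scope="session")
def reduced_proteome():
    """A 300-protein synthetic proteome shared by the trend experiments."""
    return generate_synthetic_proteome(300, seed=7)


@pytest.fixture(scope="session")
def reduced_config():
    """Reduced-scale experiment configuration: 100 background + 20 marker
    proteins and 500 test samples per class, keeping full-pipeline runs fast
    while preserving every mechanism."""
    return with_overrides(
        PipelineConfig(), n_background=100, n_markers=20, n_test_per_class=500
    )


def noiseless_config(**extra) -> PipelineConfig:
    """Distortion-free pipeline: unit efficiency and response, no noise,
    perfect MS1 detection and MS2 identification."""
    base = with_overrides(
        PipelineConfig(),
        e_lo=1.0,
        e_hi=1.0,
        kappa=1.0,
        sat=float("inf"),
        alpha=0.0,
        beta=0.0,
        perfect_detection=True,
        identifiability_model="perfect",
    )
    return with_overrides(base, **extra) if extra else base
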