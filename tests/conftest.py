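import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fsfcensus import AnnotationScheme, default_scheme  # noqa: E402
from fsfcensus.simulate import SyntheticConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def scheme() -> AnnotationScheme:
    """The packaged annotation scheme (published category sizes)."""
    return default_scheme()


@pytest.fixture(scope="session")
def mini_scheme() -> AnnotationScheme:
    """A 5-FSF toy scheme with one NONA key, for unit arithmetic."""
    return AnnotationScheme(
        minor_to_general={
            "Energy": "Metabolism",
            "Translation": "Information",
            "DNA-binding": "Regulation",
        },
        fsf_to_minor={
            "a.1.1": "Energy",
            "a.1.2": "Energy",
            "c.1.1": "Translation",
            "g.1.1": "DNA-binding",
            "k.1.1": "NONA",
        },
    )


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, scheme):
    """A written 60-genome synthetic cohort shared by I/O and CLI tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = SyntheticConfig(
        seed=11,
        n_genomes={
            ("Archaea", "FL"): 12,
            ("Bacteria", "FL"): 24,
            ("Bacteria", "OP"): 8,
            ("Eukarya", "FL"): 16,
        },
    )
    generate_cohort(config, out, scheme)
    return out
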