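import pytest

from cbp_enhance import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study condition: 500 patients, default generator, seed 1."""
    return generate_cohort(GeneratorConfig(n=500, seed=1))


@pytest.fixture(scope="session")
def large_cohort():
    """A cohort big enough for stable parameter-recovery checks."""
    return generate_cohort(GeneratorConfig(n=10_000, seed=1))
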