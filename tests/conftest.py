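import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from marshequiv import (
    EffectSpec,
    SamplerConfig,
    StudyDesign,
    build_equivalence_table,
    simulate_study,
    summarize_replicates,
)


@pytest.fixture(scope="session")
def study_table():
    """One full synthetic 13-pair study under the null (all offsets 0)."""
    return simulate_study(StudyDesign(seed=11), EffectSpec())


@pytest.fixture(scope="session")
def study_summaries(study_table):
    return summarize_replicates(study_table)


@pytest.fixture(scope="session")
def equivalence_table(study_summaries):
    return build_equivalence_table(study_summaries)


@pytest.fixture
def quick_sampler():
    """Short but convergent MCMC settings for unit tests."""
    return SamplerConfig(chains=4, iterations=8_000, warmup=2_000, thin=2,
                         seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
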