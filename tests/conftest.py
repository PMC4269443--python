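import numpy as np
import pytest

import bilescreen as bs


@pytest.fixture(scope="session")
def community_small():
    """Default mock community on 8-kb genomes (fast to search)."""
    return bs.build_community(genome_len=8_000)


@pytest.fixture(scope="session")
def fixture_cohort(community_small):
    """Bundled small cohort: 2 groups × 10 samples × 3000 reads."""
    spec = bs.CohortSpec(
        groups=[("control", 10), ("disease", 10)],
        base_weights=bs.BASE_WEIGHTS,
        effects=bs.disease_effects(0.5),
        compensator="g_background",
        read_count=3_000,
        error_rate=0.01,
        seed=7,
    )
    return bs.simulate_cohort(spec, community_small.genomes)


@pytest.fixture(scope="session")
def analysis_small(community_small, fixture_cohort):
    """Full pipeline result over the bundled small cohort."""
    return bs.run_cohort_analysis(community_small, fixture_cohort)


@pytest.fixture(scope="session")
def single_sample(community_small):
    """One error-free sample with recorded origins."""
    profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
    return bs.simulate_sample(
        community_small.genomes, profile, 20_000, 75, 0.0, seed=5, sample_id="s0"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
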