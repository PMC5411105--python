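import pytest

import paleowean as pw


@pytest.fixture(scope="session")
def samples():
    """The 49 bundled individuals (31 juveniles, 18 adult females)."""
    return pw.load_samples(pw.bundled_samples_path())


@pytest.fixture(scope="session")
def groups(samples):
    return pw.group_juveniles(samples)


@pytest.fixture(scope="session")
def female_summary(groups):
    return pw.summarize_group(groups["females"], "females")


@pytest.fixture(scope="session")
def plant_sources():
    return [s for s in pw.load_bundled_sources() if s.name != "Breast Milk"]


@pytest.fixture(scope="session")
def all_sources(female_summary, plant_sources):
    """Derived breast-milk source plus the three bundled plant sources."""
    return [pw.milk_source_from_females(female_summary)] + plant_sources


@pytest.fixture(scope="session")
def small_mixing_config():
    from paleowean.mixing_model import MixingConfig

    return MixingConfig(n_iterations=6000, n_burn=3000, thin=3, n_chains=2, rng_seed=7)
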