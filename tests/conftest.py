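import numpy as np
import pytest

from ystrkit.markers import Haplotype, PopulationSample, YFILER17

# a complete, plausible Yfiler profile used as the template for fixtures
BASE_PROFILE = {
    "DYS19": 14.0,
    "DYS385": (11.0, 14.0),
    "DYS389I": 13.0,
    "DYS389II": 29.0,
    "DYS390": 24.0,
    "DYS391": 10.0,
    "DYS392": 11.0,
    "DYS393": 12.0,
    "DYS437": 15.0,
    "DYS438": 10.0,
    "DYS439": 12.0,
    "DYS448": 19.0,
    "DYS456": 15.0,
    "DYS458": 16.0,
    "DYS635": 23.0,
    "Y_GATA_H4": 12.0,
}


def make_hap(sample_id: str, population: str = "Pop", **overrides) -> Haplotype:
    alleles = dict(BASE_PROFILE)
    alleles.update(overrides)
    return Haplotype(sample_id=sample_id, population=population, alleles=alleles)


def make_sample(label: str, haps) -> PopulationSample:
    return PopulationSample(label=label, haplotypes=tuple(haps), panel=YFILER17)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Two modest synthetic populations for integration-style tests."""
    from ystrkit.simulate import (
        DEFAULT_MUT_RATES,
        make_founders,
        simulate_population,
    )

    r = np.random.default_rng(11)
    founders = make_founders(r, 3)
    a = simulate_population("Alpha", 30, founders, [1, 1, 1], 40,
                            DEFAULT_MUT_RATES, r)
    b = simulate_population("Beta", 28, founders, [2, 1, 1], 40,
                            DEFAULT_MUT_RATES, r)
    return [a, b]
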