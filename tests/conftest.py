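import pytest

from aerodep.aerosol import default_products
from aerodep.breathing import measured_profiles
from aerodep.cohort import build_airway_tree, generate_cohort
from aerodep.deposition import RegionalTargets, calibrate
from aerodep.stats import synthetic_paired_depositions


@pytest.fixture(scope="session")
def products():
    return default_products()


@pytest.fixture(scope="session")
def cohort20():
    return generate_cohort(20, seed=1)


@pytest.fixture(scope="session")
def trees20(cohort20):
    return [build_airway_tree(p) for p in cohort20]


@pytest.fixture(scope="session")
def profiles20():
    return measured_profiles(20, seed=1)


@pytest.fixture(scope="session")
def dual_calibration(products, cohort20, trees20, profiles20):
    """Surrogate constants fitted once to the dual product's printed outcomes."""
    return calibrate(
        products["BDP/FF"], RegionalTargets(), cohort20, profiles20, trees=trees20
    )


@pytest.fixture(scope="session")
def synth_table():
    return synthetic_paired_depositions(20, seed=1)
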