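import pytest

from lofclust.cluster import fit_clusterer
from lofclust.profiles import build_profiles
from lofclust.synthetic import (
    CountDistribution,
    SyntheticSpec,
    generate_dataset,
    start_depleted,
    uniform_regime,
    zero_regime,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with all three positional regimes plus a clinical set."""
    spec = SyntheticSpec(
        plof_regimes=(
            (uniform_regime(), 80),
            (start_depleted(), 25),
            (zero_regime(), 15),
        ),
        counts={
            "synonymous": CountDistribution(mean=40.0),
            "missense": CountDistribution(mean=80.0),
            "plof": CountDistribution(kind="uniform_int", low=10, high=50),
            "clinical_plof": CountDistribution(mean=10.0),
        },
        generate_clinical=True,
        seed=5,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return build_profiles(small_cohort.variants, small_cohort.models)


@pytest.fixture(scope="session")
def fitted_model(small_profiles):
    pop = small_profiles[small_profiles["dataset"] == "population"]
    return fit_clusterer(pop, random_state=7)
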