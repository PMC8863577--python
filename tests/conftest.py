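import numpy as np
import pytest

from cardstage import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with all archetypes planted (seeded)."""
    spec = SyntheticSpec(
        group_sizes={"HC": 60, "UMMC": 50, "MMC": 60, "IHD": 60},
        n_features={"taxon": 30, "metabolite": 30},
        archetype_mix={
            "null": 0.4,
            "dmf": 0.15,
            "ihdf": 0.15,
            "escf": 0.1,
            "dscf": 0.1,
            "drug_driven": 0.1,
        },
        effect_size=0.5,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
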