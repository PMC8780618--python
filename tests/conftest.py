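import numpy as np
import pytest

from cohort_demog import (
    IndividualRecord,
    generate_head_capsules,
    paper_morphometry_defaults,
)


@pytest.fixture(scope="session")
def trimodal_sample():
    """98 widths, 3 lognormal components at the published scale, cv 6%."""
    return generate_head_capsules(paper_morphometry_defaults(seed=1))


@pytest.fixture(scope="session")
def unimodal_sample():
    rng = np.random.default_rng(11)
    from cohort_demog import HeadCapsuleSample
    return HeadCapsuleSample(widths=rng.normal(400.0, 30.0, 100).clip(min=1.0))


@pytest.fixture()
def single_female():
    return IndividualRecord("f1", "female", adult_longevity=3.0,
                            daily_eggs=[2, 2, 0])


@pytest.fixture()
def two_females():
    return [
        IndividualRecord("f1", "female", adult_longevity=1.0, daily_eggs=[3]),
        IndividualRecord("f2", "female", adult_longevity=2.0, daily_eggs=[1, 4]),
    ]
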