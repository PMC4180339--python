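import numpy as np
import pytest

from catgrm.core import Item, ItemBank, ResponseMatrix, default_bank
from catgrm.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def bank() -> ItemBank:
    return default_bank()


@pytest.fixture(scope="session")
def item7(bank) -> Item:
    return bank[7]


@pytest.fixture(scope="session")
def clinical_cohort(bank):
    """505-person cohort under the default clinical mixture."""
    return generate_cohort(CohortSpec(n_persons=505, bank=bank, seed=20140911))


@pytest.fixture(scope="session")
def normal_cohort(bank):
    """2000-person cohort with theta ~ N(0,1), matching the MML latent density."""
    return generate_cohort(
        CohortSpec(n_persons=2000, bank=bank, seed=42, theta_mixture=((1.0, 0.0, 1.0),))
    )


@pytest.fixture()
def toy_matrix() -> ResponseMatrix:
    """4 persons x 3 items with a hand-checkable covariance structure."""
    responses = np.array(
        [
            [0, 0, 1],
            [1, 1, 0],
            [2, 1, 2],
            [2, 2, 2],
        ]
    )
    return ResponseMatrix(person_ids=np.arange(1, 5), responses=responses)


@pytest.fixture(scope="session")
def tiny_bank() -> ItemBank:
    """Three 3-category items, symmetric around zero for the EAP symmetry test."""
    return ItemBank(
        (
            Item(1, "a", 1.5, (-1.0, 0.2)),
            Item(2, "b", 2.0, (-0.6, 0.6)),
            Item(3, "c", 1.5, (-0.2, 1.0)),
        )
    )
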