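from datetime import date

import numpy as np
import pytest

import dogyears as dy


@pytest.fixture(scope="session")
def reference_table() -> dy.LifeTable:
    """The packaged UK companion-dog table rebuilt from its d and a columns."""
    return dy.load_reference_aggregates()


@pytest.fixture(scope="session")
def pseudo_cohort(reference_table) -> np.ndarray:
    """Individual lifespans expanded from the aggregate table: every animal
    dying in interval x gets lifespan x + a_x."""
    return np.concatenate(
        [np.full(r.d, r.x + r.a_hat) for r in reference_table.rows]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160101)


def make_record(animal_id="A1", **kw) -> dy.DeathRecord:
    defaults = dict(
        breed="Labrador Retriever",
        sex=dy.Sex.FEMALE,
        neuter_status=dy.NeuterStatus.NEUTERED,
        birth_date=date(2008, 5, 1),
        death_date=date(2018, 5, 1),
        clinical_note="euthanased today",
        treatment_text="pentobarbital",
    )
    defaults.update(kw)
    return dy.DeathRecord(animal_id=animal_id, **defaults)


@pytest.fixture()
def record_factory():
    return make_record
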