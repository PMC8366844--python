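import numpy as np
import pytest

from plantocc.data import DietRecord, env_design
from plantocc.synthetic import default_design, default_truth, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """40 records over 6 species: enough structure for every stage, fast to fit."""
    truth = default_truth(n_species=6, n_pv_axes=2, seed=7)
    design = default_design(n_records=40, n_species=6, seed=7)
    return simulate_dataset(truth, design)


@pytest.fixture(scope="session")
def small_model_inputs(small_bundle):
    b = small_bundle
    return {
        "records": b.records,
        "X_env": env_design(b.records).to_numpy(float),
        "X_sp": b.sp_design.to_numpy(float),
        "species_labels": list(b.species_table.index),
    }


def make_record(record_id="r1", species_id="spA", N=10, y=None, mentioned=False, **kw):
    return DietRecord(
        record_id=record_id, species_id=species_id, N=N, y=y,
        mentioned=mentioned, **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
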