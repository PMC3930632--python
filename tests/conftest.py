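import numpy as np
import pytest

from trawlcontact import (
    HaulRecord,
    SpeciesDataset,
    default_simulation,
    simulate_paired_catch,
)


def make_dataset(rows, species="cod", **kwargs):
    """Build a SpeciesDataset from (haul_id, length, n_exp, n_std) tuples."""
    hauls: dict[str, dict] = {}
    for haul_id, length, n_exp, n_std in rows:
        h = hauls.setdefault(haul_id, {"exp": {}, "std": {}})
        h["exp"][length] = float(n_exp)
        h["std"][length] = float(n_std)
    records = [
        HaulRecord(haul_id=hid, counts_exp=h["exp"], counts_std=h["std"])
        for hid, h in hauls.items()
    ]
    return SpeciesDataset(species=species, hauls=records, **kwargs)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def csv_factory(tmp_path):
    """Write a catch-table CSV from a list of row dicts and return its path."""

    def write(rows, name="catch.csv", columns=None):
        import pandas as pd

        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    return write


@pytest.fixture(scope="session")
def sim_spec():
    """The diagnostic paired-gear configuration at a test-sized effort."""
    return default_simulation(n_fish=20_000, n_hauls=5, seed=11)


@pytest.fixture(scope="session")
def sim_dataset(sim_spec):
    return simulate_paired_catch(sim_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
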