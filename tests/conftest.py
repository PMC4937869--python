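from pathlib import Path

import pytest
from hypothesis import settings

from erconsensus import curation as cur
from erconsensus import reference as ref
from erconsensus import simulate as sim

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_smiles_path() -> Path:
    return DATA_DIR / "fixture_molecules.smi"


@pytest.fixture(scope="session")
def fixture_records(fixture_smiles_path) -> list[cur.RawStructureRecord]:
    return cur.parse_structures(fixture_smiles_path, "smiles")


@pytest.fixture(scope="session")
def small_world() -> sim.SyntheticWorld:
    """A compact synthetic study shared by read-only tests."""
    config = sim.SimulationConfig(n_chemicals=400, seed=11, n_models=10)
    return sim.generate_world(config)


@pytest.fixture(scope="session")
def small_world_entries(small_world) -> list[ref.ActivityEntry]:
    return ref.harmonize_entries(small_world.literature.to_dict("records"))
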