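import numpy as np
import pytest

from simpd.data import AssayDataset, CompoundRecord
from simpd.synth import SeriesConfig, generate, reference_toy_dataset


@pytest.fixture(scope="session")
def toy():
    """The fixed 12-compound toy dataset (3 series + a singleton)."""
    return reference_toy_dataset()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic lead-optimization dataset (4 series, 120 compounds)."""
    return generate(SeriesConfig(n_series=4, compounds_per_series=30, seed=11))


@pytest.fixture(scope="session")
def medium_dataset():
    """Default-size synthetic dataset (8 series, ~500 compounds)."""
    return generate(SeriesConfig(seed=1))


def make_labeled_dataset(n_active: int, n_inactive: int, seed: int = 0) -> AssayDataset:
    """Tiny labeled dataset with trivial molecules, for splitter logic tests."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_active + n_inactive):
        active = i < n_active
        records.append(
            CompoundRecord(
                id=f"M{i:03d}",
                smiles="C" * (2 + i % 5) if i % 2 else "CCO",
                activity=7.0 + rng.normal(0, 0.2) if active else 5.0 + rng.normal(0, 0.2),
                date=int(2000 + i),
            )
        )
    return AssayDataset(records, threshold=6.3)
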