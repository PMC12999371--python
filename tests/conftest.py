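import numpy as np
import pytest

from cemeta import MetaDataset, StudyRecord, bundled_tricco


@pytest.fixture(scope="session")
def tricco() -> MetaDataset:
    """The bundled 16-study wound-intervention dataset."""
    return bundled_tricco()


def make_dataset(delta_c, delta_e, n, **kwargs) -> MetaDataset:
    """Build a dataset from parallel vectors (test helper)."""
    studies = tuple(
        StudyRecord(f"s{i}", float(c), float(e), int(m))
        for i, (c, e, m) in enumerate(zip(delta_c, delta_e, n))
    )
    return MetaDataset(studies, **kwargs)


@pytest.fixture
def random_dataset():
    """Factory for random well-behaved datasets of a given size."""

    def _make(seed: int, m: int = 12) -> MetaDataset:
        rng = np.random.default_rng(seed)
        return make_dataset(
            rng.normal(-500.0, 2000.0, m),
            rng.normal(0.1, 0.4, m),
            rng.integers(10, 400, m),
        )

    return _make
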