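import numpy as np
import pytest

from tmcontact.seqio import MultipleAlignment


def msa_from_columns(*columns: str) -> MultipleAlignment:
    """Build an alignment from per-column residue strings."""
    nrows = len(columns[0])
    rows = tuple(
        (f"r{r}", "".join(col[r] for col in columns)) for r in range(nrows)
    )
    return MultipleAlignment(rows=rows, ncols=len(columns))


@pytest.fixture
def covarying_toy() -> MultipleAlignment:
    """4 rows, 2 columns: X = A,A,C,C against Y = D,D,E,E (MI = 1 bit)."""
    return msa_from_columns("AACC", "DDEE")


@pytest.fixture
def independent_toy() -> MultipleAlignment:
    """4 rows, 2 columns: X = A,A,C,C against Y = D,E,D,E (MI = 0)."""
    return msa_from_columns("AACC", "DEDE")


@pytest.fixture
def tiny_model_config():
    """Small channel counts so training-path tests stay fast."""
    from tmcontact.model import ModelConfig

    return ModelConfig(channels=(8, 16, 8, 16, 16), epochs=30, seed=0,
                       learning_rate=3e-3, batch_size=32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
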