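import numpy as np
import pytest

from codoncall import SyntheticGenomeSpec, generate_genome


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def table15_genome():
    """One table-15 synthetic genome with known truth (seed 7)."""
    return generate_genome(SyntheticGenomeSpec(table_id=15, seed=7))


@pytest.fixture(scope="session")
def table11_genome():
    return generate_genome(SyntheticGenomeSpec(table_id=11, seed=12))
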