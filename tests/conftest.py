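import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cutovir.io_formats import GenomeRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture
def small_genome(rng) -> GenomeRecord:
    return GenomeRecord("g_small", random_seq(rng, 5000))
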