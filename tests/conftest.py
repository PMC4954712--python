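import numpy as np
import pytest

from insjunction.core import GenomicInterval
from insjunction.pipeline import run_cmtx3, run_simulation
from insjunction.synthetic_data import (
    JunctionSpec,
    build_reference,
    cmtx3_reference,
    plant_junction,
)


@pytest.fixture(scope="session")
def cmtx3():
    """Planted preset reference and spec."""
    refs, spec = cmtx3_reference(seed=0)
    return refs, spec


@pytest.fixture(scope="session")
def cmtx3_run():
    """Full preset pipeline at 40x, seed 1 (shared across tests; ~5 s)."""
    return run_cmtx3(coverage=40, seed=1)


@pytest.fixture(scope="session")
def small_genome():
    """A small planted insertion genome for fast simulations."""
    config = {
        "seed": 11,
        "contigs": [
            {"name": "accA", "length": 20000, "offset": 0},
            {"name": "donB", "length": 12000, "offset": 0},
            {"name": "thrC", "length": 1500, "offset": 0},
        ],
    }
    spec = JunctionSpec(
        "accA", 10000, GenomicInterval("donB", 3001, 9000, "+"), microhomology=2
    )
    refs = plant_junction(build_reference(config), spec, seed=7)
    return refs, spec


@pytest.fixture(scope="session")
def small_sim(small_genome):
    refs, spec = small_genome
    truth, records, mut = run_simulation(refs, spec, coverage=30, seed=5)
    return refs, spec, truth, records, mut


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
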