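"""Shared fixtures: synthetic genomes at two scales.

``small_sim`` is a fast desk-scale pair for unit tests; ``default_sim`` is
the full default study condition (2 chromosomes x 2 Mb, 10 planted gaps,
2,194 recurrent sites, error fraction 0.126) used by the end-to-end and
acceptance tests.  Both are session-scoped and seeded.
"""

import numpy as np
import pytest

from asmcurate.align import align_all
from asmcurate.liftover import build_chains
from asmcurate.simulate import SimConfig, simulate

SMALL_PARAMS = dict(
    n_chroms=2,
    chrom_length=300_000,
    gap_count=4,
    gap_len_range=(100, 800),
    flank=2000,
    min_total_aln=3000,
    sv_spec={
        "DEL": (1, (200, 500)),
        "DUP": (1, (200, 500)),
        "INV": (1, (300, 800)),
        "INS": (1, (200, 500)),
    },
    recurrent_site_count=300,
    decoy_site_count=60,
    n_strains=24,
    reference_error_fraction=0.126,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SimConfig(**SMALL_PARAMS))


@pytest.fixture(scope="session")
def small_chainset(small_sim):
    return build_chains(align_all(small_sim.assembly, small_sim.reference))


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_chainset(default_sim):
    return build_chains(align_all(default_sim.assembly, default_sim.reference))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
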