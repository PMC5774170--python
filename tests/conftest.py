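import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panforge import (
    BuildParams,
    SimParams,
    filter_short_contigs,
    iterate_pangenome,
    simulate_species,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


# --- study-condition simulation: 200 kb core, 10 strains, snp 0.005, ---
# --- indel 0.0005, 1-3 accessory segments of 2-10 kb per strain       ---

@pytest.fixture(scope="session")
def sim_default():
    return simulate_species(SimParams(seed=42))


@pytest.fixture(scope="session")
def build_states_default(sim_default):
    genomes, _ = sim_default
    return list(iterate_pangenome(genomes, BuildParams()))


@pytest.fixture(scope="session")
def pan_default(build_states_default):
    return filter_short_contigs(build_states_default[-1], BuildParams().min_contig_len)


# --- mutation-free variant (accessory content only) ---

@pytest.fixture(scope="session")
def sim_clean():
    return simulate_species(SimParams(snp_rate=0.0, indel_rate=0.0, seed=42))


@pytest.fixture(scope="session")
def pan_clean(sim_clean):
    genomes, _ = sim_clean
    pan = None
    for pan in iterate_pangenome(genomes, BuildParams()):
        pass
    return filter_short_contigs(pan, BuildParams().min_contig_len)


# --- a small, fast species for unit-level checks ---

@pytest.fixture(scope="session")
def sim_small():
    return simulate_species(
        SimParams(core_len=20_000, n_strains=4, accessory_len=(1000, 3000), seed=7)
    )
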