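import numpy as np
import pytest

from numtrack import assembly
from numtrack.aligner import scan_genome
from numtrack.model import ScoringScheme
from numtrack.simulate import generate

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitution-only mutation helper for alignment tests."""
    out = list(seq)
    n = int(round(divergence * len(seq)))
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def small_genome():
    """120 kb chromosome with 6 low-divergence implants (some split)."""
    return generate(
        genome_size=120_000,
        n_implants=6,
        length_range=(300, 2000),
        divergence_range=(0.0, 0.05),
        duplication_rate=0.0,
        split_rate=0.3,
        spacer_range=(100, 1500),
        seed=11,
    )


@pytest.fixture(scope="session")
def pipeline_comp(small_genome):
    """scan -> assemble -> assign_ids on the small synthetic genome."""
    hsps = scan_genome(
        small_genome.mtdna, small_genome.nuclear, ScoringScheme()
    )
    records = assembly.assemble(hsps)
    return assembly.assign_ids(records, "Hsa", species="synthetic", genome_build="sim1")
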