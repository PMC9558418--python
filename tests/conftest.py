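import numpy as np
import pytest

from neoenhancer import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome():
    """100 kb genome with a handful of planted runs on both strands."""
    spec = syn.GenomeSpec(
        lengths={"chr1": 60_000, "chr2": 40_000},
        planted=(
            syn.PlantedRun("chr1", 1_000, 25),
            syn.PlantedRun("chr1", 10_000, 4),
            syn.PlantedRun("chr1", 30_000, 17, "-"),
            syn.PlantedRun("chr2", 5_000, 6),
            syn.PlantedRun("chr2", 20_000, 10, "-"),
        ),
    )
    return syn.make_genome(spec, seed=42)


def random_dna(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), size=n, p=list(p)))
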