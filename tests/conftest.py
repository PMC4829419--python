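import numpy as np
import pandas as pd
import pytest

from mztkit.repeats import RepeatAnnotation
from mztkit.sim import RepeatGenomeConfig, simulate_repeat_genome


@pytest.fixture(scope="session")
def identical_copy_genome():
    """2 families x 3 identical copies: every in-copy read maps 3 times."""
    config = RepeatGenomeConfig(
        n_families=2,
        copies_per_family=3,
        copy_length=120,
        intra_family_identity=1.0,
        genome_length=3000,
        seed=7,
    )
    genome, annotation, rrna = simulate_repeat_genome(config)
    return genome, annotation, rrna, config


@pytest.fixture(scope="session")
def divergent_genome():
    """5 families x 4 copies at 98% identity on a 20 kb genome."""
    config = RepeatGenomeConfig(
        n_families=5,
        copies_per_family=4,
        copy_length=300,
        intra_family_identity=0.98,
        genome_length=20_000,
        seed=11,
    )
    genome, annotation, rrna = simulate_repeat_genome(config)
    return genome, annotation, rrna, config


@pytest.fixture
def toy_annotation():
    return RepeatAnnotation(
        pd.DataFrame(
            {
                "reference": ["chr1", "chr1", "chr2"],
                "start": [90, 500, 10],
                "end": [400, 700, 200],
                "family": ["L1", "B1", "L1"],
                "repeat_class": ["LINE", "SINE", "LINE"],
            }
        )
    )


def brute_force_hits(genome: str, read_seq: str):
    """Sliding-window oracle: all zero-mismatch locations, both strands."""
    from mztkit.mapping import revcomp

    L = len(read_seq)
    hits = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for i in range(len(genome) - L + 1):
            if genome[i : i + L] == seq:
                hits.append((i, i + L, strand))
    return sorted(hits)
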