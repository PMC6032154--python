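import numpy as np
import pytest

from ggapnb import (
    Feature,
    GGapPattern,
    PlantedMotif,
    SequenceRecord,
    SimulationConfig,
    admissible_patterns,
    build_vocabulary,
    generate,
)


@pytest.fixture(scope="session")
def full_vocab():
    """The default ten-pattern vocabulary (49,220 features)."""
    return build_vocabulary(admissible_patterns())


@pytest.fixture(scope="session")
def small_vocab():
    """A 820-column vocabulary (x, xx, x-x) for cheap pipeline tests."""
    return build_vocabulary(
        [GGapPattern("x"), GGapPattern("xx"), GGapPattern("x-x")]
    )


@pytest.fixture(scope="session")
def planted_config():
    """Strongly separable study conditions: three motifs in the positives."""
    motifs = [
        PlantedMotif(Feature(GGapPattern("x--x"), ("A", "C")), 0.3, 1),
        PlantedMotif(Feature(GGapPattern("xx"), ("W", "W")), 0.3, 1),
        PlantedMotif(Feature(GGapPattern("x-x-x"), ("M", "H", "M")), 0.3, 1),
    ]
    return SimulationConfig(
        n_pos=60, n_neg=60, length_range=(100, 300), planted=motifs, seed=7
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return generate(planted_config)


def random_records(rng: np.random.Generator, n: int, lo: int = 5, hi: int = 50):
    """Uniform-background records for property checks."""
    from ggapnb import AMINO_ACIDS

    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        out.append(SequenceRecord(f"r{i}", seq))
    return out
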