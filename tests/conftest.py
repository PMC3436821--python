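import numpy as np
import pytest

from ibbpair import CountMatrix, FeaturePairSet, PairedCountTable, PairingDesign

WORKED_TOTAL = 13_331_120
WORKED_COUNTS = [(57, 95), (27, 50), (55, 135)]


@pytest.fixture
def worked_example() -> FeaturePairSet:
    """Three down-regulated pairs with a common normalized total."""
    return FeaturePairSet(
        "gene1",
        tuple(
            PairedCountTable(a, b, WORKED_TOTAL, WORKED_TOTAL, f"subject{i + 1}")
            for i, (a, b) in enumerate(WORKED_COUNTS)
        ),
    )


@pytest.fixture
def small_matrix() -> tuple[CountMatrix, PairingDesign]:
    """One feature, three subjects, six samples."""
    counts = np.array([[57, 95, 27, 50, 55, 135]])
    samples = ["p1_b", "p1_a", "p2_b", "p2_a", "p3_b", "p3_a"]
    matrix = CountMatrix(
        ["gene1"], samples, counts, np.full(6, WORKED_TOTAL, dtype=np.int64)
    )
    design = PairingDesign(
        [
            ("p1_b", "subject1", "before"),
            ("p1_a", "subject1", "after"),
            ("p2_b", "subject2", "before"),
            ("p2_a", "subject2", "after"),
            ("p3_b", "subject3", "before"),
            ("p3_a", "subject3", "after"),
        ]
    )
    return matrix, design


def random_table(rng: np.random.Generator, max_s: int = 40) -> PairedCountTable:
    s = int(rng.integers(1, max_s + 1))
    a = int(rng.integers(0, s + 1))
    t_a = int(rng.integers(s + 1, 10 * s + 100))
    t_b = int(rng.integers(s + 1, 10 * s + 100))
    return PairedCountTable(a, s - a, t_a, t_b, "x")


def random_pair_set(
    rng: np.random.Generator, n_pairs: int = 4, max_s: int = 40
) -> FeaturePairSet:
    pairs = tuple(
        PairedCountTable(
            t.before, t.after, t.total_before, t.total_after, f"s{i}"
        )
        for i, t in enumerate(random_table(rng, max_s) for _ in range(n_pairs))
    )
    return FeaturePairSet("f", pairs)
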