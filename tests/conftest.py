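import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spliceland import DictGenome, HexamerTable
from spliceland.hexamers import all_hexamers

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def constant_table():
    return HexamerTable.constant(0.2)


@pytest.fixture(scope="session")
def toy3_table():
    """Three scored hexamers, everything else 0."""
    return HexamerTable.filled(
        {"ACGTAC": 1.0, "CGTACG": -0.5, "GTACGT": 0.25}, source_label="toy3"
    )


@pytest.fixture(scope="session")
def random_table():
    """Complete table with seeded standard-normal scores."""
    rng = np.random.default_rng(12345)
    return HexamerTable(
        {h: float(s) for h, s in zip(all_hexamers(), rng.normal(0, 0.5, 4096))},
        source_label="random-seeded",
    )


def brute_force_per_nt(seq, table, left="", right="", aggregate="mean"):
    """Independent oracle: enumerate every covering hexamer per position."""
    left = left[-5:] if left else ""
    right = right[:5] if right else ""
    padded = left + seq + right
    windows = [(w, padded[w : w + 6]) for w in range(len(padded) - 5)]
    out = []
    off = len(left)
    for i in range(len(seq)):
        j = off + i
        cov = [table[h] for w, h in windows if w <= j <= w + 5 and "N" not in h]
        if not cov:
            out.append(0.0)
        elif aggregate == "mean":
            out.append(sum(cov) / len(cov))
        else:
            out.append(sum(cov))
    return np.array(out)


def brute_force_window_total(seq, table):
    """Independent oracle: sum of all 6-mer window scores of a sequence."""
    return sum(table[seq[i : i + 6]] for i in range(len(seq) - 5))


@pytest.fixture
def rng():
    return np.random.default_rng(777)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
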