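import numpy as np
import pandas as pd
import pytest

from peptarray import ToxinRecord, build_library


def make_signal_frame(rows):
    """rows: (peptide_sequence, class, replicate, intensity)."""
    return pd.DataFrame(
        rows, columns=["peptide_sequence", "class", "replicate", "intensity"]
    )


def median_table_from(medians: dict, classes: dict | None = None) -> pd.DataFrame:
    """Hand-built median table: peptide -> median (class defaults to wt)."""
    classes = classes or {}
    return pd.DataFrame(
        {
            "median": list(medians.values()),
            "sd": 0.0,
            "n": 5,
            "class": [classes.get(p, "wt") for p in medians],
        },
        index=pd.Index(medians.keys(), name="peptide_sequence"),
    )


def random_toxins(rng, n, lo=12, hi=40, prefix="T"):
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(
            ToxinRecord(
                accession=f"{prefix}{i}",
                sequence="".join(rng.choice(alphabet, size=length)),
            )
        )
    return out


@pytest.fixture
def two_tile_toxin():
    """Length-14 toxin producing exactly two tiles (starts 1 and 3)."""
    return ToxinRecord(accession="TOX14", sequence="ACDEFGHIKLMNPQ")


@pytest.fixture
def small_library(two_tile_toxin):
    return build_library([two_tile_toxin], seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
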