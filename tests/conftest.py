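import numpy as np
import pandas as pd
import pytest

from assemblyproc.io_formats import OtuTable, parse_tree


@pytest.fixture
def four_tip_tree():
    """Balanced 4-tip tree with unit branch lengths; total length 6."""
    return parse_tree("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def toy_table():
    counts = np.array([
        [5, 3, 1, 0],
        [0, 2, 4, 1],
        [7, 0, 0, 2],
    ])
    return OtuTable(("s1", "s2", "s3"), ("A", "B", "C", "D"), counts)


@pytest.fixture
def toy_meta():
    df = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "host_species": ["ce", "ce", "me"],
        "site": ["x", "y", "x"],
        "latitude": [25.0, 30.0, 25.0],
        "longitude": [110.0, 112.0, 110.0],
        "mat": [24.0, 20.0, 24.0],
        "map_mm": [1600.0, 1400.0, 1600.0],
        "haplotype": ["h1", "h1", "h2"],
    })
    return df.set_index("sample_id")


def random_table(rng, n_samples=4, n_otus=6, max_count=9):
    """Random valid OtuTable (each sample has at least one read)."""
    while True:
        counts = rng.integers(0, max_count + 1, size=(n_samples, n_otus))
        if (counts.sum(axis=1) > 0).all():
            break
    return OtuTable(
        tuple(f"s{i}" for i in range(n_samples)),
        tuple(f"o{j}" for j in range(n_otus)),
        counts,
    )
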