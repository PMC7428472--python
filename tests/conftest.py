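import numpy as np
import pandas as pd
import pytest

from crosskingdom.table_io import AbundanceTable, SampleMetadata


@pytest.fixture
def tiny_bact():
    data = pd.DataFrame(
        [[5, 0, 3, 2],
         [1, 4, 0, 5],
         [2, 2, 2, 2],
         [0, 1, 7, 2],
         [3, 3, 1, 3],
         [4, 0, 0, 6]],
        index=[f"s{i}" for i in range(1, 7)],
        columns=["TaxA", "TaxB", "TaxC", "TaxD"],
    )
    taxonomy = {
        "TaxA": "k__Bacteria; p__Firmicutes; c__; o__; f__Lachnospiraceae; g__TaxA",
        "TaxB": "k__Bacteria; p__Firmicutes; c__; o__; f__Lachnospiraceae; g__TaxB",
        "TaxC": "k__Bacteria; p__Bacteroidetes; c__; o__; f__; g__TaxC",
        "TaxD": "k__Bacteria; p__Bacteroidetes; c__; o__; f__; g__TaxD",
    }
    return AbundanceTable(data, "bacteria", taxonomy)


@pytest.fixture
def tiny_fungi():
    data = pd.DataFrame(
        [[2, 1], [0, 3], [4, 4], [1, 0], [2, 5], [3, 1]],
        index=[f"s{i}" for i in range(1, 7)],
        columns=["FunA", "FunB"],
    )
    return AbundanceTable(data, "fungi")


@pytest.fixture
def tiny_meta():
    frame = pd.DataFrame(
        {"group": ["case", "case", "case", "ctrl", "ctrl", "ctrl"]},
        index=[f"s{i}" for i in range(1, 7)],
    )
    return SampleMetadata(frame)


def two_group_table(rng, n1=12, n2=12, n_taxa=20, scale=200):
    """Exchangeable random count table plus metadata, for null checks."""
    counts = rng.poisson(scale, size=(n1 + n2, n_taxa))
    ids = [f"s{i}" for i in range(n1 + n2)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=ids, columns=[f"t{j}" for j in range(n_taxa)]),
        "bacteria",
    )
    meta = SampleMetadata(
        pd.DataFrame({"group": ["a"] * n1 + ["b"] * n2}, index=ids))
    return table, meta
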