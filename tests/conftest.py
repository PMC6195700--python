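import numpy as np
import pandas as pd
import pytest

from lotteryassembly import AbundanceTable, Lineage


@pytest.fixture
def tiny_lineages():
    """Three OTUs: two in genus g__A, one in g__B, all in family f__F."""
    gg = "k__Bacteria; p__P; c__C; o__O; f__F; g__{}"
    return {
        "otu1": Lineage.from_greengenes(gg.format("A")),
        "otu2": Lineage.from_greengenes(gg.format("A")),
        "otu3": Lineage.from_greengenes(gg.format("B")),
    }


@pytest.fixture
def tiny_table():
    """3 features x 4 samples, relative abundances (columns sum to 1)."""
    data = pd.DataFrame(
        {
            "s1": [0.95, 0.03, 0.02],
            "s2": [0.10, 0.85, 0.05],
            "s3": [0.50, 0.30, 0.20],
            "s4": [0.02, 0.01, 0.97],
        },
        index=["otu1", "otu2", "otu3"],
    )
    return AbundanceTable(data, "relative")


def random_relative_table(rng: np.random.Generator, n_features: int, n_samples: int):
    """Random relative table (columns sum to 1) with generic feature ids."""
    raw = rng.gamma(0.5, size=(n_features, n_samples))
    raw /= raw.sum(axis=0)
    fids = [f"otu{i:03d}" for i in range(n_features)]
    sids = [f"s{j:03d}" for j in range(n_samples)]
    return AbundanceTable(pd.DataFrame(raw, index=fids, columns=sids), "relative")


def random_lineages(rng: np.random.Generator, feature_ids, n_genera: int):
    """Assign features to random genera nested under two families."""
    out = {}
    for fid in feature_ids:
        gi = int(rng.integers(n_genera))
        fam = gi % 2
        out[fid] = Lineage.from_ranks(
            kingdom="k__Bacteria", phylum="p__P", **{"class": "c__C"},
            order="o__O", family=f"f__F{fam}", genus=f"g__G{gi}")
    return out
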