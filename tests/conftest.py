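import numpy as np
import pandas as pd
import pytest

from clrbalance.tables_io import CountTable, parse_lineage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_lineages():
    labels = [
        "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia/Dorea;Blautia/Dorea_u",
        "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Roseburia;Roseburia_u",
        "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Roseburia;SpeciesX",
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus_u",
    ]
    return labels


@pytest.fixture
def small_count_table(small_lineages):
    counts = pd.DataFrame(
        [[3, 10, 0], [5, 0, 7], [2, 1, 9], [0, 4, 11]],
        index=small_lineages, columns=["s1", "s2", "s3"],
    )
    lineages = {t: parse_lineage(t) for t in small_lineages}
    return CountTable(counts, rank="species", lineages=lineages)


def random_count_table(rng, n_taxa=12, n_samples=6, max_count=50):
    from clrbalance.synthetic_data import make_taxonomy

    taxa = make_taxonomy(n_taxa)
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_taxa, n_samples)),
        index=taxa, columns=[f"s{i}" for i in range(n_samples)],
    )
    # keep every sample non-empty
    counts.iloc[0, :] += 1
    return CountTable(counts, rank="species",
                      lineages={t: parse_lineage(t) for t in taxa})
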