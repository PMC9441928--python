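import numpy as np
import pandas as pd
import pytest

from rootpheno.traits import genotype_means, validate_table


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Two genotypes × two treatments × two replicates, two traits."""
    rows = []
    values = {
        ("g1", "WW"): [(10.0, 0.8), (12.0, 0.9)],
        ("g1", "D"): [(4.0, 0.7), (6.0, 0.6)],
        ("g2", "WW"): [(8.0, 1.0), (9.0, 1.1)],
        ("g2", "D"): [(5.0, 0.9), (5.5, 0.8)],
    }
    for (g, trt), reps in values.items():
        for i, (bm, rx) in enumerate(reps):
            rows.append(dict(experiment="E1", genotype=g, treatment=trt,
                             replicate=f"r{i + 1}", biomass=bm, RXSA=rx))
    return validate_table(pd.DataFrame(rows))


@pytest.fixture
def small_means(small_table) -> pd.DataFrame:
    return genotype_means(small_table)


def make_means(experiment: str, trait: str, by_genotype: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a genotype-means frame from {genotype: {treatment: mean}}."""
    rows = []
    for g, trts in by_genotype.items():
        for trt, m in trts.items():
            rows.append(dict(experiment=experiment, genotype=g, treatment=trt,
                             trait=trait, mean=m, sd=0.0, n=3, single_rep=False))
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
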