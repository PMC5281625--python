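import numpy as np
import pandas as pd
import pytest

from corrosomics.feature_pipeline import FeatureTable, filter_low_abundance
from corrosomics.annotate import fit_rt_model
from corrosomics.synthetic_data import GeneratorConfig, simulate_metabolome


def make_table(masses, rts, modes, abundances, samples=("LC3", "LC11", "HC3", "HC11"), replicates=3):
    """Build a small FeatureTable from per-feature per-sample mean abundances.

    ``abundances`` is a list (per feature) of dicts sample -> mean; every
    replicate gets the mean value exactly.
    """
    n = len(masses)
    ids = [f"F{k + 1:03d}" for k in range(n)]
    features = pd.DataFrame(
        {"neutral_mass_da": masses, "rt_min": rts, "ion_mode": modes},
        index=pd.Index(ids, name="feature_id"),
    )
    columns = pd.MultiIndex.from_product([list(samples), list(range(1, replicates + 1))], names=["sample", "replicate"])
    data = np.zeros((n, len(columns)))
    for i, per_sample in enumerate(abundances):
        for j, (s, _r) in enumerate(columns):
            data[i, j] = per_sample.get(s, 0.0)
    return FeatureTable(features=features, abundances=pd.DataFrame(data, index=features.index, columns=columns))


@pytest.fixture(scope="session")
def bundle():
    """One seeded full metabolome simulation shared across the suite."""
    return simulate_metabolome(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def filtered_table(bundle):
    table, _report = filter_low_abundance(bundle.table, 1000.0)
    return table


@pytest.fixture(scope="session")
def rt_model(bundle):
    X, y = bundle.standards
    return fit_rt_model(X, y)
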