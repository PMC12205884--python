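import warnings

import numpy as np
import pandas as pd
import pytest

from crossgp import genoqc
from crossgp.matrix import GenotypeMatrix
from crossgp.simdata import SimConfig, TraitSpec, simulate_dataset


def toy_matrix(calls, batch="toy", chrom=None, alleles=None, genotypes=None, series=None):
    """Small GenotypeMatrix from a nested list (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in calls]
    )
    n_g, n_m = arr.shape
    genotypes = genotypes or [f"g{i + 1}" for i in range(n_g)]
    alleles = alleles or [("A", "G")] * n_m
    markers = pd.DataFrame(
        {
            "chrom": chrom or ["1A"] * n_m,
            "pos": np.arange(1, n_m + 1) * 1000,
            "allele1": [a for a, _ in alleles],
            "allele2": [b for _, b in alleles],
        },
        index=pd.Index([f"m{j + 1}" for j in range(n_m)], name="marker"),
    )
    return GenotypeMatrix(genotypes, markers, arr, series, batch)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_series=3,
        genotypes_per_series=(80, 80, 80),
        n_markers=400,
        n_founders=40,
        n_locations=3,
        stages=((0.5, 2, 1), (0.3, 4, 1), (0.2, 6, 2)),
        traits=(TraitSpec(h2_target=0.8),),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def merged_matrix(small_dataset):
    filtered = [genoqc.filter_batch(b)[0] for b in small_dataset.batches]
    plan = genoqc.build_harmonization_plan(filtered)
    return genoqc.merge_batches(filtered, plan)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
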