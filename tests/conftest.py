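"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import crossmosaic as cm


@pytest.fixture(scope="session")
def two_pools():
    """Two divergent pools (EU, IND) on one 100 cM chromosome, 2,000 sites."""
    pools, gmap = cm.make_ancestral_pools(
        2, 60, 2000, divergence=0.3, seed=1, names=["EU", "IND"]
    )
    return pools, gmap


@pytest.fixture(scope="session")
def pool_freqs(two_pools):
    pools, _ = two_pools
    return pd.DataFrame({p.name: p.allele_freqs for p in pools})


@pytest.fixture(scope="session")
def three_pools():
    """Three pools mimicking European taurine / African taurine / indicus."""
    pools, gmap = cm.make_ancestral_pools(
        3, 60, 2000, divergence=(0.2, 0.3, 0.45), seed=2, names=["EU", "AFT", "BI"]
    )
    return pools, gmap


@pytest.fixture(scope="session")
def f1_cohort(two_pools):
    pools, gmap = two_pools
    return cm.make_cross(cm.CrossSpec.f1("EU", "IND", 40, seed=3), pools, gmap)


@pytest.fixture(scope="session")
def bc1_cohort(two_pools):
    """BC1 = F1(EU, IND) x pure IND; EU proportion varies around 0.25."""
    pools, gmap = two_pools
    return cm.make_cross(
        cm.CrossSpec.bc1("EU", "IND", 60, seed=4, recurrent="IND"), pools, gmap
    )


@pytest.fixture(scope="session")
def mixed_cohort(two_pools):
    """Pure + F1 + F2 + both BC1 directions, concatenated."""
    pools, gmap = two_pools
    parts = [
        cm.make_cross(cm.CrossSpec.pure("EU", 15, seed=5), pools, gmap),
        cm.make_cross(cm.CrossSpec.pure("IND", 15, seed=5), pools, gmap),
        cm.make_cross(cm.CrossSpec.f1("EU", "IND", 20, seed=5), pools, gmap),
        cm.make_cross(cm.CrossSpec.f2("EU", "IND", 20, seed=5), pools, gmap),
        cm.make_cross(cm.CrossSpec.bc1("EU", "IND", 20, seed=5, recurrent="IND"), pools, gmap),
        cm.make_cross(cm.CrossSpec.bc1("EU", "IND", 20, seed=5, recurrent="EU"), pools, gmap),
    ]
    return cm.concat_cohorts(parts)


def toy_matrix(genotypes, cm_start=0.0):
    """GenotypeMatrix from a plain nested list, sites on one chromosome."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = g.shape
    sites = pd.DataFrame(
        {
            "chrom": ["1"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 1000,
            "cm": np.linspace(cm_start, cm_start + n_sites - 1, n_sites),
        }
    )
    return cm.GenotypeMatrix(g, [f"i{k}" for k in range(n_ind)], sites)
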