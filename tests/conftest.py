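import numpy as np
import pandas as pd
import pytest

import microbiability as mb


@pytest.fixture(scope="session")
def small_spec():
    """A compact linked dataset spec reused across modules."""
    return mb.SimSpec(
        n_individuals=150,
        n_snps=400,
        n_taxa=30,
        taxon_h2=np.r_[np.full(10, 0.4), np.zeros(20)],
        taxon_prevalence=np.full(30, 0.9),
        n_mediators=2,
        mediator_config=[
            mb.MediatorConfig(taxa=["taxon01"], coefficients=[0.6], name="butyrate"),
            mb.MediatorConfig(taxa=["taxon02"], coefficients=[0.0], name="acetate"),
        ],
        trait_config=[
            mb.TraitConfig(h2_true=0.4, m2_true=0.1, mediator_paths=[0.4, 0.0],
                           name="semen_volume"),
            mb.TraitConfig(h2_true=0.1, m2_true=0.4, name="motility"),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return mb.simulate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    return mb.build_grm(small_dataset.genotypes)


@pytest.fixture()
def two_sample_table():
    """Two samples, one taxon, abundances 0.1 and 0.3."""
    return mb.AbundanceTable(
        pd.DataFrame({"taxA": [0.1, 0.3]}, index=["s1", "s2"])
    )


def random_abundance_table(rng, n, v):
    """Random strictly positive compositions (helper for property tests)."""
    raw = rng.gamma(2.0, 1.0, size=(n, v)) + 1e-6
    rel = raw / raw.sum(axis=1, keepdims=True)
    return mb.AbundanceTable(
        pd.DataFrame(rel, index=[f"s{i}" for i in range(n)],
                     columns=[f"t{j}" for j in range(v)])
    )
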