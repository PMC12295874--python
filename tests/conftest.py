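import numpy as np
import pandas as pd
import pytest

from epireg import synth
from epireg.mcfs import MCFSParams

# Small, fast study conditions shared across tests; the planted effect size
# and cohort composition mirror the package defaults at reduced width.
SMALL_SPEC = synth.CohortSpec(
    n_cancer=100, n_normal=20, p_mrna=220, p_mirna=220, p_meth=220,
    k_informative=20, effect_size=2.0, seed=7, n_regulated_targets=10)

FAST_MCFS = MCFSParams(m=50, projections_per_feature=5, t=3, n_perm=10,
                       seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return synth.generate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_genome(small_cohort):
    matrices, _, _ = small_cohort
    return synth.generate_genome_fixture(
        n_chrom=2, genes=20, cpgi=30, seed=11, chrom_length=3_000_000,
        meth_ids=matrices["meth"].features)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
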