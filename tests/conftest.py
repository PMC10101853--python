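import numpy as np
import pytest

import mesoaxes as mx
from mesoaxes import cimp as cimp_mod
from mesoaxes import factor as factor_mod
from mesoaxes import preprocess as pre_mod


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort (n=120, seed 1) shared across tests."""
    return mx.generate_dataset(mx.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def preprocessed_views(default_dataset):
    ds = default_dataset
    expr = pre_mod.filter_expression(ds.expression, ds.expression_fpkm)
    meth = pre_mod.filter_methylation(ds.meth_beta, ds.meth_M, ds.region_map)
    cn_adj = pre_mod.gene_level_copy_number(
        ds.copy_number, mx.PurityTable(purity=ds.purity, ploidy=ds.truth.ploidy_true)
    )
    cn = pre_mod.group_and_select_cn(cn_adj)
    views = {
        "expression": pre_mod.center_view(expr),
        **{k: pre_mod.center_view(v) for k, v in meth.items()},
        "copy_number": cn,
    }
    return views


@pytest.fixture(scope="session")
def fitted_model(preprocessed_views):
    return factor_mod.fit_multiview_factors(preprocessed_views, K=10, seed=1)


@pytest.fixture(scope="session")
def cimp_result(default_dataset):
    return cimp_mod.compute_cimp(default_dataset.meth_beta, default_dataset.island_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
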