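import warnings

import numpy as np
import pytest

import effconn as ec


@pytest.fixture(scope="session")
def default_spec():
    """Study-condition cohort spec: 24 subjects, 160 nodes, 240 volumes."""
    return ec.CohortSpec(seed=20160552)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ec.simulate_cohort(default_spec)


@pytest.fixture(scope="session")
def subject_graphs(default_cohort):
    """Thresholded graph series (default grid) for every subject."""
    grid = ec.SparsityGrid()
    cfg = ec.ConditioningConfig()
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts, nuis in zip(default_cohort.series, default_cohort.nuisance):
            cond = ec.condition_series(ts, nuis, cfg)
            out.append(ec.threshold_series(ec.correlation_matrix(cond), grid))
    return out


@pytest.fixture(scope="session")
def normalized_local(default_cohort, subject_graphs):
    """Subject x node matrix of integrated, normalized nodal local efficiency."""
    n_sub = default_cohort.spec.n_subjects
    n_nodes = default_cohort.spec.n_nodes
    local = np.empty((n_sub, n_nodes))
    for s, graphs in enumerate(subject_graphs):
        curves = ec.nodal_curves(graphs)
        local[s] = ec.integrate_and_normalize(curves)["e_loc_normalized"]
    return local


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
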