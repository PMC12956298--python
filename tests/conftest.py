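"""Shared fixtures: desk-scale oracle cohorts and their fits.

The default-scale cohort (80 nodes / 20 DMN / 15 subjects per group,
sigma_e = 0.05, sigma_b = 0.02) is expensive enough to build once per
session; smaller cohorts are used wherever replicate loops are needed.
"""

import numpy as np
import pytest

import netlmm as nl


@pytest.fixture(scope="session")
def nodes80():
    return nl.generate_node_layout(80, 20, 160.0, seed=7)


@pytest.fixture(scope="session")
def subjects15():
    return nl.generate_subject_table(15, seed=1)


@pytest.fixture(scope="session")
def m1_cohort(nodes80, subjects15):
    """Default oracle cohort with published-scale group-difference truths."""
    return nl.simulate_oracle_cohort(
        nodes80, subjects15, nl.default_ground_truth("model1", seed=42)
    )


@pytest.fixture(scope="session")
def m1_table(m1_cohort):
    return m1_cohort.edge_table()


@pytest.fixture(scope="session")
def m1_design(m1_table):
    return nl.assemble_design_matrix(m1_table, "model1")


@pytest.fixture(scope="session")
def m1_fit(m1_design):
    return nl.fit_lmm(m1_design)


@pytest.fixture(scope="session")
def m2_cohort(nodes80, subjects15):
    """Oracle cohort whose GlobalT-moderation truths are the published ones."""
    return nl.simulate_oracle_cohort(
        nodes80, subjects15, nl.default_ground_truth("model2", seed=43)
    )


@pytest.fixture(scope="session")
def m2_fit(m2_cohort):
    return nl.fit_lmm(nl.assemble_design_matrix(m2_cohort.edge_table(), "model2"))


@pytest.fixture(scope="session")
def small_cohort():
    """30-node / 8-DMN / 5-per-group cohort for cheap structural tests."""
    nodes = nl.generate_node_layout(30, 8, 160.0, seed=11)
    subjects = nl.generate_subject_table(5, seed=3)
    truth = nl.truth_from_contrasts("model1", seed=4)
    return nl.simulate_oracle_cohort(nodes, subjects, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
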