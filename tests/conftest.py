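"""Shared fixtures: the full-scale synthetic cohort and derived objects.

Session-scoped because the gradient cohort (441 samples) and its distance
matrix / CAG model feed many recovery tests; each is computed once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cagscape as cs

GRADIENT_SEED = 42
CLUSTERS_SEED = 7


@pytest.fixture(scope="session")
def gradient_bundle() -> cs.synthetic_data.SyntheticBundle:
    return cs.simulate_all(cs.SimulationConfig(seed=GRADIENT_SEED))


@pytest.fixture(scope="session")
def gradient_rel(gradient_bundle):
    return cs.to_relative(gradient_bundle.table)


@pytest.fixture(scope="session")
def gradient_filtered(gradient_bundle, gradient_rel):
    return cs.filter_by_median_abundance(gradient_rel, 1e-4)


@pytest.fixture(scope="session")
def gradient_jsd(gradient_rel):
    return cs.jsd_sqrt_matrix(gradient_rel)


@pytest.fixture(scope="session")
def gradient_scan(gradient_jsd):
    return cs.enterotype_scan(gradient_jsd, 2, 20)


@pytest.fixture(scope="session")
def clusters_scan():
    table, _ = cs.simulate_community(
        cs.SimulationConfig(seed=CLUSTERS_SEED, mode="clusters")
    )
    jsd = cs.jsd_sqrt_matrix(cs.to_relative(table))
    return cs.enterotype_scan(jsd, 2, 20)


@pytest.fixture(scope="session")
def cag_model(gradient_filtered):
    rho = cs.spearman_coabundance(gradient_filtered)
    return cs.ward_cags(rho, gradient_filtered, 5)


@pytest.fixture(scope="session")
def dominance_selection(cag_model):
    return cs.select_dominated(cag_model.profile)


@pytest.fixture(scope="session")
def cag_to_block(gradient_bundle, cag_model):
    """Majority planted block behind each discovered CAG."""
    blocks = gradient_bundle.truth.block_of_otu
    return {
        label: int(blocks.loc[cag_model.membership[cag_model.membership == label].index].mode()[0])
        for label in cag_model.names
    }


def small_table(values, mode="counts", prefix="S", otu_prefix="O"):
    """Helper to build tiny AbundanceTables inline."""
    values = np.asarray(values, dtype=float)
    return cs.AbundanceTable(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i + 1}" for i in range(values.shape[0])],
            columns=[f"{otu_prefix}{j + 1}" for j in range(values.shape[1])],
        ),
        mode=mode,
    )
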