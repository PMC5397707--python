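"""Shared fixtures: bundled count tables and simulated gene sets.

The three simulated datasets (one per generator regime) and the full
pipeline runs on them are session-scoped: they are the expensive shared
inputs for both the module tests and the end-to-end acceptance tests.
"""

from decimal import ROUND_HALF_UP, Decimal

import pytest

from cubkit import datasets
from cubkit.pipeline import analyze
from cubkit.synthetic_data import SimConfig, simulate


def round_half_up(x: float, places: int = 2) -> float:
    return float(
        Decimal(repr(float(x))).quantize(
            Decimal(f"1e-{places}"), rounding=ROUND_HALF_UP
        )
    )


@pytest.fixture(scope="session")
def codon_usage_df():
    return datasets.load_codon_usage()


@pytest.fixture(scope="session")
def pools_df():
    return datasets.load_expression_pools()


@pytest.fixture(scope="session")
def pool_tables():
    return datasets.pool_counts()


@pytest.fixture(scope="session")
def sim_mutation():
    return simulate(SimConfig.mutation_only(n_genes=2000, seed=1))


@pytest.fixture(scope="session")
def sim_selection():
    return simulate(SimConfig.selection(n_genes=2000, seed=13))


@pytest.fixture(scope="session")
def sim_neutral():
    return simulate(SimConfig.neutrality_coupled(n_genes=2000, seed=12))


@pytest.fixture(scope="session")
def mutation_analysis(sim_mutation):
    return analyze(sim_mutation.records)


@pytest.fixture(scope="session")
def selection_analysis(sim_selection):
    return analyze(sim_selection.records)
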