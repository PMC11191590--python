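"""Shared fixtures: the strong-signal and null synthetic pipelines.

The expensive products (ORA results, ER matrices, the grid-search solution)
are computed once per session and reused across test modules.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from addscreen import cluster_pipeline as cp
from addscreen import enrichment as en
from addscreen import gene_interactions as gi
from addscreen import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the reduced embedding grid used for parameter-recovery runs
REDUCED_GRID = cp.GridSpec(
    n_neighbors=(5, 10, 15), min_dist=(0.0, 0.5), seeds=(0, 1, 2, 3, 4)
)


def run_enrichment(dataset: sd.SyntheticDataset) -> dict:
    """Remap, assemble ORA inputs, and run batch enrichment for a dataset."""
    remapped, _ = gi.remap_orthologs(dataset.interactions, dataset.ortholog_map)
    inputs = {
        cas: d["up"] | d["down"]
        for cas, d in gi.direction_sets(remapped).items()
    }
    return en.enrich_all(inputs, dataset.gene_sets, dataset.background)


@pytest.fixture(scope="session")
def strong_dataset() -> sd.SyntheticDataset:
    return sd.generate_all(sd.strong_signal_config(seed=0))


@pytest.fixture(scope="session")
def strong_results(strong_dataset):
    return run_enrichment(strong_dataset)


@pytest.fixture(scope="session")
def strong_er(strong_results):
    return en.build_er_matrix(strong_results)


@pytest.fixture(scope="session")
def strong_solution(strong_er):
    return cp.cluster_er_matrix(strong_er, REDUCED_GRID)


@pytest.fixture(scope="session")
def null_dataset() -> sd.SyntheticDataset:
    return sd.generate_all(sd.null_config(seed=0))


@pytest.fixture(scope="session")
def null_results(null_dataset):
    return run_enrichment(null_dataset)
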