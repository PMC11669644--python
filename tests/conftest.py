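"""Shared fixtures: a small simulated dataset reused across test modules."""

import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

import momfkit as mk

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def sim_config():
    return mk.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    adata, truth = mk.simulate_counts(sim_config)
    return adata, truth


@pytest.fixture(scope="session")
def momf_scored(sim_config, sim_data):
    """QC-filtered, MOMF-isolated, scored population from the default simulation."""
    adata, _ = sim_data
    filtered, _ = mk.qc_filter(adata)
    momf_clusters = mk.classify_momf_clusters(filtered, "cluster")
    momf = filtered[filtered.obs["cluster"].isin(momf_clusters).to_numpy()].copy()
    norm = mk.normalize_expression(momf)
    scores = mk.score_subtypes(norm, mk.signature_genes(sim_config))
    return momf, scores


def make_adata(counts, genes=None, cells=None, **obs_cols) -> ad.AnnData:
    """Small dense-count AnnData helper for constructed examples."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"g{j + 1}" for j in range(g)]
    cells = list(cells) if cells is not None else [f"c{i + 1}" for i in range(n)]
    obs = pd.DataFrame({k: list(v) for k, v in obs_cols.items()}, index=pd.Index(cells, name="cell_id"))
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
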