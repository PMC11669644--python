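"""UMAP-proximity pseudobulking and pan-tissue atlas integration.

Each sample (one tissue-condition) is summarised to a fixed number of
pseudobulks (default 100) by iterating proximity aggregation on the 2-D
embedding: a seed cell is drawn at random from the not-yet-aggregated cells
and pooled with its nearest unaggregated neighbours (Euclidean distance, ties
broken by cell order). The nominal cells-per-pseudobulk is the pseudobulking
factor ceil(n_cells / 100); because 100 rarely divides n evenly the emitted
pseudobulks use balanced sizes differing by at most 1 (never exceeding the
factor), which preserves the exact pseudobulk count. The result is a
partition: transcripts are conserved and every cell belongs to exactly one
pseudobulk. Pseudobulk subtype characters are arithmetic means of their
member cells' scores.

Atlas integration restricts all samples' pseudobulks to the genes commonly
expressed across samples, normalizes (counts-per-total, log1p) and optionally
mean-centres per sample — a deliberately simple stand-in at the interface
point where a mutual-nearest-neighbour batch correction would sit.
Re-embedding is delegated to a standard reducer (scanpy neighbors + UMAP) and
its parameters are recorded on the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .scoring import SubtypeScores

logger = logging.getLogger(__name__)

__all__ = [
    "pseudobulking_factor",
    "balanced_sizes",
    "PseudobulkSet",
    "pseudobulk_sample",
    "integrate_pseudobulks",
    "embed_atlas",
]


def pseudobulking_factor(n_cells: int, n_target: int = 100) -> int:
    """Nominal cells per pseudobulk: ceil(n_cells / n_target)."""
    if n_cells < 1 or n_target < 1:
        raise ValueError("n_cells and n_target must be >= 1")
    return math.ceil(n_cells / n_target)


def balanced_sizes(n_cells: int, n_target: int = 100) -> list[int]:
    """Partition ``n_cells`` into ``n_target`` group sizes differing by <= 1.

    The larger sizes equal the pseudobulking factor and come first.
    """
    base, extra = divmod(n_cells, n_target)
    return [base + 1] * extra + [base] * (n_target - extra)


@dataclass
class PseudobulkSet:
    """Aggregated pseudobulks of one sample.

    ``counts`` is pseudobulks x genes (sum of member cells' UMI); ``members``
    maps each pseudobulk id to its member cell ids (a partition of the
    sample); ``mean_scores`` holds the averaged subtype characters.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    pseudobulk_ids: list[str]
    members: dict[str, list[str]]
    tissue_condition: str
    mean_scores: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_pseudobulks(self) -> int:
        return len(self.pseudobulk_ids)


def pseudobulk_sample(
    adata: ad.AnnData,
    embedding: pd.DataFrame | np.ndarray,
    scores: SubtypeScores | None = None,
    n_target: int = 100,
    seed: int = 0,
    tissue_condition: str | None = None,
) -> PseudobulkSet:
    """Summarise one sample's cells to ``n_target`` pseudobulks by iterative
    embedding-proximity aggregation.

    Each iteration picks a random seed cell among the unaggregated cells and
    pools it with its (size - 1) nearest unaggregated neighbours in the 2-D
    embedding. With fewer cells than ``n_target``, one pseudobulk per cell is
    emitted with a warning. Deterministic under a fixed seed.
    """
    coords = np.asarray(embedding[["x", "y"]] if isinstance(embedding, pd.DataFrame) else embedding, dtype=float)
    if coords.shape != (adata.n_obs, 2) or not np.isfinite(coords).all():
        raise ValueError("embedding must give one finite (x, y) pair per cell")
    if isinstance(embedding, pd.DataFrame) and not embedding.index.equals(adata.obs_names):
        raise ValueError("embedding index does not match the cells")
    if scores is not None and not scores.scores.index.equals(adata.obs_names):
        raise ValueError("scores were not computed on these cells")
    if tissue_condition is None:
        tissue_condition = "-".join(
            str(adata.obs[c].iloc[0]) for c in ("condition", "sample") if c in adata.obs
        ) or "sample"

    n = adata.n_obs
    warnings: list[str] = []
    if n < n_target:
        msg = f"{tissue_condition}: only {n} cells for target {n_target}; emitting one pseudobulk per cell"
        logger.warning(msg)
        warnings.append(msg)
        sizes = [1] * n
    else:
        sizes = balanced_sizes(n, n_target)

    rng = np.random.default_rng(seed)
    unaggregated = np.ones(n, dtype=bool)
    groups: list[np.ndarray] = []
    for size in sizes:
        free = np.flatnonzero(unaggregated)
        seed_cell = rng.choice(free)
        d = np.linalg.norm(coords[free] - coords[seed_cell], axis=1)
        # nearest first; distance ties broken by cell-index order
        order = free[np.lexsort((free, d))]
        chosen = order[:size]
        unaggregated[chosen] = False
        groups.append(np.sort(chosen))

    X = sp.csr_matrix(adata.X)
    ids = [f"{tissue_condition}_pb{i + 1:03d}" for i in range(len(groups))]
    agg = sp.vstack([sp.csr_matrix(X[g].sum(axis=0)) for g in groups], format="csr")
    members = {pid: list(adata.obs_names[g]) for pid, g in zip(ids, groups)}
    mean_scores = None
    if scores is not None:
        mean_scores = pd.DataFrame(
            [scores.scores.iloc[g].mean(axis=0) for g in groups], index=ids
        )
    return PseudobulkSet(
        counts=agg,
        gene_ids=list(adata.var_names),
        pseudobulk_ids=ids,
        members=members,
        tissue_condition=tissue_condition,
        mean_scores=mean_scores,
        warnings=warnings,
    )


def integrate_pseudobulks(
    sets: list[PseudobulkSet],
    expressed_gene_sets: dict[str, set[str]],
    scale_total: float = 1e4,
    batch_center: bool = False,
) -> ad.AnnData:
    """Integrate samples' pseudobulks on commonly expressed genes.

    Restricts every pseudobulk to the intersection of the per-sample
    expressed-gene sets, normalizes (counts-per-total ``scale_total``, log1p)
    and, when ``batch_center``, mean-centres each sample's block (a simple
    stand-in at the batch-correction interface). Returns an AnnData carrying
    tissue-condition tags and averaged subtype scores in ``.obs``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 samples to integrate")
    common: set[str] | None = None
    for tag, genes in expressed_gene_sets.items():
        common = set(genes) if common is None else common & set(genes)
    if not common:
        sizes = {t: len(g) for t, g in expressed_gene_sets.items()}
        raise ValueError(f"no commonly expressed genes; per-sample set sizes: {sizes}")
    common_genes = sorted(common)

    blocks, obs_rows, index = [], [], []
    for ps in sets:
        gcol = {g: i for i, g in enumerate(ps.gene_ids)}
        missing = [g for g in common_genes if g not in gcol]
        if missing:
            raise ValueError(f"{ps.tissue_condition}: gene {missing[0]} absent")
        blocks.append(ps.counts[:, [gcol[g] for g in common_genes]])
        for pid in ps.pseudobulk_ids:
            row = {"tissue_condition": ps.tissue_condition, "n_cells": len(ps.members[pid])}
            if ps.mean_scores is not None:
                row.update({f"score_{s}": ps.mean_scores.loc[pid, s] for s in ps.mean_scores.columns})
            obs_rows.append(row)
            index.append(pid)
    X = sp.vstack(blocks, format="csr").astype(float)
    atlas = ad.AnnData(
        X=X,
        obs=pd.DataFrame(obs_rows, index=pd.Index(index, name="pseudobulk_id")),
        var=pd.DataFrame(index=pd.Index(common_genes, name="gene_id")),
    )
    sc.pp.normalize_total(atlas, target_sum=scale_total)
    sc.pp.log1p(atlas)
    if batch_center:
        dense = atlas.X.toarray() if sp.issparse(atlas.X) else np.asarray(atlas.X)
        for tag in atlas.obs["tissue_condition"].unique():
            m = (atlas.obs["tissue_condition"] == tag).to_numpy()
            dense[m] -= dense[m].mean(axis=0)
        atlas.X = dense
    atlas.uns["integration"] = {
        "n_common_genes": len(common_genes),
        "batch_center": batch_center,
        "scale_total": scale_total,
    }
    return atlas


def embed_atlas(
    atlas: ad.AnnData, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.5
) -> ad.AnnData:
    """Project the atlas on UMAP via scanpy (delegated reducer); parameters
    and seed are recorded in ``.uns['atlas_embedding']``."""
    sc.pp.neighbors(atlas, n_neighbors=min(n_neighbors, atlas.n_obs - 1), use_rep="X", random_state=seed)
    sc.tl.umap(atlas, min_dist=min_dist, random_state=seed)
    atlas.uns["atlas_embedding"] = {
        "method": "umap",
        "seed": seed,
        "n_neighbors": int(min(n_neighbors, atlas.n_obs - 1)),
        "min_dist": min_dist,
    }
    return atlas
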