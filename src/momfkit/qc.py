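"""Cell-level QC, the expressed-gene rule and detection-rate MOMF isolation.

QC keeps cells with 200-5000 detected genes (inclusive) and a mitochondrial
UMI fraction strictly below 10%. A gene counts as expressed in a group when it
is detected (UMI >= 1) in at least 10% of the group's cells. A cluster is
called monocyte/macrophage (MOMF) when Csf1r or Adgre1 is detected in >50% of
its cells, or Cd68 in >60%, or (optionally) Cd207 in >40% — the Cd207 arm is
switchable off for archived datasets where Langerhans cells are absent or
ambiguous.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter",
    "expressed_genes",
    "classify_momf_clusters",
    "detection_rates",
    "MOMF_RULES",
]

# (marker, strict detection-rate threshold); Cd207 participation is a flag
MOMF_RULES: tuple[tuple[str, float], ...] = (
    ("Csf1r", 0.50),
    ("Adgre1", 0.50),
    ("Cd68", 0.60),
    ("Cd207", 0.40),
)

MITO_PREFIX = "mt-"


def _dense_detection(X) -> np.ndarray:
    return (X > 0).toarray() if sp.issparse(X) else np.asarray(X) > 0


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito: float = 0.10,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells on detected-gene count and mitochondrial fraction.

    Bounds on detected genes are inclusive; the mitochondrial bound is strict
    (< ``max_mito``). Returns the filtered matrix (gene set unchanged) and a
    per-cell report covering every input cell with columns
    ``n_genes_detected``, ``mito_fraction``, ``retained``.
    """
    if not (0 < min_genes <= max_genes):
        raise ValueError("need 0 < min_genes <= max_genes")
    if adata.n_obs == 0:
        logger.warning("qc_filter: matrix has zero cells")
        report = pd.DataFrame(
            columns=["n_genes_detected", "mito_fraction", "retained"], index=adata.obs_names
        )
        return adata.copy(), report

    X = adata.X
    detected = _dense_detection(X).sum(axis=1)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.clip(total, 1, None), 0.0)
    retained = (
        (detected >= min_genes)
        & (detected <= max_genes)
        & (mito_frac < max_mito)
        & (total > 0)
    )
    report = pd.DataFrame(
        {
            "n_genes_detected": detected.astype(int),
            "mito_fraction": mito_frac,
            "retained": retained,
        },
        index=adata.obs_names.copy(),
    )
    n_removed = int((~retained).sum())
    if n_removed:
        logger.warning("qc_filter: removed %d of %d cells", n_removed, adata.n_obs)
    return adata[retained].copy(), report


def _resolve_genes(adata: ad.AnnData, genes: list[str]) -> dict[str, str | None]:
    """Map requested gene symbols to matrix gene ids, case-sensitively with a
    case-insensitive fallback (archived datasets vary in capitalisation)."""
    present = set(adata.var_names)
    lower = {}
    for g in adata.var_names:
        lower.setdefault(g.lower(), g)
    out: dict[str, str | None] = {}
    for g in genes:
        if g in present:
            out[g] = g
        elif g.lower() in lower:
            out[g] = lower[g.lower()]
            logger.warning("gene %s matched case-insensitively as %s", g, out[g])
        else:
            out[g] = None
    return out


def detection_rates(
    adata: ad.AnnData, labels: pd.Series | np.ndarray, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-group fraction of cells with UMI >= 1, groups x genes."""
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    if genes is not None:
        resolved = _resolve_genes(adata, genes)
        cols = [resolved[g] for g in genes]
        det = np.zeros((adata.n_obs, len(genes)))
        keep = [i for i, c in enumerate(cols) if c is not None]
        if keep:
            sub = adata[:, [cols[i] for i in keep]].X
            det[:, keep] = _dense_detection(sub)
        names = genes
    else:
        det = _dense_detection(adata.X)
        names = list(adata.var_names)
    frame = pd.DataFrame(det, index=adata.obs_names, columns=names)
    return frame.groupby(labels, observed=True).mean()


def expressed_genes(
    adata: ad.AnnData,
    labels: pd.Series | np.ndarray | str,
    threshold: float = 0.10,
) -> dict[str, set[str]]:
    """Genes detected (UMI >= 1) in at least ``threshold`` of a group's cells.

    ``labels`` may be an ``.obs`` column name or a per-cell vector; the 10%
    boundary is inclusive.
    """
    if isinstance(labels, str):
        labels = adata.obs[labels]
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    if labels.isna().any():
        bad = labels.index[labels.isna()][0]
        raise ValueError(f"cell {bad} has no group label")
    rates = detection_rates(adata, labels)
    genes = np.array(rates.columns)
    return {
        str(group): set(genes[(rates.loc[group] >= threshold).to_numpy()])
        for group in rates.index
    }


def classify_momf_clusters(
    adata: ad.AnnData,
    cluster_labels: pd.Series | np.ndarray | str = "cluster",
    use_cd207: bool = True,
) -> set[str]:
    """Detection-rate rule for monocyte/macrophage clusters.

    A cluster is MOMF iff Csf1r > 50% or Adgre1 > 50% or Cd68 > 60% or (when
    ``use_cd207``) Cd207 > 40% detection; thresholds strict. Missing markers
    are treated as 0% detection with a warning.
    """
    if isinstance(cluster_labels, str):
        if cluster_labels not in adata.obs:
            raise ValueError(
                "no cluster labels: supply per-cell clustering (e.g. truth labels "
                "or a standard graph-clustering result)"
            )
        cluster_labels = adata.obs[cluster_labels]
    labels = pd.Series(np.asarray(cluster_labels), index=adata.obs_names)
    if labels.isna().any() or len(labels) == 0:
        raise ValueError("every cell needs a cluster label")
    markers = [m for m, _ in MOMF_RULES]
    resolved = _resolve_genes(adata, markers)
    for m, r in resolved.items():
        if r is None:
            logger.warning("marker %s absent from gene ids; treated as 0%% detection", m)
    rates = detection_rates(adata, labels, genes=markers)
    momf: set[str] = set()
    for cluster in rates.index:
        row = rates.loc[cluster]
        rules = MOMF_RULES if use_cd207 else MOMF_RULES[:3]
        if any(row[m] > thr for m, thr in rules):
            momf.add(str(cluster))
    return momf
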