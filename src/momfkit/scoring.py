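"""Subtype identity scores and marker-gate capture analysis.

The score of subtype S in cell c is the mean over S's signature genes of the
gene's expression scaled across the whole cell population (z-score by default,
so every gene contributes on the same footing), with each subtype's score
vector then min-max rescaled over the population to [0, 1]. Scores are
population-relative by construction: re-scoring a subset of cells changes
values, so scores are only comparable within one scored population.

Marker gates select cells by detected / undetected markers on raw UMI
(positive markers with an any/all rule, negative markers required at 0 UMI)
and report how well each gate captures each subtype: the fraction of gated
cells whose argmax score is that subtype, plus the gate pseudo-bulk's mean
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_expression",
    "score_subtypes",
    "SubtypeScores",
    "MarkerGate",
    "marker_gate_capture",
]


def normalize_expression(adata: ad.AnnData, scale_total: float = 1e4) -> ad.AnnData:
    """Library-size normalization: counts / library * ``scale_total``, log1p.

    Returns a copy; cells with zero library size must be removed upstream
    (they are, by QC) and are rejected here.
    """
    lib = np.asarray(adata.X.sum(axis=1)).ravel()
    if (lib == 0).any():
        bad = adata.obs_names[np.flatnonzero(lib == 0)[0]]
        raise ValueError(f"cell {bad} has zero library size; run QC first")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=scale_total)
    sc.pp.log1p(out)
    return out


@dataclass
class SubtypeScores:
    """Cells x subtypes score matrix with per-cell argmax assignment.

    ``degenerate`` lists subtypes whose score column was constant across the
    population (all scores set to 0 for those columns).
    """

    scores: pd.DataFrame
    assigned: pd.Series
    degenerate: list[str] = field(default_factory=list)
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def subtypes(self) -> list[str]:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["assigned"] = self.assigned
        return out


def score_subtypes(
    expression: ad.AnnData,
    signatures: dict[str, list[str]],
    gene_scaling: str = "zscore",
) -> SubtypeScores:
    """Score every cell for every subtype signature.

    Step 1: scale each signature gene across the whole population
    (``gene_scaling``: "zscore" standardises to mean 0 / sd 1; "minmax" maps
    to [0, 1]).  Step 2: per cell, average the scaled values of each subtype's
    genes.  Step 3: min-max rescale each subtype's score vector over the
    population to [0, 1].  Assignment is the argmax column, ties broken by
    signature order.

    Signature genes missing from the matrix (or constant across cells, which
    carry no population-relative information) are dropped with a warning; a
    subtype losing all its genes is an error, as is a population of <2 cells.
    """
    if expression.n_obs < 2:
        raise ValueError("population scaling needs at least 2 cells")
    if gene_scaling not in ("zscore", "minmax"):
        raise ValueError("gene_scaling must be 'zscore' or 'minmax'")

    present = set(expression.var_names)
    dropped: dict[str, list[str]] = {}
    used: dict[str, list[str]] = {}
    for s, genes in signatures.items():
        if not genes:
            raise ValueError(f"subtype {s} has an empty signature")
        missing = [g for g in genes if g not in present]
        if missing:
            logger.warning("subtype %s: dropping %d missing genes", s, len(missing))
        used[s] = [g for g in genes if g in present]
        dropped[s] = missing
        if not used[s]:
            raise ValueError(f"subtype {s}: no signature genes present in the matrix")

    all_genes = sorted({g for gs in used.values() for g in gs})
    sub = expression[:, all_genes].X
    E = sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)
    E = E.astype(float)

    if gene_scaling == "zscore":
        mu, sd = E.mean(axis=0), E.std(axis=0)
        constant = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (E - mu) / np.where(constant, 1.0, sd)
    else:
        lo, hi = E.min(axis=0), E.max(axis=0)
        constant = hi == lo
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (E - lo) / np.where(constant, 1.0, hi - lo)
    Z[:, constant] = np.nan  # constant genes carry no signal; drop from means
    col = {g: i for i, g in enumerate(all_genes)}
    if constant.any():
        const_names = {all_genes[i] for i in np.flatnonzero(constant)}
        logger.warning("dropping %d constant signature genes", len(const_names))
        for s in used:
            dropped[s] = dropped[s] + [g for g in used[s] if g in const_names]

    scores = pd.DataFrame(index=expression.obs_names.copy(), columns=list(signatures), dtype=float)
    degenerate: list[str] = []
    for s, genes in used.items():
        valid = [col[g] for g in genes if not constant[col[g]]]
        raw = Z[:, valid].mean(axis=1) if valid else np.zeros(expression.n_obs)
        lo, hi = np.min(raw), np.max(raw)
        if hi == lo:
            degenerate.append(s)
            scores[s] = 0.0
        else:
            scores[s] = (raw - lo) / (hi - lo)
    assigned = pd.Series(
        np.array(list(signatures))[scores.to_numpy().argmax(axis=1)],
        index=scores.index,
        name="assigned",
    )
    return SubtypeScores(scores=scores, assigned=assigned, degenerate=degenerate, dropped_genes=dropped)


@dataclass(frozen=True)
class MarkerGate:
    """A flow-style boolean cell selector.

    A cell is in the gate iff every negative marker has 0 UMI and the positive
    rule holds: "any" needs >=1 positive marker detected, "all" needs every
    positive marker detected (a slash in flow notation, e.g. Folr2/Cd163+,
    is the "any" rule).
    """

    name: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()
    rule: str = "any"

    def __post_init__(self) -> None:
        if self.rule not in ("any", "all"):
            raise ValueError("rule must be 'any' or 'all'")

    def member_mask(self, adata: ad.AnnData) -> np.ndarray:
        for g in (*self.positive, *self.negative):
            if g not in adata.var_names:
                raise ValueError(f"gate {self.name}: gene {g} absent from the matrix")
        det = {}
        for g in (*self.positive, *self.negative):
            v = adata[:, g].X
            det[g] = (np.asarray(v.todense() if sp.issparse(v) else v).ravel() >= 1)
        mask = np.ones(adata.n_obs, dtype=bool)
        for g in self.negative:
            mask &= ~det[g]
        if self.positive:
            pos = np.column_stack([det[g] for g in self.positive])
            mask &= pos.any(axis=1) if self.rule == "any" else pos.all(axis=1)
        return mask


def marker_gate_capture(
    adata: ad.AnnData, scores: SubtypeScores, gates: list[MarkerGate]
) -> pd.DataFrame:
    """Capture table: per gate, how the gated cells distribute over subtypes.

    Columns: member-cell count, per-subtype capture (fraction of gated cells
    assigned to that subtype), per-subtype mean score of the gate pseudo-bulk,
    and an ``empty`` flag (fractions NaN when no cell falls in the gate).
    """
    if not scores.scores.index.equals(adata.obs_names):
        raise ValueError("scores were not computed on these cells")
    rows = []
    for gate in gates:
        mask = gate.member_mask(adata)
        n = int(mask.sum())
        row: dict[str, object] = {"gate": gate.name, "n_cells": n, "empty": n == 0}
        for s in scores.subtypes:
            if n == 0:
                row[f"capture_{s}"] = np.nan
                row[f"mean_score_{s}"] = np.nan
            else:
                row[f"capture_{s}"] = float((scores.assigned[mask] == s).mean())
                row[f"mean_score_{s}"] = float(scores.scores.loc[mask, s].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("gate")
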