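"""In-silico coculture ligand screen.

Candidate niche factors are shortlisted by (1) restricting an annotated
ligand-receptor table to ligands with at least one receptor expressed on
macrophages, (2) summarising ligand expression by cell type, (3) estimating
each coculture design's ligand content as the sum of its member types'
summaries, and (4) comparing contents between phenotype-inductive and
non-inductive designs with Welch's t test, shortlisting at fold-change > 3 and
p < 0.05 with the inductive mean required to exceed the non-inductive mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CocultureDesign",
    "filter_ligands",
    "celltype_ligand_summary",
    "coculture_ligand_content",
    "shortlist_ligands",
]


@dataclass(frozen=True)
class CocultureDesign:
    """A named set of co-present cell types and its phenotype label
    (inductive = the composition induces CD163 on macrophages)."""

    name: str
    members: frozenset[str]
    inductive: bool

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"design {self.name}: member set is empty")


def filter_ligands(lr: pd.DataFrame, momf_expressed: set[str]) -> set[str]:
    """Ligands with at least one receptor in the macrophage expressed-gene set."""
    if lr.empty:
        raise ValueError("ligand-receptor table is empty")
    if lr.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows")
    ok = lr["receptor"].isin(momf_expressed)
    return set(lr.loc[ok, "ligand"])


def celltype_ligand_summary(
    expression: ad.AnnData,
    cell_type_labels: pd.Series | np.ndarray | str,
    ligands: set[str] | list[str],
    statistic: str = "mean",
) -> pd.DataFrame:
    """Cell types x ligands table of mean normalized expression.

    ``statistic``: "mean" (default) of normalized expression, or "detection"
    (fraction of cells with any signal). Ligands missing from the matrix get a
    0 column with a warning.
    """
    if isinstance(cell_type_labels, str):
        cell_type_labels = expression.obs[cell_type_labels]
    labels = pd.Series(np.asarray(cell_type_labels), index=expression.obs_names)
    if labels.isna().any():
        raise ValueError("every cell needs a cell-type label")
    ligands = sorted(ligands)
    present = [g for g in ligands if g in expression.var_names]
    missing = [g for g in ligands if g not in expression.var_names]
    if missing:
        logger.warning("%d ligand genes missing from matrix; summarised as 0", len(missing))
    sub = expression[:, present].X
    E = sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)
    if statistic == "detection":
        E = (E > 0).astype(float)
    elif statistic != "mean":
        raise ValueError("statistic must be 'mean' or 'detection'")
    frame = pd.DataFrame(E, index=expression.obs_names, columns=present)
    summary = frame.groupby(labels, observed=True).mean()
    for g in missing:
        summary[g] = 0.0
    return summary[ligands]


def coculture_ligand_content(summary: pd.DataFrame, design: CocultureDesign) -> pd.Series:
    """Ligand content of a design: sum of its member types' summary rows."""
    absent = [t for t in design.members if t not in summary.index]
    if absent:
        raise ValueError(f"design {design.name}: cell type {absent[0]} absent from summary")
    return summary.loc[sorted(design.members)].sum(axis=0).rename(design.name)


def shortlist_ligands(
    contents: pd.DataFrame,
    designs: list[CocultureDesign],
    fc_threshold: float = 3.0,
    p_threshold: float = 0.05,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Compare ligand contents between inductive and non-inductive designs.

    ``contents`` is designs x ligands (one row per design name). Per ligand:
    fold-change = mean(inductive) / mean(non-inductive) with pseudocount
    ``eps`` added to both when the denominator is 0 (flagged); p from Welch's
    two-sided two-sample t test; shortlisted iff fold-change > ``fc_threshold``
    and p < ``p_threshold`` and the inductive mean exceeds the non-inductive
    mean. Constant contents in both classes give p = 1.
    """
    ind = [d.name for d in designs if d.inductive]
    non = [d.name for d in designs if not d.inductive]
    if len(ind) < 2 or len(non) < 2:
        raise ValueError("need at least 2 inductive and 2 non-inductive designs")
    missing = [n for n in ind + non if n not in contents.index]
    if missing:
        raise ValueError(f"design {missing[0]} has no content row")

    rows = []
    for ligand in contents.columns:
        a = contents.loc[ind, ligand].to_numpy(dtype=float)
        b = contents.loc[non, ligand].to_numpy(dtype=float)
        ma, mb = a.mean(), b.mean()
        flagged = mb == 0
        fc = (ma + eps) / (mb + eps) if flagged else ma / mb
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0  # no variance in either class: the t test is uninformative
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append(
            {
                "ligand": ligand,
                "mean_inductive": ma,
                "mean_non_inductive": mb,
                "fold_change": fc,
                "p_value": p,
                "zero_denominator": flagged,
                "shortlisted": bool(fc > fc_threshold and p < p_threshold and ma > mb),
            }
        )
    return pd.DataFrame(rows).set_index("ligand")
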