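"""Readers and writers for the plain-text exchange formats used across the pipeline.

Count matrices travel as Matrix Market (.mtx) in the 10x genes x cells
orientation with ``genes.tsv`` / ``barcodes.tsv`` sidecars; everything else is
tab- or comma-delimited with a header row, or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_table",
    "read_table",
    "write_signatures",
    "read_signatures",
    "write_lr_table",
    "read_lr_table",
    "write_json",
    "read_json",
]


def write_counts_mtx(adata: ad.AnnData, outdir: str | Path) -> dict[str, Path]:
    """Write an AnnData (cells x genes) as MTX (genes x cells) plus sidecars.

    Cell annotations in ``.obs`` are written to ``cells.tsv`` alongside the
    barcode list so labels survive the round trip.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / "matrix.mtx"
    genes = outdir / "genes.tsv"
    barcodes = outdir / "barcodes.tsv"
    cells = outdir / "cells.tsv"
    X = sp.csc_matrix(adata.X.T if sp.issparse(adata.X) else np.asarray(adata.X).T)
    scipy.io.mmwrite(str(mtx), X, field="integer")
    genes.write_text("\n".join(adata.var_names) + "\n")
    barcodes.write_text("\n".join(adata.obs_names) + "\n")
    adata.obs.to_csv(cells, sep="\t", index=True, index_label="cell_id")
    return {"matrix": mtx, "genes": genes, "barcodes": barcodes, "cells": cells}


def read_counts_mtx(indir: str | Path) -> ad.AnnData:
    """Read an MTX directory written by :func:`write_counts_mtx` into AnnData."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx").T)
    gene_ids = (indir / "genes.tsv").read_text().splitlines()
    cell_ids = (indir / "barcodes.tsv").read_text().splitlines()
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    cells = indir / "cells.tsv"
    if cells.exists():
        obs = pd.read_csv(cells, sep="\t", index_col="cell_id", dtype={"cell_id": str})
        obs.index = obs.index.astype(str)
        obs = obs.loc[cell_ids]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")))
    return adata


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t", index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index)
    return path


def read_table(path: str | Path, sep: str = "\t", index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=index_col)


def write_signatures(signatures: dict[str, list[str]], path: str | Path) -> Path:
    """Write a signature set as a two-column (subtype, gene) TSV."""
    rows = [(s, g) for s, genes in signatures.items() for g in genes]
    return write_table(
        pd.DataFrame(rows, columns=["subtype", "gene"]), path, index=False
    )


def read_signatures(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {s: list(sub["gene"]) for s, sub in df.groupby("subtype", sort=False)}


def write_lr_table(lr: pd.DataFrame, path: str | Path) -> Path:
    return write_table(lr, path, index=False)


def read_lr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("ligand-receptor table needs 'ligand' and 'receptor' columns")
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
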