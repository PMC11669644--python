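"""End-to-end orchestration: simulate -> QC -> isolate MOMF -> score ->
coculture screen -> pseudobulk atlas, with a run manifest.

The pipeline is configured by a single JSON-serialisable dict with per-stage
sections; every stage is also callable standalone on files produced by any
conforming producer. Deterministic stages reproduce byte-identical outputs
when re-run with identical configuration and seeds; the manifest records per
stage the parameters, seed, output paths with content hashes, wall-clock and
warnings.
"""

from __future__ import annotations

import copy
import hashlib
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coculture as cc
from . import io as mio
from . import pseudobulk as pb
from . import qc as qcm
from . import scoring as sco
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["default_config", "default_designs", "run_pipeline"]

STAGES = ("simulate", "qc", "isolate", "score", "coculture", "atlas")


def default_designs() -> list[dict]:
    """Coculture compositions for the synthetic screen: inductive designs all
    contain fibroblasts (the planted ligand source), the paired non-inductive
    designs are the same mixtures without them."""
    return [
        {"name": "FKM", "members": ["fibroblast", "keratinocyte", "MF_S3"], "inductive": True},
        {"name": "FEM", "members": ["fibroblast", "endothelial", "MF_S3"], "inductive": True},
        {"name": "complete", "members": ["fibroblast", "keratinocyte", "endothelial", "Tcell", "MF_S3"], "inductive": True},
        {"name": "KM", "members": ["keratinocyte", "MF_S3"], "inductive": False},
        {"name": "EM", "members": ["endothelial", "MF_S3"], "inductive": False},
        {"name": "KETM", "members": ["keratinocyte", "endothelial", "Tcell", "MF_S3"], "inductive": False},
    ]


def default_config(outdir: str | Path = "momfkit_run", seed: int = 0) -> dict:
    return {
        "outdir": str(outdir),
        "seed": int(seed),
        "stages": list(STAGES),
        "simulate": {"embedding_spread": 0.3},
        "qc": {"min_genes": 200, "max_genes": 5000, "max_mito": 0.10},
        "isolate": {"use_cd207": True, "cluster_key": "cluster"},
        "score": {"scale_total": 1e4, "gene_scaling": "zscore"},
        "coculture": {
            "fc_threshold": 3.0,
            "p_threshold": 0.05,
            "expressed_threshold": 0.10,
            "designs": default_designs(),
        },
        "atlas": {"n_target": 100, "batch_center": False, "embed": False},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: dict) -> None:
    """Check every enabled stage's parameters before any stage runs."""
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for i, s in enumerate(stages):
        needed = STAGES[: STAGES.index(s)]
        for dep in needed:
            if dep not in stages:
                raise ValueError(
                    f"stage '{s}' needs upstream stage '{dep}': enable it or provide its outputs"
                )
    q = config.get("qc", {})
    if not (0 < q.get("min_genes", 200) <= q.get("max_genes", 5000)):
        raise ValueError("qc: need 0 < min_genes <= max_genes")
    if not (0 < q.get("max_mito", 0.10) <= 1):
        raise ValueError("qc: max_mito must be in (0, 1]")
    co = config.get("coculture", {})
    designs = co.get("designs", default_designs())
    n_ind = sum(d["inductive"] for d in designs)
    if "coculture" in stages and (n_ind < 2 or len(designs) - n_ind < 2):
        raise ValueError("coculture: need >= 2 inductive and >= 2 non-inductive designs")


def run_pipeline(config: dict | None = None) -> dict:
    """Run the enabled stages in dependency order; returns the manifest.

    The manifest is always written to ``<outdir>/manifest.json``, even on
    failure of a later stage (the failing stage is named in the raised error).
    """
    config = copy.deepcopy(config) if config else default_config()
    base = default_config(config.get("outdir", "momfkit_run"), config.get("seed", 0))
    for k, v in base.items():
        if isinstance(v, dict):
            config[k] = {**v, **config.get(k, {})}
        else:
            config.setdefault(k, v)
    _validate(config)

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    manifest: dict = {"config": {k: v for k, v in config.items() if k != "sim_config"}, "stages": {}}

    # mutable pipeline state handed from stage to stage
    state: dict = {}

    def record(stage: str, t0: float, outputs: dict[str, Path], warnings: list[str], **params):
        manifest["stages"][stage] = {
            "parameters": params,
            "seed": seed,
            "outputs": {k: str(p) for k, p in outputs.items()},
            "output_hashes": {k: _sha256(Path(p)) for k, p in outputs.items()},
            "wall_clock_s": round(time.perf_counter() - t0, 3),
            "warnings": warnings,
        }

    current = "setup"
    try:
        if "simulate" in stages:
            current = "simulate"
            t0 = time.perf_counter()
            sim_cfg = config.get("sim_config") or syn.SimulationConfig(seed=seed)
            adata, truth = syn.simulate_counts(sim_cfg)
            emb = syn.simulate_embedding(
                truth, spread=config["simulate"]["embedding_spread"], seed=seed + 1
            )
            lr = syn.simulate_lr_table(sim_cfg)
            sigs = syn.signature_genes(sim_cfg)
            outs = mio.write_counts_mtx(adata, outdir / "counts")
            outs["truth"] = mio.write_table(truth, outdir / "truth.tsv")
            outs["embedding"] = mio.write_table(emb, outdir / "embedding.tsv")
            outs["lr_table"] = mio.write_lr_table(lr, outdir / "lr_table.tsv")
            outs["signatures"] = mio.write_signatures(sigs, outdir / "signatures.tsv")
            state.update(adata=adata, truth=truth, embedding=emb, lr=lr, signatures=sigs)
            record("simulate", t0, outs, [], spread=config["simulate"]["embedding_spread"],
                   n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))

        if "qc" in stages:
            current = "qc"
            t0 = time.perf_counter()
            p = config["qc"]
            filtered, report = qcm.qc_filter(
                state["adata"], p["min_genes"], p["max_genes"], p["max_mito"]
            )
            outs = {"qc_report": mio.write_table(report, outdir / "qc_report.tsv")}
            state["adata"] = filtered
            state["embedding"] = state["embedding"].loc[filtered.obs_names]
            record("qc", t0, outs, [], **p,
                   n_retained=int(report["retained"].sum()), n_input=len(report))

        if "isolate" in stages:
            current = "isolate"
            t0 = time.perf_counter()
            p = config["isolate"]
            momf = qcm.classify_momf_clusters(
                state["adata"], p["cluster_key"], use_cd207=p["use_cd207"]
            )
            table = pd.DataFrame(
                {
                    "cluster": sorted(state["adata"].obs[p["cluster_key"]].unique()),
                }
            )
            table["is_momf"] = table["cluster"].isin(momf)
            outs = {"momf_clusters": mio.write_table(table, outdir / "momf_clusters.tsv", index=False)}
            mask = state["adata"].obs[p["cluster_key"]].isin(momf).to_numpy()
            state["momf"] = state["adata"][mask].copy()
            state["momf_embedding"] = state["embedding"].loc[state["momf"].obs_names]
            record("isolate", t0, outs, [], **p, n_momf_clusters=len(momf),
                   n_momf_cells=int(mask.sum()))

        if "score" in stages:
            current = "score"
            t0 = time.perf_counter()
            p = config["score"]
            state["norm_all"] = sco.normalize_expression(state["adata"], p["scale_total"])
            state["norm_momf"] = state["norm_all"][state["momf"].obs_names].copy()
            scores = sco.score_subtypes(
                state["norm_momf"], state["signatures"], gene_scaling=p["gene_scaling"]
            )
            state["scores"] = scores
            outs = {"scores": mio.write_table(scores.to_frame(), outdir / "subtype_scores.csv", sep=",")}
            record("score", t0, outs, [], **p, n_cells=int(scores.scores.shape[0]),
                   degenerate=scores.degenerate)

        if "coculture" in stages:
            current = "coculture"
            t0 = time.perf_counter()
            p = config["coculture"]
            expressed = qcm.expressed_genes(
                state["momf"],
                np.full(state["momf"].n_obs, "MOMF"),
                threshold=p["expressed_threshold"],
            )["MOMF"]
            eligible = cc.filter_ligands(state["lr"], expressed)
            summary = cc.celltype_ligand_summary(state["norm_all"], "cell_type", eligible)
            designs = [
                cc.CocultureDesign(d["name"], frozenset(d["members"]), d["inductive"])
                for d in p["designs"]
            ]
            contents = pd.DataFrame(
                [cc.coculture_ligand_content(summary, d) for d in designs]
            )
            shortlist = cc.shortlist_ligands(
                contents, designs, p["fc_threshold"], p["p_threshold"]
            )
            state["shortlist"] = shortlist
            outs = {
                "ligand_contents": mio.write_table(contents, outdir / "ligand_contents.csv", sep=","),
                "shortlist": mio.write_table(shortlist, outdir / "ligand_shortlist.csv", sep=","),
            }
            record("coculture", t0, outs, [], fc_threshold=p["fc_threshold"],
                   p_threshold=p["p_threshold"], n_eligible=len(eligible),
                   n_shortlisted=int(shortlist["shortlisted"].sum()))

        if "atlas" in stages:
            current = "atlas"
            t0 = time.perf_counter()
            p = config["atlas"]
            momf = state["momf"]
            sets, expr_sets = [], {}
            warnings: list[str] = []
            tags = sorted(momf.obs["sample"].unique())
            for i, s in enumerate(tags):
                mask = (momf.obs["sample"] == s).to_numpy()
                sub = momf[mask].copy()
                emb = state["momf_embedding"].loc[sub.obs_names]
                scores_sub = sco.SubtypeScores(
                    scores=state["scores"].scores.loc[sub.obs_names],
                    assigned=state["scores"].assigned.loc[sub.obs_names],
                    degenerate=state["scores"].degenerate,
                )
                ps = pb.pseudobulk_sample(
                    sub, emb, scores_sub, n_target=p["n_target"], seed=seed + 100 + i
                )
                warnings += ps.warnings
                sets.append(ps)
                expr_sets[ps.tissue_condition] = qcm.expressed_genes(
                    sub, np.full(sub.n_obs, ps.tissue_condition)
                )[ps.tissue_condition]
            atlas = pb.integrate_pseudobulks(sets, expr_sets, batch_center=p["batch_center"])
            if p.get("embed"):
                pb.embed_atlas(atlas, seed=seed)
            membership = pd.DataFrame(
                [(pid, c) for ps in sets for pid, cells in ps.members.items() for c in cells],
                columns=["pseudobulk_id", "cell_id"],
            )
            meta = atlas.obs.copy()
            outs = {
                "membership": mio.write_table(membership, outdir / "pseudobulk_members.tsv", index=False),
                "atlas_meta": mio.write_table(meta, outdir / "atlas_metadata.csv", sep=","),
            }
            state["atlas"] = atlas
            state["pseudobulk_sets"] = sets
            record("atlas", t0, outs, warnings, n_target=p["n_target"],
                   batch_center=p["batch_center"], n_pseudobulks=int(atlas.n_obs),
                   n_common_genes=int(atlas.n_vars))
    except Exception as err:
        manifest["error"] = {"stage": current, "message": str(err)}
        mio.write_json(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage '{current}' failed: {err}") from err
    mio.write_json(manifest, outdir / "manifest.json")
    manifest["state"] = state  # in-memory results for library callers
    return manifest
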