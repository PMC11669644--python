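# momfkit

Tools for characterising monocyte/macrophage (MOMF) subtype identity in
single-cell RNA-seq, built for the kind of analysis done in inflammatory skin
disease (e.g. atopic dermatitis in mouse): isolating macrophage clusters by
marker detection rates, measuring each cell's resemblance to transcriptomic
subtypes S1–S5 from gene signatures, screening candidate niche ligands with
in-silico cocultures, and compressing samples into embedding-proximity
pseudobulks for a pan-tissue identity atlas. A synthetic-data generator with
planted ground truth makes the whole pipeline testable end to end without any
download.

## The core procedures

**MOMF isolation.** After QC (cells with 200–5000 detected genes and <10%
mitochondrial UMI), a cluster is called MOMF iff

> det(*Csf1r*) > 0.5 ∨ det(*Adgre1*) > 0.5 ∨ det(*Cd68*) > 0.6 ∨ det(*Cd207*) > 0.4

where det(g) is the fraction of the cluster's cells with ≥1 UMI of g. A gene
is *expressed* in a group when det(g) ≥ 0.1.

**Subtype identity score.** For subtype S with signature gene set G_S, on
log-normalized expression x:

&nbsp;&nbsp;score_S(c) = minmax_cells( mean_{g∈G_S} z_cells(x_gc) ) ∈ [0, 1]

each gene is z-scored across the whole population (equal contribution), the
per-cell mean over the signature is taken, and each subtype's score vector is
min-max rescaled over the population so every column spans exactly [0, 1].
Cells are assigned to their argmax subtype; scores are population-relative by
construction.

**Coculture ligand screen.** Ligands with an expressed receptor on
macrophages are summarised per cell type (mean normalized expression); a
coculture's ligand content is the sum over its member cell types. Contents of
phenotype-inductive vs non-inductive compositions are compared by Welch's t
test and ligands with fold-change > 3 and p < 0.05 (inductive above
non-inductive) are shortlisted.

**Proximity pseudobulking.** Each sample is summarised to 100 pseudobulks:
iteratively, a random unaggregated seed cell is pooled with its nearest
unaggregated neighbours on the 2-D embedding, with balanced sizes that never
exceed the pseudobulking factor ⌈n/100⌉. Pseudobulks partition the sample,
conserve transcripts, carry mean subtype scores, and are integrated across
samples on commonly expressed genes.

## Worked example

```python
import momfkit as mk

config = mk.default_config("run_out", seed=0)     # synthetic end-to-end run
manifest = mk.run_pipeline(config)
state = manifest["state"]

momf, scores = state["momf"], state["scores"]
print("MOMF cells:", momf.n_obs)
print("accuracy:", (scores.assigned == momf.obs["subtype"]).mean())
print(scores.to_frame().head(3).round(3))
print(state["shortlist"].round(4))
print("atlas:", state["atlas"].shape)
```

prints

```
MOMF cells: 981
accuracy: 1.0
              S1     S2     S3     S4     S5 assigned
cell_id
cell00001  0.804  0.163  0.232  0.190  0.096       S1
cell00002  0.916  0.118  0.172  0.181  0.033       S1
cell00003  0.836  0.151  0.158  0.137  0.157       S1

        mean_inductive  mean_non_inductive  fold_change  p_value  zero_denominator  shortlisted
ligand
Lama2           5.4339              1.5598       3.4837   0.0023             False         True

atlas: (300, 1499)
```

The simulation plants five macrophage subtypes (200 cells each, 81 signature
genes per subtype at 8-fold elevation) among fibroblasts, keratinocytes and
other skin cells across 3 samples. After QC, the five macrophage clusters —
and only those — pass the detection-rate rule (981 cells); every MOMF cell is
assigned its true subtype (accuracy 1.0), and the per-cell score rows show
the population-scaled [0, 1] identity profile. The coculture screen recovers
the planted fibroblast-restricted ligand *Lama2* (contents 5.43 vs 1.56,
fold-change 3.48 > 3, p = 0.0023 < 0.05) while the decoy pair, whose receptor
is absent from macrophages, never enters the test. The atlas holds exactly
100 pseudobulks per tissue-condition (3 × 100) over the 1499 commonly
expressed genes.

The same stages are available from a shell:

```bash
momfkit simulate --outdir sim --seed 0
momfkit qc --counts sim/counts --out qc.tsv
momfkit isolate --counts sim/counts
momfkit run-all --outdir full_run --seed 0
```

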