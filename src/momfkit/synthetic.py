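"""Synthetic single-cell UMI data with planted ground truth.

Emulates the statistical structure the downstream stages assume: multi-cell-type
negative-binomial UMI counts, planted subtype-specific signature genes,
mitochondrial genes for QC, cell-type-specific ligands with receptors elevated
on macrophages, per-sample batch structure (library-size shifts only), and
cluster-structured 2-D embeddings. Everything is a pure function of
(configuration, seed).

Counts for gene g in cell c are drawn NB(mean, dispersion) with
``variance = mean + mean**2 / dispersion`` and
``mean = baseline_mean * fold`` where ``fold`` is the planted elevation if g is
a signature / marker / ligand / receptor gene of c's cell type, else 1.
Mitochondrial genes are sized so a cell with target mitochondrial fraction f
carries expected mito UMI ``f/(1-f)`` times its expected nuclear library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellTypeSpec",
    "LigandSpec",
    "SimulationConfig",
    "simulate_counts",
    "simulate_embedding",
    "simulate_lr_table",
    "signature_genes",
]

# canonical mouse markers used by the MOMF detection-rate rule
MOMF_MARKERS = ("Csf1r", "Adgre1", "Cd68")
LC_MARKER = "Cd207"  # Langerhans-cell marker, planted on the S5 subtype only

# flow-style subtype markers planted so marker-gate analyses have real targets
DEFAULT_SUBTYPE_MARKERS: dict[str, str] = {
    "Folr2": "S1",
    "Cd163": "S1",
    "Ly6c1": "S3",
    "Ly6c2": "S3",
}


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell population: name, subtype (MOMF only) and size."""

    name: str
    subtype: str | None
    n_cells: int


@dataclass(frozen=True)
class LigandSpec:
    """A planted ligand-receptor pair and the cell types expressing the ligand."""

    ligand: str
    receptor: str
    expressing_types: tuple[str, ...]
    fold: float


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe a leukocyte-enriched mouse skin sample: five macrophage
    subtypes S1-S5 plus fibroblasts, keratinocytes and T cells, 81 signature
    genes per subtype (405 total), modest baseline expression with NB noise,
    13 ``mt-`` genes, and one fibroblast-restricted ligand whose receptor is
    elevated on macrophages.
    """

    n_genes: int = 1500
    cell_type_spec: list[CellTypeSpec] = field(
        default_factory=lambda: [
            CellTypeSpec("MF_S1", "S1", 200),
            CellTypeSpec("MF_S2", "S2", 200),
            CellTypeSpec("MF_S3", "S3", 200),
            CellTypeSpec("MF_S4", "S4", 200),
            CellTypeSpec("MF_S5", "S5", 200),
            CellTypeSpec("fibroblast", None, 150),
            CellTypeSpec("keratinocyte", None, 150),
            CellTypeSpec("endothelial", None, 100),
            CellTypeSpec("Tcell", None, 100),
        ]
    )
    signature_spec: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {s: (81, 8.0) for s in ("S1", "S2", "S3", "S4", "S5")}
    )
    baseline_mean: float = 0.2
    nb_dispersion: float = 2.0
    mito_gene_count: int = 13
    mito_fraction_range: tuple[float, float] = (0.02, 0.08)
    ligand_spec: list[LigandSpec] = field(
        default_factory=lambda: [
            LigandSpec("Lama2", "Itga6", ("fibroblast",), 20.0),
        ]
    )
    marker_fold: float = 25.0
    receptor_fold: float = 10.0
    n_decoy_pairs: int | None = None  # default: half the planted pairs, rounded up
    n_samples: int = 3
    sample_conditions: tuple[str, ...] = ("healthy", "AD")
    sample_libsize_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0 or self.mito_gene_count < 0:
            raise ValueError("counts must be positive")
        if not all(ct.n_cells > 0 for ct in self.cell_type_spec):
            raise ValueError("cell counts must be positive")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be > 0")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mito_fraction_range must lie within [0, 1]")
        for s, (n, f) in self.signature_spec.items():
            if n <= 0:
                raise ValueError(f"subtype {s}: signature gene count must be positive")
            if f < 1.0:
                raise ValueError(f"subtype {s}: fold-elevation must be >= 1")
        for ls in self.ligand_spec:
            if ls.fold < 1.0:
                raise ValueError(f"ligand {ls.ligand}: fold-elevation must be >= 1")
        known_subtypes = set(self.signature_spec)
        for ct in self.cell_type_spec:
            if ct.subtype is not None and ct.subtype not in known_subtypes:
                raise ValueError(f"cell type {ct.name}: unknown subtype {ct.subtype}")
        # signature gene sets are disjoint by construction (distinct name stems),
        # but a ligand/receptor name colliding with a generated name would alias
        names = [g for genes in signature_genes(self).values() for g in genes]
        if len(names) != len(set(names)):
            raise ValueError("signature gene sets overlap")

    @property
    def n_decoys(self) -> int:
        if self.n_decoy_pairs is not None:
            return self.n_decoy_pairs
        return math.ceil(len(self.ligand_spec) / 2)


def signature_genes(config: SimulationConfig) -> dict[str, list[str]]:
    """Planted signature gene names per subtype (deterministic from config)."""
    return {
        s: [f"Sig{s}_{i + 1:03d}" for i in range(n)]
        for s, (n, _) in config.signature_spec.items()
    }


def _gene_universe(config: SimulationConfig) -> list[str]:
    """Assemble the gene id list: mito, markers, signatures, ligand pairs,
    decoys, then anonymous filler up to ``n_genes``."""
    genes: list[str] = [f"mt-{i + 1}" for i in range(config.mito_gene_count)]
    genes += list(MOMF_MARKERS) + [LC_MARKER]
    genes += list(DEFAULT_SUBTYPE_MARKERS)
    for sig in signature_genes(config).values():
        genes += sig
    for ls in config.ligand_spec:
        for g in (ls.ligand, ls.receptor):
            if g not in genes:
                genes.append(g)
    for i in range(config.n_decoys):
        genes += [f"DecoyLig{i + 1}", f"DecoyRec{i + 1}"]
    if len(genes) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {len(genes)} structured genes"
        )
    genes += [f"Gene{i + 1:05d}" for i in range(config.n_genes - len(genes))]
    return genes


def simulate_counts(config: SimulationConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Draw the UMI count matrix and the per-cell ground truth.

    Returns an AnnData (cells x genes, sparse integer ``.X``) whose ``.obs``
    carries the truth columns, plus the same truth as a standalone frame
    (cell_id, cell_type, subtype, sample, condition, cluster).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    mito_idx = np.array(
        [gene_index[f"mt-{i + 1}"] for i in range(config.mito_gene_count)], dtype=int
    )
    nuclear = np.ones(len(genes), dtype=bool)
    nuclear[mito_idx] = False

    n_cells = sum(ct.n_cells for ct in config.cell_type_spec)
    sigs = signature_genes(config)

    # per-cell-type nuclear mean profile
    type_means: dict[str, np.ndarray] = {}
    for ct in config.cell_type_spec:
        mu = np.full(len(genes), config.baseline_mean)
        if ct.subtype is not None:
            n_sig, fold = config.signature_spec[ct.subtype]
            for g in sigs[ct.subtype]:
                mu[gene_index[g]] *= fold
            for m in MOMF_MARKERS:
                mu[gene_index[m]] *= config.marker_fold
            if ct.subtype == "S5":
                mu[gene_index[LC_MARKER]] *= config.marker_fold
            for m, s in DEFAULT_SUBTYPE_MARKERS.items():
                if s == ct.subtype:
                    mu[gene_index[m]] *= config.marker_fold
            for ls in config.ligand_spec:
                mu[gene_index[ls.receptor]] *= config.receptor_fold
            for i in range(config.n_decoys):
                mu[gene_index[f"DecoyRec{i + 1}"]] = 0.0  # absent from macrophages
        for ls in config.ligand_spec:
            if ct.name in ls.expressing_types:
                mu[gene_index[ls.ligand]] *= ls.fold
        mu[mito_idx] = 0.0  # filled per cell below
        type_means[ct.name] = mu

    # assemble per-cell truth; samples assigned round-robin within each type
    cell_type = np.empty(n_cells, dtype=object)
    subtype = np.empty(n_cells, dtype=object)
    sample = np.empty(n_cells, dtype=object)
    pos = 0
    for ct in config.cell_type_spec:
        for j in range(ct.n_cells):
            cell_type[pos] = ct.name
            subtype[pos] = ct.subtype
            sample[pos] = f"sample{j % config.n_samples + 1}"
            pos += 1
    conditions = {
        f"sample{i + 1}": config.sample_conditions[i % len(config.sample_conditions)]
        for i in range(config.n_samples)
    }
    lib_factors = {
        f"sample{i + 1}": (
            config.sample_libsize_factors[i] if config.sample_libsize_factors else 1.0
        )
        for i in range(config.n_samples)
    }

    # per-cell mean matrix: nuclear profile scaled by the sample's library
    # factor, mito block sized from the cell's target mito fraction
    mean = np.empty((n_cells, len(genes)), dtype=np.float64)
    for i in range(n_cells):
        mean[i] = type_means[cell_type[i]] * lib_factors[sample[i]]
    lo, hi = config.mito_fraction_range
    mito_frac = rng.uniform(lo, hi, size=n_cells)
    if config.mito_gene_count > 0:
        nuclear_load = mean[:, nuclear].sum(axis=1)
        mito_total = mito_frac / np.clip(1.0 - mito_frac, 1e-12, None) * nuclear_load
        mean[:, mito_idx] = (mito_total / config.mito_gene_count)[:, None]

    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    X = sp.csr_matrix(counts.astype(np.int32))

    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    truth = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_type.astype(str)),
            "subtype": [s if s is not None else "" for s in subtype],
            "sample": sample.astype(str),
            "condition": [conditions[s] for s in sample],
            # one simulated population per transcriptomic cluster
            "cluster": pd.Categorical(cell_type.astype(str)),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(
        X=X,
        obs=truth.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.uns["simulation"] = {"seed": config.seed, "n_genes": config.n_genes}
    return adata, truth


def simulate_embedding(
    truth: pd.DataFrame, spread: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Cluster-structured 2-D coordinates: one Gaussian blob per true cell type.

    Type centres sit on a circle of radius 10, so inter-centre distances are
    large relative to the default spread; coordinates are deterministic under a
    fixed seed. Returns a frame (x, y) indexed by cell id.
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    types = list(dict.fromkeys(truth["cell_type"]))
    angles = 2 * np.pi * np.arange(len(types)) / max(len(types), 1)
    centres = {t: 10.0 * np.array([np.cos(a), np.sin(a)]) for t, a in zip(types, angles)}
    coords = np.empty((len(truth), 2))
    for i, t in enumerate(truth["cell_type"]):
        coords[i] = centres[t] + rng.normal(0.0, spread, size=2)
    return pd.DataFrame(coords, columns=["x", "y"], index=truth.index)


def simulate_lr_table(
    config: SimulationConfig, n_decoys: int | None = None
) -> pd.DataFrame:
    """The ligand-receptor annotation table: planted pairs plus decoy pairs
    whose receptors are absent from the simulated macrophages.

    Decoy genes must exist in the configured gene universe; asking for more
    decoys than the generator planted is a configuration error.
    """
    if not config.ligand_spec:
        raise ValueError("ligand_spec is empty")
    if n_decoys is None:
        n_decoys = config.n_decoys
    if n_decoys > config.n_decoys:
        raise ValueError(
            f"requested {n_decoys} decoy pairs but only {config.n_decoys} decoy "
            "receptor genes exist in the simulated gene universe"
        )
    rows = [(ls.ligand, ls.receptor) for ls in config.ligand_spec]
    rows += [(f"DecoyLig{i + 1}", f"DecoyRec{i + 1}") for i in range(n_decoys)]
    if len(rows) != len(set(rows)):
        raise ValueError("duplicate (ligand, receptor) rows")
    return pd.DataFrame(rows, columns=["ligand", "receptor"])
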