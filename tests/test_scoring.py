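"""Subtype identity score: normalization contract, brute-force oracle
equivalence, the [0,1] population scaling, and marker-gate capture."""

import numpy as np
import pandas as pd
import pytest

import momfkit as mk
from conftest import make_adata


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain loops, no shared code with the package
def oracle_scores(X, genes, signatures):
    X = np.asarray(X, dtype=float)
    scaled = {}
    for j, g in enumerate(genes):
        col = X[:, j]
        sd = col.std()
        if sd > 0:
            scaled[g] = (col - col.mean()) / sd
    out = {}
    for s, gl in signatures.items():
        usable = [g for g in gl if g in scaled]
        if not usable:
            out[s] = np.zeros(X.shape[0])
            continue
        raw = np.zeros(X.shape[0])
        for i in range(X.shape[0]):
            raw[i] = sum(scaled[g][i] for g in usable) / len(usable)
        lo, hi = raw.min(), raw.max()
        out[s] = (raw - lo) / (hi - lo) if hi > lo else np.zeros(X.shape[0])
    return out


class TestNormalize:
    def test_hand_computed_single_cell(self):
        adata = make_adata([[2, 0]])
        norm = mk.normalize_expression(adata, scale_total=10)
        vals = np.asarray(norm.X.todense()).ravel()
        assert vals == pytest.approx([np.log1p(10), 0.0])

    def test_all_zero_gene_stays_zero(self):
        adata = make_adata([[1, 0], [3, 0]])
        norm = mk.normalize_expression(adata)
        assert np.asarray(norm.X.todense())[:, 1].sum() == 0

    def test_library_size_invariance(self):
        adata = make_adata([[2, 4, 6], [1, 2, 3]])
        norm = np.asarray(mk.normalize_expression(adata).X.todense())
        assert norm[0] == pytest.approx(norm[1])

    def test_zero_library_cell_rejected(self):
        adata = make_adata([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="zero library"):
            mk.normalize_expression(adata)


class TestScoreSubtypes:
    TOY = np.array([[2, 0, 1, 0, 0, 0], [0, 1, 0, 1, 0, 2], [1, 1, 1, 0, 1, 0], [0, 0, 0, 2, 2, 1]])
    SIGS = {"A": ["g1", "g2", "g3"], "B": ["g4", "g5", "g6"]}

    def test_frozen_toy_values(self):
        """4-cell x 6-gene toy, expected values frozen from an independent
        step-by-step computation of scale -> average -> min-max."""
        scores = mk.score_subtypes(make_adata(self.TOY), self.SIGS)
        assert scores.scores["A"].to_numpy() == pytest.approx(
            [0.84749372, 0.38416876, 1.0, 0.0], abs=1e-8
        )
        assert scores.scores["B"].to_numpy() == pytest.approx([0.0, 0.6, 0.2, 1.0], abs=1e-8)
        assert list(scores.assigned) == ["A", "B", "A", "B"]

    def test_oracle_equivalence_small_random_matrices(self):
        """Matches the brute-force oracle to 1e-10 on random matrices <=10x10."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n, g = rng.integers(3, 11), rng.integers(4, 11)
            X = rng.poisson(1.0, size=(n, g))
            genes = [f"g{j + 1}" for j in range(g)]
            k = rng.integers(1, g)
            sigs = {"A": genes[:k], "B": genes[k:]}
            got = mk.score_subtypes(make_adata(X, genes=genes), sigs)
            exp = oracle_scores(X, genes, sigs)
            for s in sigs:
                np.testing.assert_allclose(got.scores[s].to_numpy(), exp[s], atol=1e-10)

    def test_top_cell_scores_exactly_one(self):
        X = np.array([[9, 9, 0], [1, 1, 0], [0, 0, 1]])
        scores = mk.score_subtypes(make_adata(X), {"A": ["g1", "g2"], "B": ["g3"]})
        assert scores.scores.loc["c1", "A"] == 1.0

    def test_nondegenerate_columns_attain_zero_and_one(self, momf_scored):
        _, scores = momf_scored
        for s in scores.subtypes:
            if s not in scores.degenerate:
                assert scores.scores[s].min() == 0.0
                assert scores.scores[s].max() == 1.0
            assert scores.scores[s].between(0, 1).all()

    def test_constant_signature_is_degenerate(self):
        X = np.array([[1, 5], [1, 2], [1, 7]])
        scores = mk.score_subtypes(make_adata(X), {"A": ["g1"], "B": ["g2"]})
        assert scores.degenerate == ["A"]
        assert (scores.scores["A"] == 0).all()

    def test_missing_genes_dropped_all_missing_is_error(self):
        X = np.array([[1, 2], [3, 1]])
        scores = mk.score_subtypes(make_adata(X), {"A": ["g1", "nope"], "B": ["g2"]})
        assert scores.dropped_genes["A"] == ["nope"]
        with pytest.raises(ValueError, match="no signature genes"):
            mk.score_subtypes(make_adata(X), {"A": ["nope"], "B": ["g2"]})

    def test_fewer_than_two_cells_is_error(self):
        with pytest.raises(ValueError, match="2 cells"):
            mk.score_subtypes(make_adata([[1, 2]]), {"A": ["g1"], "B": ["g2"]})

    def test_argmax_tie_broken_by_signature_order(self):
        X = np.array([[2, 2], [0, 0]])
        scores = mk.score_subtypes(make_adata(X), {"S1": ["g1"], "S2": ["g2"]})
        assert (scores.scores["S1"] == scores.scores["S2"]).all()
        assert list(scores.assigned) == ["S1", "S1"]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(1.5, size=(8, 6))
        adata = make_adata(X)
        base = mk.score_subtypes(adata, self.SIGS)
        perm = rng.permutation(8)
        shuffled = mk.score_subtypes(adata[perm].copy(), self.SIGS)
        pd.testing.assert_frame_equal(base.scores.iloc[perm], shuffled.scores)

    def test_subset_scoring_changes_values(self):
        """Scores are population-relative: re-scoring a strict subset of cells
        generally changes individual scores."""
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, size=(12, 6))
        adata = make_adata(X)
        full = mk.score_subtypes(adata, self.SIGS)
        sub = mk.score_subtypes(adata[:6].copy(), self.SIGS)
        assert not np.allclose(full.scores.iloc[:6].to_numpy(), sub.scores.to_numpy())

    def test_parameter_recovery_on_synthetic_momf(self, sim_config, momf_scored):
        """Fold-elevation 8, 200 cells/subtype: >=95% of MOMF cells get their
        true subtype back."""
        momf, scores = momf_scored
        acc = (scores.assigned == momf.obs["subtype"]).mean()
        assert acc >= 0.95


class TestMarkerGates:
    S1_GATE = mk.MarkerGate(
        "Ly6c12-Folr2Cd163+", positive=("Folr2", "Cd163"), negative=("Ly6c1", "Ly6c2"), rule="any"
    )

    def test_gate_membership_rules(self):
        genes = ["Folr2", "Cd163", "Ly6c1", "Ly6c2"]
        X = np.array(
            [[1, 0, 0, 0],   # Folr2+ only: in ("any")
             [1, 1, 0, 0],   # both positives: in
             [0, 0, 0, 0],   # no positive: out
             [1, 0, 2, 0]]   # Ly6c1 detected: out (negative marker)
        )
        adata = make_adata(X, genes=genes)
        assert list(self.S1_GATE.member_mask(adata)) == [True, True, False, False]
        all_rule = mk.MarkerGate("both", positive=("Folr2", "Cd163"), rule="all")
        assert list(all_rule.member_mask(adata)) == [False, True, False, False]

    def test_absent_gate_gene_is_error(self):
        adata = make_adata([[1]], genes=["Folr2"])
        gate = mk.MarkerGate("g", positive=("Folr2",), negative=("Nope",))
        with pytest.raises(ValueError, match="Nope"):
            gate.member_mask(adata)

    def test_empty_gate_flagged(self, momf_scored):
        momf, scores = momf_scored
        never = mk.MarkerGate("never", positive=("Folr2",), negative=("Folr2",))
        cap = mk.marker_gate_capture(momf, scores, [never])
        assert bool(cap.loc["never", "empty"])
        assert np.isnan(cap.loc["never", "capture_S1"])

    def test_capture_matches_direct_enumeration(self, momf_scored):
        """Capture fractions equal brute-force enumeration over cells."""
        momf, scores = momf_scored
        cap = mk.marker_gate_capture(momf, scores, [self.S1_GATE])
        det = {g: np.asarray(momf[:, g].X.todense()).ravel() >= 1 for g in ("Folr2", "Cd163", "Ly6c1", "Ly6c2")}
        manual = (det["Folr2"] | det["Cd163"]) & ~det["Ly6c1"] & ~det["Ly6c2"]
        assert cap.loc[self.S1_GATE.name, "n_cells"] == manual.sum()
        for s in scores.subtypes:
            frac = (scores.assigned[manual] == s).mean()
            assert cap.loc[self.S1_GATE.name, f"capture_{s}"] == pytest.approx(frac)

    def test_s1_gate_captures_planted_s1(self, momf_scored):
        """On synthetic data the Ly6c1/2- Folr2/Cd163+ gate is dominated by
        planted S1 cells."""
        momf, scores = momf_scored
        cap = mk.marker_gate_capture(momf, scores, [self.S1_GATE])
        captures = {s: cap.loc[self.S1_GATE.name, f"capture_{s}"] for s in scores.subtypes}
        assert max(captures, key=captures.get) == "S1"

    def test_perfectly_separable_gate_captures_at_100_percent(self):
        """When S1 cells exclusively express Folr2/Cd163 and lack Ly6c1/2 the
        gate captures S1 at exactly 100%."""
        genes = ["Folr2", "Cd163", "Ly6c1", "Ly6c2", "SigA", "SigB"]
        X = np.array(
            [[3, 2, 0, 0, 5, 0],
             [2, 0, 0, 0, 4, 0],
             [0, 0, 2, 1, 0, 5],
             [0, 0, 1, 3, 0, 4]]
        )
        adata = make_adata(X, genes=genes)
        scores = mk.score_subtypes(adata, {"S1": ["Folr2", "Cd163", "SigA"], "S3": ["Ly6c1", "Ly6c2", "SigB"]})
        cap = mk.marker_gate_capture(adata, scores, [self.S1_GATE])
        assert cap.loc[self.S1_GATE.name, "n_cells"] == 2
        assert cap.loc[self.S1_GATE.name, "capture_S1"] == 1.0
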