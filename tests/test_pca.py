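"""Leave-one-out PC1 correlation scores and expression-based reassignment."""

import numpy as np
import pytest

from pathxtalk.diffexpr import ExpressionMatrix
from pathxtalk.pca_correct import build_correlation_matrix, pc1, pca_correct
from pathxtalk.synthdata import SynthesisSpec, generate_expression, generate_membership


def _expr_from(X, values):
    return ExpressionMatrix(
        gene_ids=list(X.gene_ids),
        sample_ids=[f"S{j}" for j in range(values.shape[1])],
        values=values,
        groups=["a"] * (values.shape[1] // 2) + ["b"] * (values.shape[1] - values.shape[1] // 2),
    )


class TestPc1:
    def test_matches_svd_oracle_up_to_sign(self, rng):
        E = rng.normal(size=(4, 6))
        comp = pc1(E)
        M = E - E.mean(axis=1, keepdims=True)
        _, s, Vt = np.linalg.svd(M, full_matrices=False)
        oracle = s[0] * Vt[0]
        assert min(
            np.abs(comp.scores - oracle).max(),
            np.abs(comp.scores + oracle).max(),
        ) < 1e-10

    def test_rank_one_matrix_recovers_common_direction(self, rng):
        v = rng.normal(size=8)
        coeffs = np.array([1.0, -2.0, 0.5])
        E = np.outer(coeffs, v)
        comp = pc1(E)
        vc = v - v.mean()
        r = np.corrcoef(comp.scores, vc)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_single_row_returns_centered_row(self):
        row = np.array([[1.0, 2.0, 4.0]])
        comp = pc1(row)
        assert np.allclose(comp.scores, row[0] - row.mean())
        assert not comp.degenerate

    def test_constant_matrix_flagged_degenerate(self):
        comp = pc1(np.full((3, 5), 2.0))
        assert comp.degenerate
        assert np.allclose(comp.scores, 0)

    def test_sign_convention_largest_loading_positive(self, rng):
        E = rng.normal(size=(5, 10))
        comp = pc1(E)
        flipped = pc1(-E)
        # the convention resolves the sign deterministically in both cases
        assert np.allclose(np.abs(comp.scores), np.abs(flipped.scores))


class TestCorrelationMatrix:
    def test_nonmember_cells_are_zero(self, toy_membership, rng):
        X = toy_membership({"A": {"g1", "g2"}, "B": {"g3", "g4"}}, de_genes=set())
        expr = _expr_from(X, rng.normal(size=(4, 10)))
        C = build_correlation_matrix(X, expr)
        assert np.all(C.values[X.values == 0] == 0)

    def test_two_gene_pathway_identical_rows_score_one(self, toy_membership, rng):
        X = toy_membership({"A": {"g1", "g2"}}, de_genes=set())
        row = rng.normal(size=10)
        expr = _expr_from(X, np.vstack([row, row]))
        C = build_correlation_matrix(X, expr)
        assert C.values[X.values == 1] == pytest.approx(1.0)

    def test_gene_tracking_one_factor_prefers_that_pathway(self, toy_membership, rng):
        # gene "x" belongs to A and B but follows A's latent factor exactly
        X = toy_membership(
            {"A": {"a1", "a2", "a3", "x"}, "B": {"b1", "b2", "b3", "x"}},
            de_genes=set(),
        )
        fA, fB = rng.normal(size=(2, 30))
        values = np.zeros((7, 30))
        for i, g in enumerate(X.gene_ids):
            f = fA if g.startswith("a") or g == "x" else fB
            values[i] = f
        C = build_correlation_matrix(X, _expr_from(X, values))
        gi = X.gene_index()["x"]
        pa, pb = X.pathway_index()["A"], X.pathway_index()["B"]
        assert C.values[gi, pa] == pytest.approx(1.0)
        assert C.values[gi, pb] < 0.5

    def test_singleton_pathway_flagged_degenerate(self, toy_membership, rng):
        X = toy_membership({"A": {"g1"}, "B": {"g1", "g2"}}, de_genes=set())
        expr = _expr_from(X, rng.normal(size=(2, 8)))
        C = build_correlation_matrix(X, expr)
        gi, pa = X.gene_index()["g1"], X.pathway_index()["A"]
        assert C.degenerate[gi, pa]


class TestPcaCorrect:
    def _recovery(self, noise_sd, seed=0):
        spec = SynthesisSpec(
            n_pathways=12, universe_size=240, n_de=40,
            noise_sd=noise_sd, seed=seed,
        )
        X, truth = generate_membership(spec)
        expr = generate_expression(X, truth, spec)
        Z = pca_correct(X, expr)
        multi = np.flatnonzero(X.values.sum(axis=1) > 1)
        pw_index = X.pathway_index()
        correct = sum(
            Z.values[i, pw_index[truth.true_assignment[X.gene_ids[i]]]] == 1
            for i in multi
        )
        return correct / len(multi)

    def test_zero_noise_recovers_every_assignment(self):
        assert self._recovery(noise_sd=0.0) == 1.0

    def test_moderate_noise_recovers_most_assignments(self):
        assert self._recovery(noise_sd=0.25) >= 0.90

    def test_single_membership_gene_assigned_to_its_pathway(self, toy_membership, rng):
        X = toy_membership({"A": {"g1", "g2"}, "B": {"g3"}}, de_genes=set())
        Z = pca_correct(X, _expr_from(X, rng.normal(size=(3, 8))))
        gi, pb = X.gene_index()["g3"], X.pathway_index()["B"]
        assert Z.values[gi, pb] == 1
        assert (Z.values.sum(axis=1) == 1).all()
        assert (Z.values <= X.values).all()

    def test_invariance_to_subject_order_and_row_shifts(self, toy_membership, rng):
        X = toy_membership(
            {"A": {"g1", "g2", "g3"}, "B": {"g3", "g4", "g5"}}, de_genes=set()
        )
        values = rng.normal(size=(5, 16))
        Z1 = pca_correct(X, _expr_from(X, values)).values
        perm = rng.permutation(16)
        Z2 = pca_correct(X, _expr_from(X, values[:, perm])).values
        assert np.array_equal(Z1, Z2)
        shifted = values.copy()
        shifted[2] += 100.0  # constant offset on one gene row
        Z3 = pca_correct(X, _expr_from(X, shifted)).values
        assert np.array_equal(Z1, Z3)

    def test_correlations_invariant_to_positive_row_scaling(self, toy_membership, rng):
        X = toy_membership({"A": {"g1", "g2", "g3"}}, de_genes=set())
        values = rng.normal(size=(3, 12))
        C1 = build_correlation_matrix(X, _expr_from(X, values)).values
        scaled = values.copy()
        scaled[0] *= 7.5
        C2 = build_correlation_matrix(X, _expr_from(X, scaled)).values
        gi = X.gene_index()["g1"]
        assert C1[gi] == pytest.approx(C2[gi])

    def test_all_degenerate_falls_back_to_largest_pathway(self, toy_membership):
        X = toy_membership(
            {"A": {"g1", "g2", "g3"}, "B": {"g1", "g4"}}, de_genes=set()
        )
        expr = _expr_from(X, np.zeros((4, 8)))
        Z = pca_correct(X, expr)
        gi = X.gene_index()["g1"]
        assert Z.values[gi, X.pathway_index()["A"]] == 1  # |A| = 3 > |B| = 2
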