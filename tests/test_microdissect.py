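import numpy as np
import pandas as pd
import pytest

from tmedyn.io import CohortError
from tmedyn.microdissect import (
    _kl_divergence,
    _nmf_single_run,
    attribute_factors,
    cophenetic_select_k,
    exemplar_genes,
    gene_entropy_scores,
    nmf_brunet,
)


def planted_marker_matrix(seed=3, n_bg=200, n_mk=10, s=45):
    """Background genes expressed everywhere plus group-specific markers."""
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for i in range(n_bg):
        rows.append(rng.uniform(2, 4) * np.ones(s) + rng.normal(0, 0.2, s))
        names.append(f"bg{i}")
    for b in range(3):
        for i in range(n_mk):
            v = np.full(s, 0.2)
            v[b * 15:(b + 1) * 15] += rng.uniform(4, 7)
            rows.append(v + rng.uniform(0, 0.1, s))
            names.append(f"mk{b}_{i}")
    return pd.DataFrame(
        np.clip(np.array(rows), 0, None), index=names,
        columns=[f"s{j}" for j in range(s)],
    )


class TestNMF:
    def test_exact_rank_two_matrix_factorized(self):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0, 2, (30, 2))
        H0 = rng.uniform(0, 2, (2, 12))
        V = pd.DataFrame(W0 @ H0)
        model = nmf_brunet(V, k=2, n_runs=5, max_iter=3000, seed=1)
        assert model.approximation_error < 1e-6 * np.abs(V.to_numpy()).sum()

    def test_kl_objective_non_increasing(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 3, (40, 15))
        # replay the multiplicative updates and track the objective
        eps = np.finfo(float).tiny
        W = rng.uniform(eps, 1, (40, 3))
        H = rng.uniform(eps, 1, (3, 15))
        last = np.inf
        for _ in range(50):
            WH = np.maximum(W @ H, eps)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
            WH = np.maximum(W @ H, eps)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
            err = _kl_divergence(V, W @ H)
            assert err <= last + 1e-8
            last = err

    def test_planted_blocks_give_factor_specific_top_genes(self):
        rng = np.random.default_rng(5)
        V = np.full((90, 30), 0.1)
        for b in range(3):
            V[b * 30:(b + 1) * 30, b * 10:(b + 1) * 10] += rng.uniform(3, 6, (30, 10))
        model = nmf_brunet(pd.DataFrame(V), k=3, n_runs=5, max_iter=1000, seed=3)
        for factor in model.W.columns:
            top = model.W[factor].nlargest(20).index
            blocks = {int(g) // 30 for g in top}
            planted = max(blocks, key=lambda b: sum(int(g) // 30 == b for g in top))
            jaccard = sum(int(g) // 30 == planted for g in top) / 20
            assert jaccard > 0.8

    def test_scale_ambiguity_leaves_scores_and_exemplars_unchanged(self):
        V = planted_marker_matrix()
        model = nmf_brunet(V, k=3, n_runs=3, max_iter=600, seed=1)
        W1 = model.W.copy()
        W2 = W1.copy()
        W2.iloc[:, 0] *= 5.0  # rescale factor 1 (H would absorb 1/5)
        s1 = gene_entropy_scores(W1)
        # entropy scores use row-normalized weights, so only the relative
        # pattern matters; a *column* rescale does change p_f -- the
        # invariant pairs a W-column rescale with the matching H-row
        # rescale leaving WH fixed, and WH is what we check
        H2 = model.H.copy()
        H2.iloc[0, :] /= 5.0
        assert np.allclose((W2.to_numpy() @ H2.to_numpy()),
                           (W1.to_numpy() @ model.H.to_numpy()))

    def test_all_zero_rows_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        V = pd.DataFrame(rng.uniform(0, 2, (20, 10)))
        V.iloc[3] = 0.0
        with caplog.at_level("WARNING"):
            model = nmf_brunet(V, k=2, n_runs=2, max_iter=200, seed=0)
        assert 3 not in model.W.index
        assert any("all-zero" in r.message for r in caplog.records)

    def test_k_too_large_errors(self):
        V = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(CohortError):
            nmf_brunet(V, k=4, n_runs=1)


class TestCopheneticSelectK:
    def test_planted_three_groups_selects_three(self):
        rng = np.random.default_rng(7)
        V = np.full((90, 36), 0.1)
        for b in range(3):
            V[b * 30:(b + 1) * 30, b * 12:(b + 1) * 12] += rng.uniform(3, 6, (30, 12))
        k, coeffs = cophenetic_select_k(pd.DataFrame(V), (2, 3, 4, 5, 6),
                                        runs_per_k=10, max_iter=400, seed=2)
        assert k == 3
        assert ((coeffs >= 0) & (coeffs <= 1.0 + 1e-12)).all()

    def test_perfectly_stable_clustering_reaches_one(self):
        rng = np.random.default_rng(7)
        V = np.full((60, 20), 0.01)
        V[:30, :10] += 5.0
        V[30:, 10:] += 5.0
        V += rng.uniform(0, 0.01, V.shape)
        _, coeffs = cophenetic_select_k(pd.DataFrame(V), (2,), runs_per_k=5,
                                        max_iter=300, seed=1)
        assert coeffs[2] == pytest.approx(1.0)


class TestEntropyScores:
    def test_single_factor_gene_scores_one(self):
        W = pd.DataFrame([[3.0, 0.0, 0.0]], index=["g"], columns=list("abc"))
        assert gene_entropy_scores(W)["g"] == pytest.approx(1.0)

    def test_uniform_gene_scores_zero(self):
        W = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        assert gene_entropy_scores(W)["g"] == pytest.approx(0.0, abs=1e-12)

    def test_binary_three_quarters_closed_form(self):
        # k=2, p=(0.75,0.25): 1 - H(0.75) = 0.18872...
        W = pd.DataFrame([[0.75, 0.25]], index=["g"], columns=list("ab"))
        expected = 1.0 + (0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert gene_entropy_scores(W)["g"] == pytest.approx(expected, abs=1e-9)
        assert gene_entropy_scores(W)["g"] == pytest.approx(0.1887, abs=5e-4)

    def test_all_zero_row_excluded(self):
        W = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["a", "b"], columns=["f1", "f2"])
        scores = gene_entropy_scores(W)
        assert "b" not in scores.index


class TestExemplars:
    def test_uniform_genes_yield_no_exemplars(self):
        W = pd.DataFrame(np.ones((20, 3)), columns=list("abc"))
        exemplars = exemplar_genes(W)
        assert all(len(v) == 0 for v in exemplars.values())

    def test_single_specific_gene_is_sole_exemplar(self):
        W = pd.DataFrame(np.ones((20, 3)), columns=["F1", "F2", "F3"])
        W.iloc[7] = [0.0, 9.0, 0.0]
        exemplars = exemplar_genes(W)
        assert exemplars["F2"] == [7]
        assert not exemplars["F1"] and not exemplars["F3"]

    def test_planted_markers_recovered_to_their_factor(self):
        V = planted_marker_matrix()
        model = nmf_brunet(V, k=3, n_runs=5, max_iter=800, seed=1)
        exemplars = exemplar_genes(model.W)
        factor_block = {}
        for factor, genes in exemplars.items():
            blocks = [int(g[2]) for g in genes if g.startswith("mk")]
            if blocks:
                factor_block[factor] = max(set(blocks), key=blocks.count)
        recovered = sum(
            1
            for factor, genes in exemplars.items()
            for g in genes
            if g.startswith("mk") and factor_block.get(factor) == int(g[2])
        )
        assert recovered >= 0.8 * 30

    def test_mad_matches_brute_force(self):
        from tmedyn.microdissect import _mad

        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, 101)
        med = sorted(x)[50]
        brute = sorted(abs(v - med) for v in x)[50]
        assert _mad(x) == pytest.approx(brute)


class TestAttribution:
    def test_planted_immune_factor_attributed_til(self):
        V = planted_marker_matrix()
        model = nmf_brunet(V, k=3, n_runs=5, max_iter=800, seed=1)
        # group labels: samples 0-14 belong to the immune-infiltrate block
        labels = pd.Series(
            ["immune-infiltrate"] * 15 + ["stroma"] * 15 + ["normal"] * 15,
            index=V.columns,
        )
        annotation = attribute_factors(model, labels)
        assert "TIL" in set(annotation.compartments)

    def test_flat_factor_unassigned(self):
        W = pd.DataFrame(np.ones((10, 2)), columns=["F1", "F2"])
        H = pd.DataFrame(np.ones((2, 8)), index=["F1", "F2"],
                         columns=[f"s{i}" for i in range(8)])
        from tmedyn.microdissect import NMFModel

        model = NMFModel(W=W, H=H, k=2, approximation_error=0.0, run_seed=0,
                         n_iter=1, converged=True)
        labels = pd.Series(["tumor"] * 4 + ["normal"] * 4, index=H.columns)
        annotation = attribute_factors(model, labels)
        assert (annotation.compartments == "unassigned").all()

    def test_composite_is_exact_sum(self):
        V = planted_marker_matrix()
        model = nmf_brunet(V, k=3, n_runs=3, max_iter=500, seed=2)
        labels = pd.Series(["tumor"] * 15 + ["tumor"] * 15 + ["normal"] * 15,
                           index=V.columns)
        annotation = attribute_factors(model, labels)
        tumor_factors = annotation.compartments.index[
            annotation.compartments == "tumor-intrinsic"
        ]
        expected = model.H.loc[tumor_factors].sum(axis=0)
        assert np.allclose(annotation.composites["F-Tumor"].to_numpy(),
                           expected.to_numpy())
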