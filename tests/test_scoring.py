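import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmedyn.io import CohortError
from tmedyn.scoring import (
    bh_adjust,
    cyt_score,
    gsva_scores,
    hypergeom_enrichment,
    log_transform,
    zscale,
)


def brute_force_gsva(expr: pd.DataFrame, members: list[str], tau: float, max_diff: bool):
    """Independent straightforward implementation of the kernel-ECDF
    random-walk score, written as plain loops against the definition."""
    p, n = expr.shape
    genes = list(expr.index)
    # Gaussian kernel ECDF per gene
    z = np.zeros((p, n))
    for i in range(p):
        x = expr.iloc[i].to_numpy(dtype=float)
        h = np.std(x, ddof=1) / 4.0
        for j in range(n):
            z[i, j] = sum(stats.norm.cdf((x[j] - x[k]) / h) for k in range(n)) / n
    scores = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], i))
        ranks = {gene_idx: pos + 1 for pos, gene_idx in enumerate(order)}
        weights = {i: abs((p + 1) / 2.0 - ranks[i]) for i in range(p)}
        inside = [genes[i] in members for i in range(p)]
        wsum = sum(weights[i] ** tau for i in range(p) if inside[i])
        n_out = sum(1 for flag in inside if not flag)
        running, walk = 0.0, []
        for i in order:
            if inside[i]:
                running += weights[i] ** tau / wsum
            else:
                running -= 1.0 / n_out
            walk.append(running)
        max_pos = max(max(walk), 0.0)
        max_neg = max(-min(walk), 0.0)
        scores.append(max_pos - max_neg if max_diff else
                      (max_pos if max_pos >= max_neg else -max_neg))
    return np.array(scores)


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_pointwise(self, value, expected):
        expr = pd.DataFrame([[value]], index=["g"], columns=["s"])
        assert log_transform(expr).iloc[0, 0] == pytest.approx(expected)

    def test_negative_input_errors(self):
        expr = pd.DataFrame([[-1.0]], index=["g"], columns=["s"])
        with pytest.raises(CohortError):
            log_transform(expr)


class TestCytScore:
    def test_geometric_mean(self):
        expr = pd.DataFrame([[4.0], [9.0]], index=["GZMA", "PRF1"], columns=["s"])
        assert cyt_score(expr, offset=0.0).iloc[0] == pytest.approx(6.0)

    def test_equal_genes_idempotent(self):
        expr = pd.DataFrame([[5.0], [5.0]], index=["GZMA", "PRF1"], columns=["s"])
        assert cyt_score(expr, offset=0.0).iloc[0] == pytest.approx(5.0)

    def test_offset_floor(self):
        expr = pd.DataFrame([[0.0], [0.0]], index=["GZMA", "PRF1"], columns=["s"])
        assert cyt_score(expr, offset=0.01).iloc[0] == pytest.approx(0.01)

    def test_missing_gene_named(self):
        expr = pd.DataFrame([[1.0]], index=["GZMA"], columns=["s"])
        with pytest.raises(CohortError, match="PRF1"):
            cyt_score(expr)

    def test_scale_equivariance(self, tiny_expr):
        expr = tiny_expr.rename(index={"g1": "GZMA", "g2": "PRF1"})
        base = cyt_score(expr, offset=0.0)
        scaled = cyt_score(expr * 3.0, offset=0.0)
        assert np.allclose(scaled.to_numpy(), 3.0 * base.to_numpy())


class TestGSVA:
    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(0, 5, 6)
        expr = pd.DataFrame(
            {"A": col, "B": col, "C": rng.uniform(0, 5, 6)},
            index=[f"g{i}" for i in range(6)],
        )
        scores = gsva_scores(expr, {"S": ["g0", "g1"]})
        assert scores["A"].iloc[0] == pytest.approx(scores["B"].iloc[0], abs=1e-12)

    def test_reversed_ranking_negates_score(self, tiny_expr):
        sets = {"S": ["g1", "g2"]}
        scores = gsva_scores(tiny_expr, sets)
        flipped = gsva_scores(-tiny_expr + tiny_expr.to_numpy().max(), sets)
        assert np.allclose(flipped.to_numpy(), -scores.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("tau,max_diff", [(1.0, True), (1.0, False), (0.5, True)])
    def test_matches_brute_force_oracle(self, tiny_expr, tau, max_diff):
        members = ["g1", "g2"]
        ours = gsva_scores(tiny_expr, {"S": members}, tau=tau, max_diff=max_diff)
        oracle = brute_force_gsva(tiny_expr, members, tau, max_diff)
        assert np.allclose(ours.loc["S"].to_numpy(), oracle, atol=1e-9)

    def test_sample_reordering_invariance(self, tiny_expr):
        sets = {"S": ["g1", "g3"]}
        base = gsva_scores(tiny_expr, sets)
        shuffled = gsva_scores(tiny_expr[["C", "A", "D", "B"]], sets)
        assert np.allclose(base[["C", "A", "D", "B"]].to_numpy(), shuffled.to_numpy())

    def test_empty_overlap_reported_missing(self, tiny_expr, caplog):
        with caplog.at_level("WARNING"):
            scores = gsva_scores(tiny_expr, {"S": ["absent1", "absent2"]})
        assert scores.loc["S"].isna().all()


class TestZScale:
    def test_simple_row(self):
        scores = pd.DataFrame([[1.0, 2.0, 3.0]], index=["s"], columns=list("abc"))
        assert np.allclose(zscale(scores).to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_becomes_zero_with_warning(self, caplog):
        scores = pd.DataFrame([[2.0, 2.0, 2.0]], index=["s"], columns=list("abc"))
        with caplog.at_level("WARNING"):
            out = zscale(scores)
        assert np.allclose(out.to_numpy(), 0.0)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_idempotent(self, tiny_expr):
        once = zscale(tiny_expr)
        twice = zscale(once)
        pd.testing.assert_frame_equal(once, twice)


class TestHypergeom:
    def test_certain_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        p, overlap = hypergeom_enrichment(universe, universe, universe)
        assert p == pytest.approx(1.0)
        assert overlap == 10

    def test_closed_form_full_overlap(self):
        # choosing all 5 pathway genes in a 5-gene cluster from 10:
        # p = 1 / C(10,5) = 1/252
        universe = [f"g{i}" for i in range(10)]
        pathway = universe[:5]
        p, overlap = hypergeom_enrichment(pathway, pathway, universe)
        assert overlap == 5
        assert p == pytest.approx(1.0 / 252.0, rel=1e-12)

    def test_zero_overlap_is_full_upper_tail(self):
        universe = [f"g{i}" for i in range(20)]
        p, overlap = hypergeom_enrichment(universe[:5], universe[10:15], universe)
        assert overlap == 0
        assert p == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(CohortError):
            hypergeom_enrichment([], [], [])


class TestBH:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_permutation_keeps_gene_attachment(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        adj = bh_adjust(p)
        adj_perm = bh_adjust(p[perm])
        assert np.allclose(adj[perm], adj_perm)
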