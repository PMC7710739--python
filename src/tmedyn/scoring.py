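"""Expression normalization and per-sample gene-set scoring.

Implements log2(TPM+1) transformation, the cytolytic-activity (CYT) score
(geometric mean of GZMA and PRF1), single-sample gene-set scoring in the
GSVA style (Gaussian-kernel ECDF per gene followed by a weighted
Kolmogorov–Smirnov-like random walk over each sample's gene ranking), row
z-scaling, hypergeometric enrichment and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortError

logger = logging.getLogger(__name__)

__all__ = [
    "log_transform",
    "cyt_score",
    "gsva_scores",
    "zscale",
    "hypergeom_enrichment",
    "enrichment_table",
    "bh_adjust",
]


def log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``log2(x + 1)`` of a TPM-scale matrix."""
    if (expr.to_numpy() < 0).any():
        raise CohortError("log_transform: negative input values")
    return np.log2(expr + 1.0)


def cyt_score(expr: pd.DataFrame, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity per sample: sqrt((GZMA+offset)*(PRF1+offset)).

    The small offset guards against zero expression; 0.01 is the
    convention of the cytolytic-activity literature.
    """
    if offset < 0:
        raise CohortError("cyt_score: offset must be >= 0")
    for gene in ("GZMA", "PRF1"):
        if gene not in expr.index:
            raise CohortError(f"cyt_score: gene {gene!r} missing from matrix")
    gzma = expr.loc["GZMA"].to_numpy(dtype=float)
    prf1 = expr.loc["PRF1"].to_numpy(dtype=float)
    score = np.sqrt((gzma + offset) * (prf1 + offset))
    return pd.Series(score, index=expr.columns, name="CYT")


# ---------------------------------------------------------------------------
# GSVA-style scoring
# ---------------------------------------------------------------------------

def _kernel_ecdf(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel cumulative density estimate of each value against the
    sample distribution of its own gene (bandwidth sd/4).

    ``values`` is genes x samples; returns the same shape. A zero-variance
    gene degenerates to ties (0.5 everywhere)."""
    n = values.shape[1]
    sd = values.std(axis=1, ddof=1)
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        if sd[i] <= 0:
            out[i] = 0.5
            continue
        h = sd[i] / 4.0
        diff = (values[i][:, None] - values[i][None, :]) / h
        out[i] = stats.norm.cdf(diff).sum(axis=1) / n
    return out


def _walk_scores(
    order: np.ndarray, weights: np.ndarray, in_set: np.ndarray, tau: float, max_diff: bool
) -> float:
    """KS-like random walk down one sample's ranking.

    ``order``: gene indices sorted by decreasing statistic; ``weights``:
    symmetric rank weights |(p+1)/2 - rank|; ``in_set``: bool per gene.
    """
    w = np.abs(weights[order]) ** tau
    inside = in_set[order]
    n_out = (~in_set).sum()
    steps = np.where(inside, w / w[inside].sum(), -1.0 / n_out)
    walk = np.cumsum(steps)
    max_pos = max(walk.max(), 0.0)
    max_neg = max(-walk.min(), 0.0)
    if max_diff:
        return max_pos - max_neg
    return max_pos if max_pos >= max_neg else -max_neg


def gsva_scores(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    tau: float = 1.0,
    max_diff: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set scores (sets x samples).

    Per gene, a Gaussian-kernel ECDF statistic is computed across samples
    (bandwidth sd/4); per sample, genes are ranked by that statistic; per
    set, a weighted KS-like random walk with exponent ``tau`` runs down the
    ranking with symmetric rank weights ``|(p+1)/2 - rank|``. The score is
    the difference between the maximum positive and maximum negative walk
    deviation when ``max_diff``, else the single largest-magnitude
    deviation. Sets with no genes in the matrix are reported as NaN rows
    with a warning.
    """
    if expr.shape[1] < 3:
        raise CohortError("gsva_scores: need at least 3 samples")
    genes = expr.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    p, n = expr.shape

    z = _kernel_ecdf(expr.to_numpy(dtype=float))
    # per sample: rank genes by decreasing statistic (stable in gene order)
    orders = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(orders)
    cols = np.arange(n)
    ranks[orders, cols[None, :]] = np.arange(1, p + 1)[:, None]
    weights = np.abs((p + 1) / 2.0 - ranks)  # symmetric: large at both extremes

    scores = np.full((len(sets), n), np.nan)
    for si, (name, members) in enumerate(sets.items()):
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            logger.warning("gene set %s has no genes in the matrix; score undefined", name)
            continue
        if len(idx) == p:
            raise CohortError(f"gene set {name!r} covers the whole gene universe")
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        for j in range(n):
            scores[si, j] = _walk_scores(orders[:, j], weights[:, j], in_set, tau, max_diff)
    return pd.DataFrame(scores, index=list(sets), columns=expr.columns)


def zscale(scores: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sd 1 (ddof=1).

    Zero-variance rows become all-zero with a warning.
    """
    if scores.shape[1] < 2:
        raise CohortError("zscale: need at least 2 samples")
    values = scores.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] <= 0
    if flat.any():
        logger.warning("zscale: %d zero-variance rows set to 0", int(flat.sum()))
    sd[flat] = 1.0
    out = (values - mean) / sd
    out[flat.nonzero()[0], :] = 0.0
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(
    cluster_genes: list[str], pathway_genes: list[str], universe: list[str]
) -> tuple[float, int]:
    """Upper-tail hypergeometric probability of >= observed overlap.

    Universe = genes eligible for membership (typically all genes in the
    filtered expression matrix). Returns (p, overlap).
    """
    universe_set = set(universe)
    if not universe_set:
        raise CohortError("hypergeom_enrichment: empty universe")
    cluster = set(cluster_genes)
    if cluster - universe_set:
        raise CohortError("hypergeom_enrichment: cluster genes outside universe")
    pathway = set(pathway_genes) & universe_set
    overlap = len(cluster & pathway)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe_set), len(pathway), len(cluster)))
    return min(p, 1.0), overlap


def enrichment_table(
    cluster_genes: list[str], pathways: dict[str, list[str]], universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric enrichment of one cluster against many pathways,
    with Benjamini-Hochberg FDR across pathways."""
    rows = []
    for name, genes in pathways.items():
        p, overlap = hypergeom_enrichment(cluster_genes, genes, universe)
        rows.append({"pathway": name, "overlap": overlap, "p": p})
    table = pd.DataFrame(rows).set_index("pathway")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
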