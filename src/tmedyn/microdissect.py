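"""Virtual microdissection of bulk expression by non-negative matrix
factorization.

A log2(TPM+1) matrix V (genes x samples) is factorized as V ~ W H with W
(genes x k) holding gene weights and H (k x samples) sample weights, by
Kullback-Leibler multiplicative updates from random non-negative starts
(the classic Brunet scheme). Convergence is declared when the sample
connectivity matrix (argmax factor per sample) is unchanged for a fixed
number of consecutive checks. Several runs are performed and the
factorization with the lowest KL approximation error kept.

The factorization rank is selected by the cophenetic correlation of the
sample consensus matrix across runs, and factor-specific exemplar genes
are extracted with an entropy-based specificity score plus a
max-contribution criterion. Factors are then attributed to tissue
compartments (tumor-intrinsic, TIL, stromal, normal) from labeled sample
groups and exemplar pathway enrichments, with tumor and normal factors
summed into the composite F-Tumor and F-Normal weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .io import CohortError

logger = logging.getLogger(__name__)

__all__ = [
    "NMFModel",
    "nmf_brunet",
    "cophenetic_select_k",
    "gene_entropy_scores",
    "exemplar_genes",
    "attribute_factors",
    "FactorAnnotation",
]

_EPS = np.finfo(float).tiny


@dataclass
class NMFModel:
    W: pd.DataFrame  # genes x k
    H: pd.DataFrame  # k x samples
    k: int
    approximation_error: float  # KL divergence D(V || WH)
    run_seed: int
    n_iter: int
    converged: bool


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    div = float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())
    return max(div, 0.0)


def _nmf_single_run(
    V: np.ndarray, k: int, max_iter: int, seed: int,
    check_interval: int = 10, patience: int = 40,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    rng = np.random.default_rng(seed)
    g, s = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(g, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, s)) * scale

    last_conn = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % check_interval == 0:
            conn = H.argmax(axis=0)
            if last_conn is not None and np.array_equal(conn, last_conn):
                stable += 1
                if stable >= patience:
                    converged = True
                    break
            else:
                stable = 0
            last_conn = conn
    err = _kl_divergence(V, W @ H)
    return W, H, err, it, converged


def nmf_brunet(
    V: pd.DataFrame,
    k: int,
    n_runs: int = 30,
    max_iter: int = 2000,
    seed: int = 0,
) -> NMFModel:
    """Best-of-``n_runs`` KL-divergence NMF of a non-negative matrix.

    All-zero gene rows are dropped with a warning. The KL objective is
    non-increasing within each run (multiplicative-update guarantee); the
    run achieving the lowest final KL error is returned.
    """
    values = V.to_numpy(dtype=float)
    if (values < 0).any():
        raise CohortError("nmf_brunet: input must be non-negative")
    zero_rows = values.sum(axis=1) == 0
    if zero_rows.any():
        logger.warning("nmf_brunet: dropping %d all-zero gene rows", int(zero_rows.sum()))
        V = V.loc[~zero_rows]
        values = V.to_numpy(dtype=float)
    g, s = values.shape
    if k >= min(g, s):
        raise CohortError(f"k={k} must be < min(genes, samples) = {min(g, s)}")

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    best = None
    for run_seed in run_seeds:
        W, H, err, n_iter, converged = _nmf_single_run(values, k, max_iter, int(run_seed))
        if best is None or err < best[2]:
            best = (W, H, err, n_iter, converged, int(run_seed))
    W, H, err, n_iter, converged, run_seed = best
    factors = [f"F{j + 1}" for j in range(k)]
    return NMFModel(
        W=pd.DataFrame(W, index=V.index, columns=factors),
        H=pd.DataFrame(H, index=factors, columns=V.columns),
        k=k,
        approximation_error=err,
        run_seed=run_seed,
        n_iter=n_iter,
        converged=converged,
    )


def cophenetic_select_k(
    V: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    runs_per_k: int = 10,
    max_iter: int = 2000,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Select the NMF rank maximizing the cophenetic correlation.

    Per candidate k, the consensus matrix of sample co-clustering (argmax
    factor of H) is averaged over ``runs_per_k`` runs; the cophenetic
    coefficient correlates the cophenetic distances of an average-linkage
    tree of ``1 - consensus`` with ``1 - consensus`` itself. A degenerate
    all-identical consensus yields coefficient 1 (flagged via warning).
    Ties break toward smaller k.
    """
    if runs_per_k < 2:
        raise CohortError("cophenetic_select_k: need at least 2 runs per k")
    values = V.to_numpy(dtype=float)
    s = values.shape[1]
    rng = np.random.default_rng(seed)
    coeffs = {}
    for k in sorted(k_range):
        consensus = np.zeros((s, s))
        for _ in range(runs_per_k):
            _, H, _, _, _ = _nmf_single_run(values, k, max_iter, int(rng.integers(2**31)))
            conn = H.argmax(axis=0)
            consensus += conn[:, None] == conn[None, :]
        consensus /= runs_per_k
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
            logger.warning("cophenetic_select_k: degenerate consensus at k=%d", k)
            coeffs[k] = 1.0
            continue
        tree = hierarchy.linkage(condensed, method="average")
        coph = hierarchy.cophenet(tree)
        coeffs[k] = float(pearsonr(condensed, coph)[0])
    series = pd.Series(coeffs, name="cophenetic")
    best = max(sorted(coeffs), key=lambda k: (coeffs[k], -k))
    return best, series


def gene_entropy_scores(W: pd.DataFrame) -> pd.Series:
    """Factor-specificity score per gene in [0, 1].

    With p_f = w_f / sum_f w_f over a gene's factor weights, the score is
    ``1 + (1/log2 k) * sum_f p_f log2 p_f``: 1 for a gene loading on a
    single factor (zero entropy), 0 for a uniform gene (maximal entropy).
    All-zero rows are excluded (score undefined).
    """
    values = W.to_numpy(dtype=float)
    if (values < 0).any():
        raise CohortError("gene_entropy_scores: W must be non-negative")
    k = values.shape[1]
    if k < 2:
        raise CohortError("gene_entropy_scores: need at least 2 factors")
    totals = values.sum(axis=1)
    keep = totals > 0
    p = values[keep] / totals[keep][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    scores = 1.0 + plogp.sum(axis=1) / np.log2(k)
    return pd.Series(np.clip(scores, 0.0, 1.0), index=W.index[keep], name="entropy_score")


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation: median |x - median x|."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def exemplar_genes(W: pd.DataFrame) -> dict[str, list[str]]:
    """Entropy-and-contribution exemplar extraction.

    A gene is an exemplar iff its specificity score exceeds
    ``median(scores) + 3 * MAD(scores)`` (MAD unscaled) and the maximum of
    its W row exceeds the median of all W entries; each exemplar is
    assigned to its argmax factor. An empty selection is legitimate.
    """
    scores = gene_entropy_scores(W)
    values = W.loc[scores.index].to_numpy(dtype=float)
    score_arr = scores.to_numpy()
    threshold = np.median(score_arr) + 3.0 * _mad(score_arr)
    w_median = float(np.median(W.to_numpy()))
    selected = (score_arr > threshold) & (values.max(axis=1) > w_median)
    out: dict[str, list[str]] = {f: [] for f in W.columns}
    argmax = values.argmax(axis=1)
    for gene, sel, am in zip(scores.index, selected, argmax):
        if sel:
            out[W.columns[am]].append(gene)
    return out


@dataclass
class FactorAnnotation:
    compartments: pd.Series  # factor -> compartment label
    composites: pd.DataFrame  # samples x {F-Tumor, F-Normal}
    conflicts: list[str] = field(default_factory=list)


#: pathway-theme keywords supporting each compartment attribution
_COMPARTMENT_THEMES = {
    "TIL": ("immune", "lymphocyte", "cytolytic", "inflammatory", "interferon"),
    "stromal": ("stroma", "emt", "ecm", "matrix", "tgf"),
    "normal": ("normal", "tissue", "vessel", "epithelial"),
    "tumor-intrinsic": ("cell_cycle", "proliferation", "e2f", "myc", "tumor"),
}


def attribute_factors(
    model: NMFModel,
    cohort_labels: pd.Series,
    exemplar_enrichments: dict[str, list[str]] | None = None,
    group_compartments: dict[str, str] | None = None,
) -> FactorAnnotation:
    """Attribute NMF factors to tissue compartments.

    ``cohort_labels`` maps sample -> group label (e.g. ``tumor``,
    ``immune-infiltrate``, ``stroma``, ``normal``); ``group_compartments``
    maps those labels to compartments (defaults to identity-style
    matching). A factor is attributed to the compartment of the group
    where its mean sample weight is highest, provided its exemplar
    enrichments (pathway names, optional) do not support a different
    compartment; conflicts are left unassigned and reported.
    """
    group_compartments = group_compartments or {
        "tumor": "tumor-intrinsic",
        "immune-infiltrate": "TIL",
        "immune": "TIL",
        "stroma": "stromal",
        "stromal": "stromal",
        "normal": "normal",
    }
    shared = model.H.columns.intersection(cohort_labels.index)
    if len(shared) == 0:
        raise CohortError("attribute_factors: no labeled samples in the model")
    labels = cohort_labels.loc[shared]
    H = model.H.loc[:, shared]

    compartments = {}
    conflicts = []
    for factor in model.H.index:
        means = H.loc[factor].groupby(labels).mean()
        if means.empty or np.isclose(means.max(), means.min()):
            compartments[factor] = "unassigned"
            continue
        top_group = means.idxmax()
        weight_call = group_compartments.get(str(top_group))
        if weight_call is None:
            compartments[factor] = "unassigned"
            continue
        if exemplar_enrichments is not None:
            pathways = [p.lower() for p in exemplar_enrichments.get(factor, [])]
            theme_calls = {
                comp
                for comp, keys in _COMPARTMENT_THEMES.items()
                if any(key in p for p in pathways for key in keys)
            }
            if theme_calls and weight_call not in theme_calls:
                conflicts.append(factor)
                compartments[factor] = "unassigned"
                continue
        compartments[factor] = weight_call

    comp = pd.Series(compartments, name="compartment")
    tumor_factors = comp.index[comp == "tumor-intrinsic"]
    normal_factors = comp.index[comp == "normal"]
    composites = pd.DataFrame(
        {
            "F-Tumor": model.H.loc[tumor_factors].sum(axis=0)
            if len(tumor_factors)
            else pd.Series(0.0, index=model.H.columns),
            "F-Normal": model.H.loc[normal_factors].sum(axis=0)
            if len(normal_factors)
            else pd.Series(0.0, index=model.H.columns),
        }
    )
    return FactorAnnotation(compartments=comp, composites=composites, conflicts=conflicts)
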