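"""Immune-state classification and transition bookkeeping.

Samples are classified into cold (C), warm (W) and hot (H) tumor-immune
microenvironment states by integrative clustering of multiple feature
blocks (immune signature scores and immune cell fractions). The model is
the Gaussian latent-variable formulation of integrative clustering: all
standardized blocks are stacked and explained by k-1 shared latent
factors, fit by expectation-maximization with a lasso-type soft-threshold
shrinking the loadings; cluster assignments come from k-means on the
posterior latent means. The cluster count is selected by the Bayesian
information criterion, and the three clusters are ordered into C/W/H by a
per-sample immune intensity summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

from .io import CohortError, percent_of

__all__ = [
    "ImmuneStateModel",
    "integrative_cluster",
    "select_k_bic",
    "label_states",
    "transition_table",
    "transition_percentages",
    "state_feature_anova",
]


@dataclass
class ImmuneStateModel:
    k: int
    loadings: list[pd.DataFrame]  # one features x (k-1) matrix per block
    latent: pd.DataFrame  # samples x (k-1) posterior means
    assignments: pd.Series  # sample -> cluster index 0..k-1
    bic: float
    log_likelihood: float
    n_params: int
    degenerate: bool  # all loadings shrunk to zero


def _stack_blocks(blocks: list[pd.DataFrame]) -> tuple[np.ndarray, pd.Index, list[int]]:
    if not blocks:
        raise CohortError("integrative_cluster: no blocks given")
    index = blocks[0].index
    for b in blocks[1:]:
        if not b.index.equals(index):
            raise CohortError("blocks must share identical sample ids")
    sizes = [b.shape[1] for b in blocks]
    X = np.hstack([b.to_numpy(dtype=float) for b in blocks])
    # standardize features; flat features carry no signal
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    return (X - mean) / sd, index, sizes


def integrative_cluster(
    blocks: list[pd.DataFrame],
    k: int = 3,
    penalty: float = 0.2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 17,
) -> ImmuneStateModel:
    """Fit the shared latent-variable model and cluster samples.

    ``blocks`` are samples x features frames with identical sample ids.
    ``penalty`` is the soft-threshold applied to the loading matrix after
    each M-step (0 disables shrinkage). Deterministic given ``seed``
    (EM is initialized from the leading principal components).
    """
    X, index, sizes = _stack_blocks(blocks)
    n, p = X.shape
    if k < 2:
        raise CohortError("k must be >= 2")
    if k > n:
        raise CohortError("k exceeds the number of samples")
    q = k - 1  # latent dimensions

    # deterministic init from leading principal components
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    W = (vt[:q].T * s[:q]) / np.sqrt(n)  # p x q
    psi = np.full(p, 1.0)

    ll_old = -np.inf
    ll = ll_old
    for _ in range(max_iter):
        # E-step: posterior of z given x (factor-analysis identities)
        WtPi = (W / psi[:, None]).T  # q x p
        M = np.eye(q) + WtPi @ W
        Minv = np.linalg.inv(M)
        Ez = X @ WtPi.T @ Minv  # n x q
        Ezz = n * Minv + Ez.T @ Ez  # q x q

        # M-step with lasso-type soft-threshold on the loadings
        W_new = (X.T @ Ez) @ np.linalg.inv(Ezz)
        W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - penalty, 0.0)
        psi_new = np.maximum(
            (X * X).sum(axis=0) / n - ((W_new @ (Ez.T @ X)).diagonal()) / n, 1e-6
        )
        W, psi = W_new, psi_new

        # marginal log-likelihood of N(0, W W' + diag(psi))
        C = W @ W.T + np.diag(psi)
        sign, logdet = np.linalg.slogdet(C)
        Cinv = np.linalg.inv(C)
        S = (X.T @ X) / n
        ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + np.trace(Cinv @ S))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll

    degenerate = not np.any(W != 0.0)
    if degenerate:
        latent = np.zeros((n, q))
        assignments = np.zeros(n, dtype=int)
    else:
        WtPi = (W / psi[:, None]).T
        M = np.eye(q) + WtPi @ W
        latent = X @ WtPi.T @ np.linalg.inv(M)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assignments = km.fit_predict(latent)

    n_params = int(np.count_nonzero(W)) + p
    bic = -2.0 * ll + n_params * np.log(n)

    loadings = []
    offset = 0
    for b, size in zip(blocks, sizes):
        loadings.append(
            pd.DataFrame(W[offset : offset + size], index=b.columns,
                         columns=[f"LV{j + 1}" for j in range(q)])
        )
        offset += size
    return ImmuneStateModel(
        k=k,
        loadings=loadings,
        latent=pd.DataFrame(latent, index=index,
                            columns=[f"LV{j + 1}" for j in range(q)]),
        assignments=pd.Series(assignments, index=index, name="cluster"),
        bic=float(bic),
        log_likelihood=float(ll),
        n_params=n_params,
        degenerate=degenerate,
    )


def select_k_bic(
    blocks: list[pd.DataFrame],
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    penalty: float = 0.2,
    seed: int = 17,
) -> tuple[int, pd.Series]:
    """Choose the cluster count minimizing BIC = -2 loglik + params log n.

    Ties break toward smaller k. Returns (k*, BIC per k).
    """
    ks = sorted(k_range)
    if not ks:
        raise CohortError("select_k_bic: empty k range")
    n = len(blocks[0]) if blocks else 0
    bics = {}
    for k in ks:
        if not 2 <= k <= max(n - 1, 2):
            raise CohortError(f"k={k} outside [2, n-1]")
        bics[k] = integrative_cluster(blocks, k=k, penalty=penalty, seed=seed).bic
    series = pd.Series(bics, name="bic")
    # ties (including floating-point noise when extra latent dimensions
    # are fully shrunk away) break toward smaller k
    min_bic = min(bics.values())
    tol = 1e-8 * max(abs(min_bic), 1.0)
    best = min(k for k in ks if bics[k] <= min_bic + tol)
    return best, series


def label_states(model: ImmuneStateModel, immune_score: pd.Series) -> pd.Series:
    """Order the three clusters by mean immune intensity into C < W < H."""
    if model.k != 3:
        raise CohortError("label_states requires a k=3 model")
    if model.assignments.nunique() < 3:
        raise CohortError("label_states: model collapsed to fewer than 3 "
                          "clusters (lower the penalty or check the features)")
    score = immune_score.loc[model.assignments.index]
    means = score.groupby(model.assignments).mean()
    if means.round(12).duplicated().any():
        raise CohortError("label_states: exactly tied cluster means; "
                          "re-fit with a different seed to break the tie")
    order = means.sort_values().index.tolist()  # low -> high intensity
    name_map = {order[0]: "C", order[1]: "W", order[2]: "H"}
    return model.assignments.map(name_map).rename("state")


def transition_table(assignments: pd.Series, pairs: pd.DataFrame) -> pd.DataFrame:
    """Counts of immune-state transitions across a paired-sample map.

    ``assignments`` maps sample_id -> state; ``pairs`` has columns
    ``sample_a, sample_b`` (from build_pairs). Pairs with a missing state
    are skipped with a warning. Rows cover every observed from-state with
    margins equal to row sums by construction.
    """
    states = ("C", "W", "H")
    counts = {(a, b): 0 for a in states for b in states}
    skipped = 0
    for _, row in pairs.iterrows():
        sa, sb = row["sample_a"], row["sample_b"]
        if sa not in assignments.index or sb not in assignments.index:
            skipped += 1
            continue
        counts[(assignments[sa], assignments[sb])] += 1
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "transition_table: %d pairs skipped (missing state)", skipped
        )
    rows = [
        {"from_state": a, "to_state": b, "count": counts[(a, b)]}
        for a in states
        for b in states
    ]
    table = pd.DataFrame(rows)
    margins = table.groupby("from_state")["count"].sum()
    table["from_margin"] = table["from_state"].map(margins)
    return table


def transition_percentages(table: pd.DataFrame, decimals: int = 0) -> pd.DataFrame:
    """Per-edge percentage of each from-state margin (printed-number style)."""
    out = table.copy()
    out["percent"] = [
        percent_of(int(c), int(m), decimals) if m > 0 else np.nan
        for c, m in zip(out["count"], out["from_margin"])
    ]
    return out


def state_feature_anova(
    feature: pd.Series,
    states: pd.Series,
    purity: pd.Series,
    subtype: pd.Series,
) -> float:
    """F-test p-value for the state term in a linear model adjusting for
    tumor purity and subtype.

    Fits ``feature ~ purity + subtype + state`` by OLS and compares it to
    the purity + subtype model with a partial F-test.
    """
    shared = feature.index
    for s in (states, purity, subtype):
        shared = shared.intersection(s.index)
    if states.loc[shared].nunique() < 2:
        raise CohortError("state_feature_anova: need >= 2 states present")
    y = feature.loc[shared].to_numpy(dtype=float)

    def design(with_state: bool) -> np.ndarray:
        cols = [np.ones(len(shared)), purity.loc[shared].to_numpy(dtype=float)]
        for level in sorted(subtype.loc[shared].unique())[1:]:
            cols.append((subtype.loc[shared] == level).to_numpy(dtype=float))
        if with_state:
            for level in sorted(states.loc[shared].unique())[1:]:
                cols.append((states.loc[shared] == level).to_numpy(dtype=float))
        return np.column_stack(cols)

    X_full, X_red = design(True), design(False)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise CohortError("state_feature_anova: state term aliased with covariates")
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_red).fit()
    ftest = full.compare_f_test(reduced)
    return float(ftest[1])
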