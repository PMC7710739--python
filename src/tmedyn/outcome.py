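"""Association of immune features with pathologic response.

Single-feature associations are covariate-adjusted regressions: logistic
(iteratively reweighted least squares, Wald p-values) when the outcome is
binary, ordinary linear regression otherwise, with the fixed clinical
covariate panel always included. Feature panels are ranked by elastic-net
bootstrap usage: per bootstrap resample of patients a cross-validated
elastic-net logistic path is fit and the features with non-zero
coefficients at the deviance-optimal penalty counted; usage is the
selection frequency over iterations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import CohortError

logger = logging.getLogger(__name__)

__all__ = [
    "adjusted_association",
    "elasticnet_bootstrap",
    "compare_usage_groups",
]


def adjusted_association(
    panel: pd.DataFrame,
    feature: str,
    outcome: str,
    covariates: list[str] | None = None,
) -> tuple[float, float]:
    """Coefficient and Wald p for ``feature`` adjusting for ``covariates``.

    ``panel`` has one row per patient. A binary outcome (2 unique values)
    is fit by logistic regression, a continuous one by OLS. Perfect
    separation in the logistic fit falls back to a ridge-penalized refit
    with a logged flag.
    """
    covariates = covariates or []
    for col in [feature, outcome, *covariates]:
        if col not in panel.columns:
            raise CohortError(f"adjusted_association: column {col!r} missing")
    X = panel[[feature, *covariates]].astype(float)
    X = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CohortError("adjusted_association: aliased covariates")
    y_raw = panel[outcome]
    binary = y_raw.nunique() == 2
    if binary:
        levels = sorted(y_raw.unique())
        y = (y_raw == levels[1]).astype(float)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.isfinite(fit.bse[feature]) or fit.bse[feature] > 1e4:
                raise np.linalg.LinAlgError("separation")
            return float(fit.params[feature]), float(fit.pvalues[feature])
        except Exception:
            logger.warning("perfect separation for %s; penalized refit", feature)
            ridge = LogisticRegression(penalty="l2", C=10.0, max_iter=2000)
            cols = list(X.columns)[1:]
            ridge.fit(panel[cols].astype(float), y)
            coef = float(ridge.coef_[0][cols.index(feature)])
            return coef, np.nan
    fit = sm.OLS(panel[outcome].astype(float), X).fit()
    return float(fit.params[feature]), float(fit.pvalues[feature])


def _cv_elasticnet_select(
    X: np.ndarray, y: np.ndarray, alpha: float, cs: np.ndarray,
    n_folds: int, seed: int, origin: np.ndarray | None = None,
) -> np.ndarray:
    """Non-zero coefficients at the cross-validated-deviance penalty.

    ``origin`` carries the source-patient index of each (possibly
    duplicated) bootstrap row; folds are split on unique patients so a
    resampled patient never sits in both train and test, which would leak
    and bias the penalty weak.
    """
    if origin is None:
        origin = np.arange(len(y))
    uniq = np.unique(origin)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    fold_of_unique = {u: i % n_folds for i, u in enumerate(perm)}
    fold_id = np.array([fold_of_unique[o] for o in origin])

    splits = []
    for f in range(n_folds):
        train = np.nonzero(fold_id != f)[0]
        test = np.nonzero(fold_id == f)[0]
        if len(test) == 0 or len(np.unique(y[train])) < 2:
            continue
        splits.append((train, test))
    if not splits:  # degenerate fold layout: fall back to row-level CV
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))

    fold_dev = np.full((len(splits), len(cs)), np.nan)
    for fi, (train, test) in enumerate(splits):
        for ci, c in enumerate(cs):
            model = LogisticRegression(
                penalty="elasticnet", solver="saga", l1_ratio=alpha, C=c,
                max_iter=500, tol=1e-3, random_state=0,
            )
            model.fit(X[train], y[train])
            p = np.clip(model.predict_proba(X[test])[:, 1], 1e-12, 1 - 1e-12)
            fold_dev[fi, ci] = -2.0 * np.mean(
                y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)
            )
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(len(splits))
    ci_min = int(np.argmin(mean_dev))
    # one-standard-error rule: strongest penalty (smallest C) whose CV
    # deviance is within 1 SE of the minimum
    eligible = np.nonzero(mean_dev <= mean_dev[ci_min] + se_dev[ci_min])[0]
    best_c = cs[int(eligible[0])]
    final = LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=alpha, C=best_c,
        max_iter=1000, tol=1e-4, random_state=0,
    )
    final.fit(X, y)
    return final.coef_[0]


def elasticnet_bootstrap(
    panel: pd.DataFrame,
    features: list[str],
    outcome: str,
    n_boot: int = 10000,
    alpha: float = 0.5,
    n_folds: int = 5,
    n_cs: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature usage over bootstrap elastic-net logistic fits.

    Per iteration, patients are resampled with replacement (redrawn if the
    outcome becomes constant), features standardized on the resample, and
    an elastic-net logistic path fit with the penalty chosen by
    ``n_folds``-fold cross-validated deviance; every variable receives the
    same penalty factor. Usage = percent of iterations with a non-zero
    coefficient; rank is by descending usage with ties broken by mean
    absolute coefficient, then by name. Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise CohortError("elasticnet_bootstrap: n_boot must be >= 100")
    missing = [f for f in features if f not in panel.columns]
    if missing:
        raise CohortError(f"elasticnet_bootstrap: missing features {missing}")
    rng = np.random.default_rng(seed)
    y_raw = panel[outcome]
    if y_raw.nunique() != 2:
        raise CohortError("elasticnet_bootstrap: outcome must be binary")
    levels = sorted(y_raw.unique())
    y_all = (y_raw == levels[1]).to_numpy(dtype=float)
    X_all = panel[features].to_numpy(dtype=float)
    n = len(y_all)

    cs = np.logspace(-2.5, 1.0, n_cs)
    selected = np.zeros(len(features))
    coef_sums = np.zeros(len(features))
    for _ in range(n_boot):
        for _redraw in range(100):
            take = rng.integers(0, n, size=n)
            y = y_all[take]
            if 0 < y.sum() < n:
                break
        else:  # pragma: no cover - pathological outcome balance
            raise CohortError("could not draw a non-degenerate bootstrap sample")
        X = X_all[take]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd <= 0] = 1.0
        X = (X - mu) / sd
        coefs = _cv_elasticnet_select(
            X, y, alpha, cs, n_folds, seed=int(rng.integers(2**31)), origin=take
        )
        nz = np.abs(coefs) > 1e-8
        selected += nz
        coef_sums += np.abs(coefs)

    usage = 100.0 * selected / n_boot
    mean_coef = coef_sums / n_boot
    table = pd.DataFrame(
        {"feature": features, "usage_pct": usage, "mean_abs_coef": mean_coef}
    )
    table = table.sort_values(
        by=["usage_pct", "mean_abs_coef", "feature"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["n_boot"] = n_boot
    logger.info("elastic-net bootstrap: %d iterations", n_boot)
    return table.set_index("feature")


def compare_usage_groups(
    usage: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing usage between two feature
    groups (e.g. baseline vs on-treatment features)."""
    if not group_a or not group_b:
        raise CohortError("compare_usage_groups: both groups must be non-empty")
    a = usage.loc[group_a, "usage_pct"].to_numpy(dtype=float)
    b = usage.loc[group_b, "usage_pct"].to_numpy(dtype=float)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and
                         len(set(np.concatenate([a, b]))) == len(a) + len(b)) else "auto"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
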