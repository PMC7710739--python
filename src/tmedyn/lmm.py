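"""Random-intercept linear mixed models via profiled likelihood.

The model for one feature (gene, signature score or image-derived value) is

    y_i = x_i' beta + b_{d(i)} + eps_i,
    b_d ~ N(0, sigma_b^2),  eps_i ~ N(0, sigma_e^2),

with patients as the grouping factor d. For a single random intercept the
(restricted) log-likelihood can be profiled down to a one-dimensional
function of the variance ratio theta = sigma_b^2 / sigma_e^2: at each
candidate theta the fixed effects are the closed-form GLS solution and
sigma_e^2 has a closed form as well. The outer optimization is a bounded
scalar search with an explicit check of the theta = 0 boundary (where the
model collapses to OLS).

Because the marginal covariance is block diagonal (one block per patient)
with blocks I + theta * J, all per-theta quantities reduce to group sums,
so a fit costs O(n * p^2) per likelihood evaluation and thousands of
genes can be fit in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CohortError

__all__ = ["LMMFit", "fit_lmm", "lrt_time", "build_design"]


@dataclass
class LMMFit:
    """Result of a single random-intercept mixed-model fit."""

    fixed_effects: pd.Series  # named coefficients
    fixed_se: pd.Series
    random_intercept_variance: float  # sigma_b^2
    residual_variance: float  # sigma_e^2
    log_likelihood: float  # at the chosen criterion (ML or REML)
    ml_log_likelihood: float  # always the ML value, for LRTs
    n_obs: int
    n_groups: int
    criterion: str
    converged: bool

    @property
    def t_statistics(self) -> pd.Series:
        return self.fixed_effects / self.fixed_se


class _Profiler:
    """Precomputed group-wise sufficient statistics for one design."""

    def __init__(self, y: np.ndarray, X: np.ndarray, group_codes: np.ndarray):
        self.n, self.p = X.shape
        order = np.argsort(group_codes, kind="stable")
        Xs, ys, gs = X[order], y[order], group_codes[order]
        _, starts, counts = np.unique(gs, return_index=True, return_counts=True)
        self.counts = counts.astype(float)
        self.G = len(counts)
        self.XtX = Xs.T @ Xs
        self.Xty = Xs.T @ ys
        self.yty = float(ys @ ys)
        # per-group sums of rows of X and of y
        self.Sx = np.add.reduceat(Xs, starts, axis=0)  # G x p
        self.Sy = np.add.reduceat(ys, starts)  # G

    def gls(self, theta: float):
        """GLS pieces at variance ratio theta (with unit residual variance)."""
        w = theta / (1.0 + theta * self.counts)  # per-group shrinkage weight
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        c = self.Xty - self.Sx.T @ (w * self.Sy)
        yVy = self.yty - float(w @ (self.Sy ** 2))
        beta = np.linalg.solve(A, c)
        rss = yVy - float(c @ beta)  # r' V0^-1 r at the GLS solution
        logdet_v0 = float(np.log1p(theta * self.counts).sum())
        return beta, A, rss, logdet_v0

    def neg_loglik(self, theta: float, reml: bool) -> float:
        beta, A, rss, logdet_v0 = self.gls(theta)
        rss = max(rss, 1e-300)
        if reml:
            df = self.n - self.p
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            ll = -0.5 * (df * np.log(2 * np.pi * rss / df) + logdet_v0 + logdet_a + df)
        else:
            ll = -0.5 * (self.n * np.log(2 * np.pi * rss / self.n) + logdet_v0 + self.n)
        return -ll


def build_design(
    clinical: pd.DataFrame,
    *,
    include_purity: bool = True,
    include_subtype: bool = True,
    time_levels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Fixed-effect design from a clinical table.

    Intercept + purity + subtype dummies (reference ER+/HER2-) + time
    dummies (reference = first level of ``time_levels``, default T1).
    Dummy columns for absent levels are dropped.
    """
    cols = {"Intercept": np.ones(len(clinical))}
    if include_purity:
        cols["purity"] = clinical["purity"].to_numpy(float)
    if include_subtype:
        present = [s for s in sorted(set(clinical["subtype"]))]
        for s in present[1:]:
            cols[f"subtype[{s}]"] = (clinical["subtype"] == s).to_numpy(float)
    levels = time_levels or tuple(sorted(set(clinical["time"])))
    for t in levels[1:]:
        if (clinical["time"] == t).any():
            cols[f"time[{t}]"] = (clinical["time"] == t).to_numpy(float)
    return pd.DataFrame(cols, index=clinical.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify aliased columns by QR pivoting on the Gram matrix
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        raise CohortError(f"design is rank deficient; aliased columns: {aliased}")


def fit_lmm(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    criterion: str = "REML",
) -> LMMFit:
    """Fit the single-random-intercept model by profiled (RE)ML.

    Parameters
    ----------
    y : observation vector.
    design : fixed-effect design matrix (columns named; include intercept).
    groups : patient id per observation.
    criterion : ``"ML"`` or ``"REML"``. The ML log-likelihood is always
        reported alongside so nested fits can be compared by LRT.
    """
    criterion = criterion.upper()
    if criterion not in ("ML", "REML"):
        raise CohortError("criterion must be ML or REML")
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise CohortError("y and design have different lengths")
    codes, _ = pd.factorize(np.asarray(groups))
    if len(np.unique(codes)) < 2:
        raise CohortError("need at least 2 groups (patients)")
    _check_full_rank(design)

    prof = _Profiler(y, X, codes)
    reml = criterion == "REML"

    # optimize over log-theta on a generous bracket, then compare with the
    # theta = 0 boundary (variance component pinned at zero -> OLS)
    def obj(log_theta: float) -> float:
        return prof.neg_loglik(np.exp(log_theta), reml)

    converged = True
    try:
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                       options={"xatol": 1e-7})
        theta_hat = float(np.exp(res.x))
        nll_hat = float(res.fun)
        if not res.success:
            converged = False
    except Exception:
        theta_hat, nll_hat, converged = 0.0, np.inf, False

    nll0 = prof.neg_loglik(0.0, reml)
    if nll0 <= nll_hat + 1e-10:
        theta_hat = 0.0

    beta, A, rss, _ = prof.gls(theta_hat)
    df = prof.n - prof.p if reml else prof.n
    sigma_e2 = max(rss / df, 1e-300)
    sigma_b2 = theta_hat * sigma_e2
    cov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))

    ll = -prof.neg_loglik(theta_hat, reml)
    if reml:
        # report ML value at the REML variance-ratio estimate; exact ML fits
        # use criterion="ML" (run_de does, for its LRTs)
        ml_ll = -prof.neg_loglik(theta_hat, False)
    else:
        ml_ll = ll

    return LMMFit(
        fixed_effects=pd.Series(beta, index=design.columns),
        fixed_se=pd.Series(se, index=design.columns),
        random_intercept_variance=float(sigma_b2),
        residual_variance=float(sigma_e2),
        log_likelihood=float(ll),
        ml_log_likelihood=float(ml_ll),
        n_obs=prof.n,
        n_groups=prof.G,
        criterion=criterion,
        converged=converged,
    )


def lrt_time(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-squared test of nested fixed-effect structures.

    Both fits must be ML fits on identical observations; the statistic is
    ``2 * (ll_full - ll_reduced)`` floored at 0 with df = difference in
    fixed-effect count.
    """
    if full.n_obs != reduced.n_obs or full.n_groups != reduced.n_groups:
        raise CohortError("lrt_time: fits are not on identical observations")
    if full.criterion != "ML" or reduced.criterion != "ML":
        raise CohortError("lrt_time: both fits must use ML")
    extra = set(reduced.fixed_effects.index) - set(full.fixed_effects.index)
    if extra:
        raise CohortError(f"lrt_time: reduced model not nested in full ({sorted(extra)})")
    df = len(full.fixed_effects) - len(reduced.fixed_effects)
    chisq = max(0.0, 2.0 * (full.ml_log_likelihood - reduced.ml_log_likelihood))
    if df == 0:
        # identical designs: a degenerate comparison, chisq 0 by nesting
        return 0.0, 0, 1.0
    p = float(stats.chi2.sf(chisq, df)) if chisq > 0 else 1.0
    return chisq, df, p
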