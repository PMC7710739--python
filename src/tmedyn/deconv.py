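"""nu-SVR deconvolution of bulk expression into immune cell fractions.

Each bulk sample is regressed on a genes x cell-types reference signature
matrix with a linear-kernel nu-support-vector regression, after jointly
z-scoring the shared-gene mixture and signature columns. The nu
hyperparameter is chosen per sample from a small grid by the root mean
square error between fitted and observed mixture values; negative
coefficients are zeroed and the remainder normalized to relative
fractions summing to one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .io import CohortError

logger = logging.getLogger(__name__)

__all__ = [
    "nusvr_deconvolve",
    "aggregate_cell_types",
    "correlate_fractions_vs_score",
]

DEFAULT_NUS = (0.25, 0.5, 0.75)


def _validate_signature(signature: pd.DataFrame) -> None:
    if signature.shape[1] < 2:
        raise CohortError("signature must contain at least 2 cell types")
    if (signature.to_numpy() < 0).any():
        raise CohortError("signature matrix must be non-negative")
    if (signature.to_numpy().sum(axis=0) == 0).any():
        raise CohortError("signature matrix has an all-zero cell-type column")


def nusvr_deconvolve(
    mixture: pd.DataFrame,
    signature: pd.DataFrame,
    nus: tuple[float, ...] = DEFAULT_NUS,
) -> pd.DataFrame:
    """Estimate relative cell-type fractions per bulk sample.

    Returns samples x cell-types with rows summing to 1, plus ``rmse`` and
    ``nu`` columns recording the per-sample model fit. Deconvolution runs
    on the linear (TPM) scale restricted to genes shared between mixture
    and signature; at least half of the signature genes must be present.
    """
    _validate_signature(signature)
    shared = signature.index.intersection(mixture.index)
    if len(shared) == 0:
        raise CohortError("no shared genes between mixture and signature")
    if len(shared) < signature.shape[0] / 2:
        raise CohortError(
            f"only {len(shared)}/{signature.shape[0]} signature genes in mixture"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    M = mixture.loc[shared].to_numpy(dtype=float)

    # joint z-scoring: a single location/scale across signature and each
    # mixture column absorbs library-size and platform scale
    def zcol(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    Sz = np.column_stack([zcol(S[:, j]) for j in range(S.shape[1])])

    rows = []
    for si, sample in enumerate(mixture.columns):
        y = zcol(M[:, si])
        best = None
        for nu in nus:
            model = NuSVR(kernel="linear", nu=nu, C=1.0)
            model.fit(Sz, y)
            rmse = float(np.sqrt(np.mean((model.predict(Sz) - y) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, nu, model.coef_.ravel().copy())
        rmse, nu, coef = best
        coef = np.clip(coef, 0.0, None)
        total = coef.sum()
        if total <= 0:
            logger.warning("sample %s: all nu-SVR coefficients <= 0; uniform fractions",
                           sample)
            coef = np.full_like(coef, 1.0)
            total = coef.sum()
        rows.append(np.concatenate([coef / total, [rmse, nu]]))

    out = pd.DataFrame(
        rows, index=mixture.columns, columns=[*signature.columns, "rmse", "nu"]
    )
    out.index.name = "sample_id"
    return out


def fraction_columns(fractions: pd.DataFrame) -> list[str]:
    """Cell-type columns of a deconvolution result (drops fit metadata)."""
    return [c for c in fractions.columns if c not in ("rmse", "nu")]


def aggregate_cell_types(fractions: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Sum fine-grained cell-type fractions into coarser groups.

    ``mapping`` must cover every cell-type column; row sums are preserved
    exactly; fit metadata columns (rmse, nu) are carried through.
    """
    types = fraction_columns(fractions)
    unmapped = [t for t in types if t not in mapping]
    if unmapped:
        raise CohortError(f"aggregate_cell_types: unmapped types {unmapped}")
    grouped: dict[str, list[str]] = {}
    for src in types:
        grouped.setdefault(mapping[src], []).append(src)
    out = pd.DataFrame(
        {dst: fractions[srcs].sum(axis=1) for dst, srcs in grouped.items()},
        index=fractions.index,
    )
    for meta in ("rmse", "nu"):
        if meta in fractions.columns:
            out[meta] = fractions[meta]
    return out


def correlate_fractions_vs_score(
    fractions: pd.DataFrame, score: pd.Series, method: str = "spearman"
) -> pd.DataFrame:
    """Rank correlation of each cell-type fraction against a per-sample
    score (e.g. cytolytic activity). Returns per type (rho, p); constant
    columns are reported as NaN."""
    if method != "spearman":
        raise CohortError("only Spearman correlation is supported")
    shared = fractions.index.intersection(score.index)
    if len(shared) < 5:
        raise CohortError("need at least 5 shared samples")
    rows = []
    s = score.loc[shared].to_numpy(dtype=float)
    for cell_type in fraction_columns(fractions):
        x = fractions.loc[shared, cell_type].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            logger.warning("cell type %s: constant fractions, rho undefined", cell_type)
            rows.append({"cell_type": cell_type, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(x, s)
        rows.append({"cell_type": cell_type, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("cell_type")
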