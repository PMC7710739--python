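"""Longitudinal differential expression over treatment time.

For each pairwise time comparison (T1 vs T2, T2 vs T3, T1 vs T3) and each
sample group (the overall cohort and, optionally, each subtype with enough
patients), every feature is fit with the random-intercept mixed model and
the time term is tested by a likelihood-ratio chi-squared test (ML fits).
Tumor purity is always a covariate; subtype is a covariate only in the
overall group. FDR is Benjamini-Hochberg within each comparison x group.

Also houses selection of differentially expressed genes, k-means consensus
clustering of their temporal profiles, and the enrichment + score-DE rule
that maps pathways onto gene clusters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io import CohortError, validate_clinical
from .lmm import build_design, fit_lmm, lrt_time
from .scoring import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "run_de",
    "select_de_genes",
    "consensus_kmeans",
    "map_pathways_to_clusters",
    "DEFAULT_COMPARISONS",
]

DEFAULT_COMPARISONS = (("T1", "T2"), ("T2", "T3"), ("T1", "T3"))


def _de_one_group(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    comparison: tuple[str, str],
    group: str,
    include_subtype: bool,
) -> pd.DataFrame | None:
    time_a, time_b = comparison
    sub = clinical[clinical["time"].isin(comparison)]
    if sub["patient_id"].nunique() < 3:
        logger.warning("group %s comparison %s-%s: <3 patients, skipped",
                       group, time_a, time_b)
        return None
    # subtype covariate only meaningful with >1 level present
    use_subtype = include_subtype and sub["subtype"].nunique() > 1
    design_full = build_design(sub, include_subtype=use_subtype,
                               time_levels=(time_a, time_b))
    time_col = f"time[{time_b}]"
    if time_col not in design_full.columns:
        logger.warning("group %s comparison %s-%s: one time point absent, skipped",
                       group, time_a, time_b)
        return None
    design_reduced = design_full.drop(columns=[time_col])
    groups_vec = sub["patient_id"].to_numpy()
    values = expr.loc[:, sub["sample_id"]].to_numpy(dtype=float)

    rows = []
    for gi, gene in enumerate(expr.index):
        y = values[gi]
        full = fit_lmm(y, design_full, groups_vec, criterion="ML")
        reduced = fit_lmm(y, design_reduced, groups_vec, criterion="ML")
        chisq, _df, p = lrt_time(full, reduced)
        rows.append(
            {
                "gene": gene,
                "group": group,
                "comparison": f"{time_a}-{time_b}",
                "estimate": float(full.fixed_effects[time_col]),
                "t_statistic": float(full.t_statistics[time_col]),
                "lrt_chisq": chisq,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    return table


def run_de(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
    groups: str = "overall",
    min_patients: int = 3,
) -> pd.DataFrame:
    """Mixed-model DE over time for every feature (row) of ``expr``.

    ``expr`` must be log-transformed, with columns matching clinical
    ``sample_id``. ``groups`` is ``"overall"``, ``"per-subtype"`` or
    ``"both"``. Sign convention: the estimate is the log2 change of the
    later time point relative to the earlier one (T2 higher than T1 gives
    a positive estimate for the (T1, T2) comparison).
    """
    validate_clinical(clinical)
    if groups not in ("overall", "per-subtype", "both"):
        raise CohortError("groups must be overall, per-subtype or both")
    missing = set(clinical["sample_id"]) - set(expr.columns)
    if missing:
        raise CohortError(f"expression missing samples: {sorted(missing)[:5]}")

    tasks: list[tuple[pd.DataFrame, str, bool]] = []
    if groups in ("overall", "both"):
        tasks.append((clinical, "overall", True))
    if groups in ("per-subtype", "both"):
        for subtype, sub in clinical.groupby("subtype"):
            if sub["patient_id"].nunique() < min_patients:
                logger.warning("subtype %s: <%d patients, skipped", subtype, min_patients)
                continue
            tasks.append((sub, subtype, False))

    tables = []
    for sub_clinical, group, include_subtype in tasks:
        for comparison in comparisons:
            t = _de_one_group(expr, sub_clinical, comparison, group, include_subtype)
            if t is not None:
                tables.append(t)
    if not tables:
        raise CohortError("run_de: no comparison produced results")
    return pd.concat(tables, ignore_index=True)


def select_de_genes(
    results: pd.DataFrame, p_threshold: float = 0.01, log2fc_threshold: float = 1.0
) -> list[str]:
    """Aggregate union of genes passing p < 0.01 and |log2FC| > 1 in at
    least one comparison x group (fold-change > 2 on the linear scale)."""
    passing = results[
        (results["p_value"] < p_threshold)
        & (results["estimate"].abs() > log2fc_threshold)
    ]
    selected = passing["gene"].unique().tolist()
    return sorted(selected)


# ---------------------------------------------------------------------------
# consensus clustering of DE genes
# ---------------------------------------------------------------------------

def _temporal_profiles(expr: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Genes x time-points matrix of per-time means of z-scored expression.

    Each gene is z-scored across samples first so temporal shape, not
    amplitude, drives the clustering.
    """
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd <= 0] = 1.0
    z = (values - mean) / sd
    zf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    sample_time = clinical.set_index("sample_id")["time"]
    cols = {}
    for time in sorted(sample_time.unique()):
        samples = sample_time.index[sample_time == time]
        cols[time] = zf.loc[:, samples].mean(axis=1)
    return pd.DataFrame(cols)


def consensus_kmeans(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    k: int = 3,
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means consensus clustering of gene temporal profiles.

    Per resample, a random ``subsample_frac`` of samples is drawn, per-time
    mean z-scored profiles recomputed, and k-means (10 restarts) run on the
    genes; the consensus matrix is the co-assignment frequency. Final
    labels cut an average-linkage tree of ``1 - consensus`` into ``k``
    groups named C1..Ck (ordered by first gene occurrence).

    Returns (gene -> label, consensus matrix genes x genes).
    """
    if k > expr.shape[0]:
        raise CohortError("consensus_kmeans: k exceeds number of genes")
    rng = np.random.default_rng(seed)
    genes = expr.index
    n_genes, n_samples = expr.shape
    co = np.zeros((n_genes, n_genes))
    for _ in range(n_resamples):
        take = rng.choice(n_samples, size=max(3, int(round(subsample_frac * n_samples))),
                          replace=False)
        sub_expr = expr.iloc[:, take]
        sub_clin = clinical[clinical["sample_id"].isin(sub_expr.columns)]
        profiles = _temporal_profiles(sub_expr, sub_clin).to_numpy()
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(profiles)
        co += labels[:, None] == labels[None, :]
    consensus = co / n_resamples
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = squareform(1.0 - consensus, checks=False)
    tree = hierarchy.linkage(dist, method="average")
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    # rename clusters C1..Ck in order of first appearance
    seen: dict[int, str] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = f"C{len(seen) + 1}"
        labels.append(seen[r])
    assignment = pd.Series(labels, index=genes, name="cluster")
    consensus_df = pd.DataFrame(consensus, index=genes, columns=genes)
    return assignment, consensus_df


def map_pathways_to_clusters(
    enrichments: dict[str, pd.DataFrame],
    signature_de: pd.DataFrame,
    enrich_fdr: float = 0.20,
    de_fdr: float = 0.05,
) -> pd.Series:
    """Map pathways to DE gene clusters.

    ``enrichments`` maps cluster label -> enrichment table (index pathway,
    column ``fdr``); ``signature_de`` is a run_de result on a pathway-score
    matrix (``gene`` column holds pathway names). A pathway maps to a
    cluster iff its enrichment FDR < 0.20 there and its score is
    differentially expressed (FDR < 0.05) in at least one comparison.
    Pathways enriched in several clusters map to the smallest-FDR one.
    """
    de_ok = set(signature_de.loc[signature_de["fdr"] < de_fdr, "gene"])
    best: dict[str, tuple[float, str]] = {}
    for cluster, table in enrichments.items():
        hits = table[table["fdr"] < enrich_fdr]
        for pathway, row in hits.iterrows():
            if pathway not in de_ok:
                continue
            fdr = float(row["fdr"])
            if pathway not in best or fdr < best[pathway][0]:
                best[pathway] = (fdr, cluster)
    mapping = pd.Series({p: c for p, (_, c) in best.items()}, dtype=object, name="cluster")
    mapping.index.name = "pathway"
    return mapping
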