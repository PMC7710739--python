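"""Core data containers, readers/writers and cohort bookkeeping.

Conventions used throughout the package
---------------------------------------
* An *expression matrix* is a :class:`pandas.DataFrame` with genes as rows
  (index = gene symbols) and samples as columns, on the non-negative TPM
  scale unless a function says otherwise.
* A *clinical table* is a :class:`pandas.DataFrame` with one row per sample
  and the columns ``patient_id, sample_id, subtype, time, purity, pcr``.
  Time points form the closed vocabulary ``T1`` (pre-treatment), ``T2``
  (after the first treatment cycle) and ``T3`` (surgery); subtypes are the
  four clinical breast-cancer subtypes; ``pcr`` is ``pCR`` (pathologic
  complete response) or ``RD`` (residual disease).
* Gene-set collections are plain ``dict[str, list[str]]`` read from GMT.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINTS = ("T1", "T2", "T3")
SUBTYPES = ("ER+/HER2-", "ER+/HER2+", "HER2+/ER-", "TN")
PCR_LEVELS = ("pCR", "RD")

CLINICAL_COLUMNS = ["patient_id", "sample_id", "subtype", "time", "purity", "pcr"]


class CohortError(ValueError):
    """Raised for malformed cohort inputs (files or tables)."""


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame, *, allow_negative: bool = False) -> pd.DataFrame:
    """Check an expression matrix invariant set; return the frame unchanged."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise CohortError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise CohortError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy()
    if not np.isfinite(values).all():
        raise CohortError("expression matrix contains non-finite values")
    if not allow_negative and (values < 0).any():
        raise CohortError("negative values in a TPM-scale expression matrix")
    return expr


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table against the closed vocabularies."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise CohortError(f"clinical table missing columns: {missing}")
    bad_time = set(clinical["time"]) - set(TIMEPOINTS)
    if bad_time:
        raise CohortError(f"unknown time labels: {sorted(bad_time)}")
    bad_sub = set(clinical["subtype"]) - set(SUBTYPES)
    if bad_sub:
        raise CohortError(f"unknown subtype labels: {sorted(bad_sub)}")
    bad_pcr = set(clinical["pcr"]) - set(PCR_LEVELS)
    if bad_pcr:
        raise CohortError(f"unknown pCR labels: {sorted(bad_pcr)}")
    purity = clinical["purity"].to_numpy(dtype=float)
    if ((purity < 0) | (purity > 1)).any():
        raise CohortError("purity outside [0, 1]")
    if clinical.duplicated(subset=["patient_id", "time"]).any():
        raise CohortError("duplicate (patient, time) pairs")
    if clinical["sample_id"].duplicated().any():
        raise CohortError("duplicate sample ids in clinical table")
    return clinical


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    """Write genes x samples TSV; first column holds the gene symbol."""
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix.

    Raises
    ------
    CohortError
        On an empty file or duplicated gene ids (the offending gene is named).
    """
    try:
        expr = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"empty expression file: {path}") from exc
    if expr.shape[1] == 0:
        raise CohortError(f"expression file has no sample columns: {path}")
    expr.index = expr.index.astype(str)
    return validate_expression(expr.astype(float))


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical[CLINICAL_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_clinical(path) -> pd.DataFrame:
    try:
        clinical = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"empty clinical file: {path}") from exc
    return validate_clinical(clinical)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: ``name<TAB>description<TAB>gene...``.

    The description column is discarded; gene order is preserved; genes
    repeated within a set are deduplicated with a logged warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortError(f"GMT line {lineno}: fewer than 3 fields")
            name, _desc, *genes = fields
            if name in sets:
                raise CohortError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("GMT set %s: %d duplicate genes removed",
                               name, len(genes) - len(deduped))
            if not deduped:
                raise CohortError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = deduped
    if not sets:
        raise CohortError(f"GMT file contains no gene sets: {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# consort bookkeeping
# ---------------------------------------------------------------------------

def percent_of(numerator: int, denominator: int, decimals: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half-away-from-zero.

    This is the rounding used for every printed cohort percentage
    (e.g. 55 of 146 -> 38 at 0 decimals; 11 of 24 -> 45.8 at 1 decimal).
    """
    if denominator <= 0:
        raise CohortError("percent_of: denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise CohortError("percent_of: numerator outside [0, denominator]")
    if decimals not in (0, 1):
        raise CohortError("percent_of: decimals must be 0 or 1")
    quantum = Decimal("1") if decimals == 0 else Decimal("0.1")
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def consort_summary(clinical: pd.DataFrame, decimals: int = 0) -> pd.DataFrame:
    """Patient-level enrollment summary: counts and percentages.

    Returns a tidy table with sections for pathologic response, subtype
    (taken from each patient's earliest sample) and time-point availability.
    Percentages within the ``pcr`` and ``subtype`` sections partition the
    cohort and therefore sum to 100 up to rounding slack.
    """
    validate_clinical(clinical)
    if clinical.empty:
        raise CohortError("consort_summary: empty clinical table")
    order = {t: i for i, t in enumerate(TIMEPOINTS)}
    per_patient = (
        clinical.assign(_t=clinical["time"].map(order))
        .sort_values("_t")
        .groupby("patient_id", sort=False)
        .first()
    )
    n_patients = len(per_patient)
    rows = []
    for level in PCR_LEVELS:
        count = int((per_patient["pcr"] == level).sum())
        rows.append(("pcr", level, count, percent_of(count, n_patients, decimals)))
    for subtype in SUBTYPES:
        count = int((per_patient["subtype"] == subtype).sum())
        rows.append(("subtype", subtype, count, percent_of(count, n_patients, decimals)))
    by_patient_times = clinical.groupby("patient_id")["time"].agg(set)
    for time in TIMEPOINTS:
        count = int(by_patient_times.apply(lambda s: time in s).sum())
        rows.append(("time_available", time, count, percent_of(count, n_patients, decimals)))
    return pd.DataFrame(rows, columns=["section", "level", "count", "percent"])


def build_pairs(clinical: pd.DataFrame, time_a: str, time_b: str) -> pd.DataFrame:
    """Map each patient with samples at both time points to its sample pair.

    Returns a frame indexed by patient with columns ``sample_a, sample_b``.
    Patients missing either time point are excluded.
    """
    validate_clinical(clinical)
    for t in (time_a, time_b):
        if t not in TIMEPOINTS:
            raise CohortError(f"unknown time point {t!r}")
    if time_a == time_b:
        raise CohortError("build_pairs: time points must differ")
    a = clinical[clinical["time"] == time_a].set_index("patient_id")["sample_id"]
    b = clinical[clinical["time"] == time_b].set_index("patient_id")["sample_id"]
    shared = a.index.intersection(b.index)
    pairs = pd.DataFrame({"sample_a": a.loc[shared], "sample_b": b.loc[shared]})
    pairs.index.name = "patient_id"
    return pairs
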