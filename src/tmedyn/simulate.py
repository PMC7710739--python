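"""Synthetic cohort generation with retained ground truth.

The generator emulates the statistical structure of a serial-biopsy
neoadjuvant-chemotherapy (NAC) study: paired tumor samples per patient at
up to three time points (T1 pre-treatment, T2 on-treatment, T3 surgery),
log2-scale expression driven by purity/subtype/time fixed effects plus a
patient random intercept, signature-bearing gene blocks, immune cell-type
mixtures built from a reference signature matrix, and histology-like
images with planted lymphocyte and non-lymphocyte nuclei.

Every artifact carries a ground-truth record so recovery tests can compare
estimates against planted values.

Defaults mirror the emulated study's design: four subtypes at proportions
0.22 / 0.20 / 0.20 / 0.38, a 38% pathologic-complete-response (pCR) rate,
and surgery (T3) samples collected only from residual-disease patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import SUBTYPES, TIMEPOINTS, CohortError, validate_clinical

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_mixtures",
    "simulate_histology_image",
    "simulate_state_cohort",
    "default_signature_matrix",
    "CELL_TYPES_13",
    "DEFAULT_CELL_TYPE_MAP",
]


DEFAULT_SUBTYPE_PROPORTIONS = {
    "ER+/HER2-": 0.22,
    "ER+/HER2+": 0.20,
    "HER2+/ER-": 0.20,
    "TN": 0.38,
}


@dataclass
class BlockEffects:
    """Fixed effects (log2 units) for one signature-bearing gene block.

    ``time`` maps non-reference time points (T2, T3) to shifts relative to
    T1; ``subtype`` maps non-reference subtypes to shifts relative to
    ER+/HER2-; ``purity`` is the slope on tumor purity.
    """

    purity: float = 0.0
    subtype: dict[str, float] = field(default_factory=dict)
    time: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Design of a synthetic longitudinal expression cohort."""

    n_patients: int = 146
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS)
    )
    timepoints: tuple[str, ...] = TIMEPOINTS
    pcr_rate: float = 0.38
    dropout_rule: float = 0.10  # extra probability an RD patient lacks T3
    n_genes: int = 2000
    signature_blocks: dict[str, int] = field(
        default_factory=lambda: {"immune": 100, "cell_cycle": 100, "emt_ecm": 100}
    )
    effect_sizes: dict[str, BlockEffects] = field(
        default_factory=lambda: {
            "immune": BlockEffects(purity=-1.0, time={"T2": 1.0, "T3": -0.5}),
            "cell_cycle": BlockEffects(purity=1.0, time={"T2": -1.0, "T3": 0.5}),
            "emt_ecm": BlockEffects(purity=-0.5, time={"T2": 0.8, "T3": -0.3}),
        }
    )
    baseline_log2_range: tuple[float, float] = (3.0, 9.0)
    random_intercept_sd: float = 0.5
    residual_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        props = self.subtype_proportions
        if set(props) - set(SUBTYPES):
            raise CohortError(f"unknown subtypes: {set(props) - set(SUBTYPES)}")
        if abs(sum(props.values()) - 1.0) > 1e-8:
            raise CohortError("subtype proportions must sum to 1")
        if min(props.values()) < 0:
            raise CohortError("subtype proportions must be non-negative")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise CohortError("standard deviations must be >= 0")
        if not 0 <= self.pcr_rate <= 1 or not 0 <= self.dropout_rule <= 1:
            raise CohortError("rates must lie in [0, 1]")
        if self.n_genes < sum(self.signature_blocks.values()):
            raise CohortError("n_genes smaller than the sum of block sizes")
        if tuple(self.timepoints) != TIMEPOINTS:
            raise CohortError(f"timepoints must be {TIMEPOINTS}")
        for block in self.effect_sizes:
            if block not in self.signature_blocks:
                raise CohortError(f"effects given for unknown block {block!r}")
        return self


@dataclass
class CohortTruth:
    """Ground truth for one simulated cohort."""

    gene_effects: pd.DataFrame  # per gene: block, beta0, beta_purity, subtype/time betas
    patient_intercepts: pd.Series  # patient -> random intercept (log2)
    log2_expression: pd.DataFrame  # noiseless+noise log2 values actually exponentiated
    config: SimulationConfig


def _purity_draw(rng: np.random.Generator, time: str) -> float:
    # Pre-treatment biopsies are tumor-rich, Beta(5,2); purity drops
    # on-treatment/at surgery (Beta(4,3)) mirroring lower on-treatment
    # cellularity. Magnitude is a free design choice.
    if time == "T1":
        return float(rng.beta(5.0, 2.0))
    return float(rng.beta(4.0, 3.0))


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a longitudinal cohort: (TPM expression, clinical table, truth).

    Log2 expression of gene j in sample i follows

        y_ij = beta0_j + beta1_j * purity_i + beta2_j[subtype_i]
               + beta3_j[time_i] + b_patient(i) + eps_ij

    and is exponentiated to a TPM-like scale via ``2 ** y``. pCR patients
    never receive a T3 sample; RD patients may drop out of T3 with
    probability ``dropout_rule``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subtype_names = list(config.subtype_proportions)
    subtype_p = np.array([config.subtype_proportions[s] for s in subtype_names])

    # --- patients ----------------------------------------------------------
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    subtypes = rng.choice(subtype_names, size=config.n_patients, p=subtype_p)
    pcr = np.where(rng.random(config.n_patients) < config.pcr_rate, "pCR", "RD")
    intercepts = rng.normal(0.0, config.random_intercept_sd, size=config.n_patients)

    rows = []
    for idx, patient in enumerate(patients):
        times = ["T1", "T2"]
        if pcr[idx] == "RD" and rng.random() >= config.dropout_rule:
            times.append("T3")
        for time in times:
            rows.append(
                {
                    "patient_id": patient,
                    "sample_id": f"{patient}_{time}",
                    "subtype": subtypes[idx],
                    "time": time,
                    "purity": round(_purity_draw(rng, time), 4),
                    "pcr": pcr[idx],
                }
            )
    clinical = validate_clinical(pd.DataFrame(rows))

    # --- per-gene effects --------------------------------------------------
    genes, blocks = [], []
    for block, size in config.signature_blocks.items():
        genes += [f"{block.upper()}_{i + 1:04d}" for i in range(size)]
        blocks += [block] * size
    n_bg = config.n_genes - len(genes)
    genes += [f"BG_{i + 1:05d}" for i in range(n_bg)]
    blocks += ["background"] * n_bg

    lo, hi = config.baseline_log2_range
    beta0 = rng.uniform(lo, hi, size=config.n_genes)
    effect_cols: dict[str, np.ndarray] = {"beta_purity": np.zeros(config.n_genes)}
    for s in subtype_names[1:]:
        effect_cols[f"beta_subtype[{s}]"] = np.zeros(config.n_genes)
    for t in ("T2", "T3"):
        effect_cols[f"beta_time[{t}]"] = np.zeros(config.n_genes)
    block_arr = np.array(blocks)
    for block, eff in config.effect_sizes.items():
        mask = block_arr == block
        effect_cols["beta_purity"][mask] = eff.purity
        for s, v in eff.subtype.items():
            effect_cols[f"beta_subtype[{s}]"][mask] = v
        for t, v in eff.time.items():
            effect_cols[f"beta_time[{t}]"][mask] = v
    gene_effects = pd.DataFrame({"block": blocks, "beta0": beta0, **effect_cols}, index=genes)

    # --- assemble log2 expression -----------------------------------------
    purity = clinical["purity"].to_numpy()
    pat_index = clinical["patient_id"].map({p: i for i, p in enumerate(patients)}).to_numpy()
    y = np.tile(beta0[:, None], (1, len(clinical)))
    y += np.outer(effect_cols["beta_purity"], purity)
    for s in subtype_names[1:]:
        ind = (clinical["subtype"] == s).to_numpy(dtype=float)
        y += np.outer(effect_cols[f"beta_subtype[{s}]"], ind)
    for t in ("T2", "T3"):
        ind = (clinical["time"] == t).to_numpy(dtype=float)
        y += np.outer(effect_cols[f"beta_time[{t}]"], ind)
    y += intercepts[pat_index][None, :]
    if config.residual_sd > 0:
        y += rng.normal(0.0, config.residual_sd, size=y.shape)

    log2_expr = pd.DataFrame(y, index=genes, columns=clinical["sample_id"].tolist())
    expr = np.power(2.0, log2_expr)

    truth = CohortTruth(
        gene_effects=gene_effects,
        patient_intercepts=pd.Series(intercepts, index=patients, name="intercept"),
        log2_expression=log2_expr,
        config=config,
    )
    return expr, clinical, truth


# ---------------------------------------------------------------------------
# immune cell mixtures
# ---------------------------------------------------------------------------

CELL_TYPES_13 = (
    "B.naive", "B.memory", "CD4.naive", "CD4.memory", "CD8.T", "T.reg",
    "NK", "Monocyte", "Macro.M0", "Macro.M1", "Macro.M2", "Mast", "DC",
)

#: Default aggregation of the 13 reference profiles into 10 reported groups.
DEFAULT_CELL_TYPE_MAP = {
    "B.naive": "B.cells", "B.memory": "B.cells",
    "CD4.naive": "CD4.other", "T.reg": "CD4.other",
    "CD4.memory": "CD4.memory", "CD8.T": "CD8.T", "NK": "NK",
    "Monocyte": "Mono.M0", "Macro.M0": "Mono.M0",
    "Macro.M1": "Macro.M1", "Macro.M2": "Macro.M2",
    "Mast": "Mast", "DC": "DC",
}


def default_signature_matrix(
    n_markers_per_type: int = 20,
    marker_level: float = 100.0,
    background_level: float = 2.0,
    seed: int = 2024,
) -> pd.DataFrame:
    """Synthetic genes x cell-types reference signature matrix.

    Each of the 13 archetypal leukocyte profiles over-expresses its own
    marker block (around ``marker_level`` TPM) against a shared low
    background, the structure a deconvolution reference relies on. This is
    a synthetic stand-in: real signature matrices are derived from sorted
    immune-cell expression profiles.
    """
    rng = np.random.default_rng(seed)
    k = len(CELL_TYPES_13)
    genes = [
        f"MK_{ct.replace('.', '')}_{i + 1:02d}"
        for ct in CELL_TYPES_13
        for i in range(n_markers_per_type)
    ]
    values = rng.uniform(0.5, 1.5, size=(len(genes), k)) * background_level
    for t in range(k):
        rows = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        values[rows, t] = rng.uniform(0.7, 1.3, size=n_markers_per_type) * marker_level
    return pd.DataFrame(values, index=genes, columns=list(CELL_TYPES_13))


def simulate_mixtures(
    signature: pd.DataFrame,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    alpha: float = 1.0,
    fractions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear cell-type mixtures from a signature matrix.

    Each mixture column is ``signature @ f`` with ``f`` drawn from a
    Dirichlet(alpha) on the simplex (or supplied via ``fractions``), plus
    Gaussian noise truncated at zero. Returns (mixtures, true fractions
    samples x cell-types).
    """
    if signature.shape[1] < 2:
        raise CohortError("signature must have at least 2 cell types")
    if noise_sd < 0:
        raise CohortError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    k = signature.shape[1]
    if fractions is None:
        fractions = rng.dirichlet(np.full(k, alpha), size=n_samples)
    else:
        fractions = np.asarray(fractions, dtype=float)
        if fractions.shape != (n_samples, k):
            raise CohortError("fractions shape must be (n_samples, n_cell_types)")
        if (fractions < 0).any() or not np.allclose(fractions.sum(axis=1), 1.0):
            raise CohortError("fractions must lie on the simplex")
    mix = signature.to_numpy() @ fractions.T
    if noise_sd > 0:
        mix = np.clip(mix + rng.normal(0.0, noise_sd, size=mix.shape), 0.0, None)
    samples = [f"MIX_{i + 1:03d}" for i in range(n_samples)]
    mixtures = pd.DataFrame(mix, index=signature.index, columns=samples)
    true_fractions = pd.DataFrame(fractions, index=samples, columns=signature.columns)
    return mixtures, true_fractions


# ---------------------------------------------------------------------------
# histology-like images
# ---------------------------------------------------------------------------

LYMPHOCYTE_AREA_RANGE = (70, 140)  # planted areas sit inside the 60-150 gate
OTHER_AREA_RANGE = (260, 620)


def _disk_mask(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx ** 2 + yy ** 2) <= radius ** 2


def _blob_mask(rng: np.random.Generator, area: float) -> np.ndarray:
    """Irregular elliptical nucleus mask with the requested approximate area."""
    ratio = rng.uniform(1.3, 2.2)
    b = np.sqrt(area / (np.pi * ratio))
    a = ratio * b
    theta = rng.uniform(0, np.pi)
    r = int(np.ceil(a)) + 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    wobble = 1.0 + 0.15 * np.sin(3 * np.arctan2(v, u) + rng.uniform(0, 2 * np.pi))
    return (u / a) ** 2 + (v / b) ** 2 <= wobble


def simulate_histology_image(
    width: int,
    height: int,
    n_lymphocytes: int,
    n_other: int,
    seed: int = 0,
    tissue_margin_frac: float = 0.05,
    max_place_attempts: int = 200,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a grayscale-on-RGB caricature of an H&E tile.

    A light textured tissue region (with rounded corners) sits on a
    near-white slide background. Lymphocytes are small round dark nuclei
    with pixel areas in [60, 150]; non-lymphocytes are larger (area > 200),
    irregular and slightly lighter. Returns (uint8 RGB image, truth table
    with columns ``cell_type, x, y, area``).

    The intent is a detector test-bed driven by intensity and shape, not a
    realistic stain simulation.
    """
    rng = np.random.default_rng(seed)
    if width < 64 or height < 64:
        raise CohortError("image must be at least 64x64 pixels")

    margin = int(round(min(width, height) * tissue_margin_frac))
    canvas = np.full((height, width), 0.96, dtype=float)

    tissue = np.zeros((height, width), dtype=bool)
    tissue[margin : height - margin, margin : width - margin] = True
    # soften corners so tissue vs slide is not a perfect rectangle
    tissue = ndimage.binary_erosion(tissue, iterations=1)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(height, width)), 3.0)
    texture = 0.035 * texture / max(texture.std(), 1e-12)
    canvas[tissue] = 0.80 + texture[tissue]

    # rough capacity check before rejection sampling
    need = n_lymphocytes * 150 + n_other * 700
    if need > 0.5 * tissue.sum():
        raise CohortError("image too small for the requested cell counts")

    occupied = ~tissue.copy()  # cells must not leave tissue or overlap
    records = []

    def place(mask: np.ndarray, intensity: float, cell_type: str) -> bool:
        h, w = mask.shape
        for _ in range(max_place_attempts):
            top = rng.integers(margin, height - margin - h)
            left = rng.integers(margin, width - margin - w)
            region = occupied[top : top + h, left : left + w]
            grown = ndimage.binary_dilation(mask, iterations=2)
            if (region & grown).any():
                continue
            sub = canvas[top : top + h, left : left + w]
            sub[mask] = intensity + rng.normal(0.0, 0.015, size=int(mask.sum()))
            occupied[top : top + h, left : left + w] |= grown
            ys, xs = np.nonzero(mask)
            records.append(
                {
                    "cell_type": cell_type,
                    "x": float(left + xs.mean()),
                    "y": float(top + ys.mean()),
                    "area": int(mask.sum()),
                }
            )
            return True
        return False

    for _ in range(n_other):
        area = rng.uniform(*OTHER_AREA_RANGE)
        if not place(_blob_mask(rng, area), 0.38, "other"):
            raise CohortError("could not place all non-lymphocyte nuclei")
    for _ in range(n_lymphocytes):
        area = rng.uniform(*LYMPHOCYTE_AREA_RANGE)
        radius = np.sqrt(area / np.pi)
        if not place(_disk_mask(radius), 0.15, "lymphocyte"):
            raise CohortError("could not place all lymphocyte nuclei")

    canvas = np.clip(canvas, 0.0, 1.0)
    image = np.repeat((canvas * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    truth = pd.DataFrame(records, columns=["cell_type", "x", "y", "area"])
    return image, truth


# ---------------------------------------------------------------------------
# outcome feature panel with planted on-treatment signal
# ---------------------------------------------------------------------------

def simulate_outcome_panel(
    n_patients: int = 120,
    n_noise: int = 8,
    n_signal: int = 8,
    max_effect: float = 2.0,
    min_effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-patient feature panel where only on-treatment (T2) features
    carry outcome signal.

    Baseline (T1) features are pure noise; T2 features drive a logistic
    pCR model with log-odds effects spaced from ``max_effect`` down to
    ``min_effect``. Returns (panel with ``pcr`` column, noise feature
    names, signal feature names).
    """
    rng = np.random.default_rng(seed)
    noise_cols = [f"noise_T1_{i + 1}" for i in range(n_noise)]
    signal_cols = [f"immune_T2_{i + 1}" for i in range(n_signal)]
    X = pd.DataFrame(
        rng.normal(0.0, 1.0, (n_patients, n_noise + n_signal)),
        columns=noise_cols + signal_cols,
    )
    effects = np.linspace(max_effect, min_effect, n_signal)
    lin = X[signal_cols].to_numpy() @ effects
    pcr = np.where(rng.random(n_patients) < 1.0 / (1.0 + np.exp(-lin)), "pCR", "RD")
    return X.assign(pcr=pcr), noise_cols, signal_cols


# ---------------------------------------------------------------------------
# planted immune-state cohort (for integrative clustering tests)
# ---------------------------------------------------------------------------

def simulate_state_cohort(
    n_patients: int = 60,
    n_signatures: int = 24,
    n_fractions: int = 10,
    separation: float = 5.0,
    seed: int = 0,
    transition: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort with planted cold/warm/hot immune states at T1 and T2.

    Each sample gets a latent intensity level (0=cold, 1=warm, 2=hot).
    State mean patterns are distinct (affinely independent) directions in
    feature space scaled by ``separation`` noise standard deviations, with
    the overall mean increasing from cold to hot so the intensity ordering
    is planted. T2 states follow a Markov transition from T1 (default
    biased toward warming, mirroring on-treatment immune stimulation).

    Returns (signature block, fraction block, truth) where the blocks are
    samples x features and truth has columns ``sample_id, patient_id,
    time, state_level``.
    """
    rng = np.random.default_rng(seed)
    levels = ["C", "W", "H"]
    default_transition = {
        "C": {"C": 0.5, "W": 0.4, "H": 0.1},
        "W": {"C": 0.1, "W": 0.3, "H": 0.6},
        "H": {"C": 0.05, "W": 0.15, "H": 0.8},
    }
    transition = transition or default_transition

    # distinct mean patterns per level: cold at the origin, warm and hot
    # along different half-space directions so the three cluster centers
    # are affinely independent (they span two latent dimensions), while
    # the overall mean still increases cold -> warm -> hot
    def patterns(n_features: int) -> np.ndarray:
        half = n_features // 2
        warm = np.concatenate([np.ones(half), 0.3 * np.ones(n_features - half)])
        hot = np.concatenate([0.6 * np.ones(half), 1.6 * np.ones(n_features - half)])
        return np.vstack([np.zeros(n_features), warm, hot])

    sig_patterns = patterns(n_signatures)
    frac_patterns = patterns(n_fractions)

    rows, sig_rows, frac_rows = [], [], []
    for i in range(n_patients):
        patient = f"P{i + 1:03d}"
        s1 = levels[rng.integers(0, 3)]
        probs = [transition[s1][l] for l in levels]
        s2 = levels[rng.choice(3, p=np.asarray(probs) / np.sum(probs))]
        for time, state in (("T1", s1), ("T2", s2)):
            level = levels.index(state)
            sig = rng.normal(sig_patterns[level] * separation, 1.0)
            frac = rng.normal(frac_patterns[level] * separation, 1.0)
            rows.append(
                {
                    "sample_id": f"{patient}_{time}",
                    "patient_id": patient,
                    "time": time,
                    "state_level": level,
                    "state": state,
                }
            )
            sig_rows.append(sig)
            frac_rows.append(frac)
    truth = pd.DataFrame(rows)
    index = truth["sample_id"]
    signatures = pd.DataFrame(
        np.asarray(sig_rows), index=index, columns=[f"SIG_{j + 1:02d}" for j in range(n_signatures)]
    )
    fractions = pd.DataFrame(
        np.asarray(frac_rows), index=index, columns=[f"FRAC_{j + 1:02d}" for j in range(n_fractions)]
    )
    return signatures, fractions, truth
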