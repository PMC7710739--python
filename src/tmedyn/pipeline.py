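"""End-to-end orchestration of the serial-biopsy immune-dynamics analysis.

``run_pipeline`` executes the stages in order — simulate (or load),
normalize, score, differential expression, consensus clustering,
deconvolution, immune states, virtual microdissection, TIL imaging and
outcome modeling — writing per-stage TSV/CSV/JSON artifacts plus a
``summary.json`` holding the consort and immune-state-transition
percentages. One global seed fans out to per-stage seeds by fixed
offsets; every artifact directory records the config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import deconv, imaging, microdissect, scoring, states
from .io import (
    CohortError,
    build_pairs,
    consort_summary,
    percent_of,
    read_clinical,
    read_expression,
    write_clinical,
    write_expression,
)
from .outcome import elasticnet_bootstrap
from .simulate import (
    DEFAULT_CELL_TYPE_MAP,
    SimulationConfig,
    default_signature_matrix,
    simulate_cohort,
    simulate_histology_image,
    simulate_mixtures,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "demo_config"]

# per-stage seed offsets fanned out from the global seed
_SEED_OFFSETS = {
    "simulate": 1,
    "score": 2,
    "de": 3,
    "cluster": 4,
    "deconvolve": 5,
    "states": 6,
    "microdissect": 7,
    "til": 8,
    "outcome": 9,
}

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "outdir": "pipeline_out",
    "stages": {
        "simulate": True,
        "score": True,
        "de": True,
        "cluster": True,
        "deconvolve": True,
        "states": True,
        "microdissect": True,
        "til": True,
        "outcome": True,
    },
    "inputs": {"expression": None, "clinical": None},
    "synthetic": {
        "n_patients": 40,
        "n_genes": 400,
        "signature_blocks": {"immune": 40, "cell_cycle": 40, "emt_ecm": 40},
        "random_intercept_sd": 0.5,
        "residual_sd": 0.5,
    },
    "de": {"groups": "overall"},
    "cluster": {"k": 3, "n_resamples": 30},
    "deconvolve": {"noise_sd": 2.0},
    "states": {"k": 3, "penalty": 0.05},
    "microdissect": {"k": 3, "n_runs": 5, "max_iter": 600},
    "til": {"image_size": 600, "n_lymphocytes": 40, "n_other": 15},
    "outcome": {"n_boot": 100, "alpha": 0.5, "n_folds": 3, "n_cs": 4},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as handle:
        user = yaml.safe_load(handle) or {}
    return _merge(DEFAULT_CONFIG, user)


def demo_config(seed: int = 42, outdir: str = "pipeline_out") -> dict:
    return _merge(DEFAULT_CONFIG, {"seed": seed, "outdir": outdir})


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _stage_seed(config: dict, stage: str) -> int:
    return (int(config["seed"]) * 101 + _SEED_OFFSETS[stage]) % (2**31 - 1)


class _Ctx:
    """Mutable bag of stage products."""

    def __init__(self):
        self.expr = None
        self.clinical = None
        self.truth = None
        self.log_expr = None
        self.scores = None
        self.cyt = None
        self.gene_sets = None
        self.de_results = None
        self.clusters = None
        self.fractions = None
        self.state_labels = None
        self.transitions = {}
        self.nmf = None
        self.til = None
        self.usage = None


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run all enabled stages; returns the summary dict (also written to
    ``summary.json``). Raises with the failing stage named."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    if config["inputs"]["expression"] and config["stages"].get("simulate"):
        raise CohortError("config: give real input paths or a synthetic block, not both")
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    ctx = _Ctx()
    summary: dict = {
        "config_hash": _config_hash(config),
        "seed": int(config["seed"]),
        "stage_seeds": {s: _stage_seed(config, s) for s in _SEED_OFFSETS},
        "stages_run": [],
    }

    order = [
        ("simulate", _stage_simulate),
        ("score", _stage_score),
        ("de", _stage_de),
        ("cluster", _stage_cluster),
        ("deconvolve", _stage_deconvolve),
        ("states", _stage_states),
        ("microdissect", _stage_microdissect),
        ("til", _stage_til),
        ("outcome", _stage_outcome),
    ]
    for name, fn in order:
        if not stages.get(name, False):
            continue
        logger.info("stage %s", name)
        try:
            fn(config, ctx, out, summary)
        except Exception as exc:
            raise CohortError(f"stage {name!r} failed: {exc}") from exc
        summary["stages_run"].append(name)

    with open(out / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=float)
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, ctx, out, summary):
    syn = config["synthetic"]
    blocks = dict(syn["signature_blocks"])
    default_effects = SimulationConfig().effect_sizes
    sim_config = SimulationConfig(
        n_patients=syn["n_patients"],
        n_genes=syn["n_genes"],
        signature_blocks=blocks,
        effect_sizes={b: default_effects[b] for b in blocks if b in default_effects},
        random_intercept_sd=syn["random_intercept_sd"],
        residual_sd=syn["residual_sd"],
        seed=_stage_seed(config, "simulate"),
    )
    expr, clinical, truth = simulate_cohort(sim_config)
    # give the cytolytic marker genes their canonical names so the CYT
    # score is computable downstream
    immune_genes = truth.gene_effects.index[truth.gene_effects["block"] == "immune"]
    if len(immune_genes) >= 2:
        renames = {immune_genes[0]: "GZMA", immune_genes[1]: "PRF1"}
        expr = expr.rename(index=renames)
        truth.gene_effects = truth.gene_effects.rename(index=renames)
    ctx.expr, ctx.clinical, ctx.truth = expr, clinical, truth
    write_expression(expr, out / "expression_tpm.tsv")
    write_clinical(clinical, out / "clinical.csv")
    consort = consort_summary(clinical)
    consort.to_csv(out / "consort.csv", index=False)
    summary["consort"] = consort.to_dict(orient="records")
    n_patients = clinical["patient_id"].nunique()
    n_pcr = int(consort.loc[(consort["section"] == "pcr") & (consort["level"] == "pCR"),
                            "count"].iloc[0])
    summary["pcr_percent"] = percent_of(n_pcr, n_patients)


def _maybe_load(config, ctx):
    if ctx.expr is None:
        paths = config["inputs"]
        if not (paths["expression"] and paths["clinical"]):
            raise CohortError("no simulated data and no input paths; "
                              "enable the simulate stage or provide inputs")
        ctx.expr = read_expression(paths["expression"])
        ctx.clinical = read_clinical(paths["clinical"])


def _stage_score(config, ctx, out, summary):
    _maybe_load(config, ctx)
    ctx.log_expr = scoring.log_transform(ctx.expr)
    ctx.cyt = scoring.cyt_score(ctx.expr) if {"GZMA", "PRF1"} <= set(ctx.expr.index) else None
    if ctx.truth is not None:
        blocks = ctx.truth.gene_effects["block"]
        ctx.gene_sets = {
            f"{b.upper()}_BLOCK": blocks.index[blocks == b].tolist()
            for b in blocks.unique()
            if b != "background"
        }
    if ctx.gene_sets:
        ctx.scores = scoring.gsva_scores(ctx.log_expr, ctx.gene_sets)
        ctx.scores.to_csv(out / "gsva_scores.tsv", sep="\t")
    if ctx.cyt is not None:
        ctx.cyt.to_csv(out / "cyt_scores.csv")


def _stage_de(config, ctx, out, summary):
    if ctx.log_expr is None:
        raise CohortError("score stage must run before de")
    ctx.de_results = de_mod.run_de(ctx.log_expr, ctx.clinical,
                                   groups=config["de"]["groups"])
    ctx.de_results.to_csv(out / "de_results.tsv", sep="\t", index=False)
    selected = de_mod.select_de_genes(ctx.de_results)
    summary["n_de_genes"] = len(selected)
    (out / "de_genes.txt").write_text("\n".join(selected) + "\n")


def _stage_cluster(config, ctx, out, summary):
    if ctx.de_results is None:
        raise CohortError("de stage must run before cluster")
    selected = de_mod.select_de_genes(ctx.de_results)
    if len(selected) < config["cluster"]["k"]:
        logger.warning("too few DE genes (%d) to cluster; skipped", len(selected))
        summary["de_clusters"] = None
        return
    labels, consensus = de_mod.consensus_kmeans(
        ctx.log_expr.loc[selected],
        ctx.clinical,
        k=config["cluster"]["k"],
        n_resamples=config["cluster"]["n_resamples"],
        seed=_stage_seed(config, "cluster"),
    )
    ctx.clusters = labels
    labels.to_csv(out / "de_gene_clusters.csv")
    summary["de_clusters"] = labels.value_counts().to_dict()


def _stage_deconvolve(config, ctx, out, summary):
    _maybe_load(config, ctx)
    signature = default_signature_matrix()
    n = ctx.clinical.shape[0]
    mixtures, _true = simulate_mixtures(
        signature, n, noise_sd=config["deconvolve"]["noise_sd"],
        seed=_stage_seed(config, "deconvolve"),
    )
    mixtures.columns = ctx.clinical["sample_id"].tolist()
    fractions = deconv.nusvr_deconvolve(mixtures, signature)
    fractions = deconv.aggregate_cell_types(fractions, DEFAULT_CELL_TYPE_MAP)
    ctx.fractions = fractions
    fractions.to_csv(out / "cell_fractions.tsv", sep="\t")


def _stage_states(config, ctx, out, summary):
    if ctx.scores is None or ctx.fractions is None:
        raise CohortError("score and deconvolve stages must run before states")
    score_block = scoring.zscale(ctx.scores).T
    frac_block = ctx.fractions[deconv.fraction_columns(ctx.fractions)]
    frac_block = frac_block.loc[score_block.index]
    model = states.integrative_cluster(
        [score_block, frac_block],
        k=config["states"]["k"],
        penalty=config["states"]["penalty"],
        seed=_stage_seed(config, "states"),
    )
    # immune-intensity summary: z-scored CYT plus z-scored immune fraction sum
    if ctx.cyt is not None:
        cyt_z = (ctx.cyt - ctx.cyt.mean()) / max(ctx.cyt.std(ddof=1), 1e-12)
    else:
        cyt_z = pd.Series(0.0, index=score_block.index)
    imm = frac_block[[c for c in ("CD8.T", "CD4.memory", "Macro.M1")
                      if c in frac_block.columns]].sum(axis=1)
    imm_z = (imm - imm.mean()) / max(imm.std(ddof=1), 1e-12)
    intensity = cyt_z.loc[score_block.index] + imm_z
    labels = states.label_states(model, intensity)
    ctx.state_labels = labels
    labels.rename("state").to_csv(out / "immune_states.csv")
    for time_a, time_b in (("T1", "T2"), ("T2", "T3")):
        pairs = build_pairs(ctx.clinical, time_a, time_b)
        if pairs.empty:
            continue
        table = states.transition_percentages(states.transition_table(labels, pairs))
        table.to_csv(out / f"transitions_{time_a}_{time_b}.csv", index=False)
        ctx.transitions[(time_a, time_b)] = table
        summary[f"transitions_{time_a}_{time_b}"] = table.to_dict(orient="records")


def _stage_microdissect(config, ctx, out, summary):
    if ctx.log_expr is None:
        raise CohortError("score stage must run before microdissect")
    seed = _stage_seed(config, "microdissect")
    model = microdissect.nmf_brunet(
        ctx.log_expr, k=config["microdissect"]["k"],
        n_runs=config["microdissect"]["n_runs"],
        max_iter=config["microdissect"]["max_iter"], seed=seed,
    )
    ctx.nmf = model
    model.W.to_csv(out / "nmf_gene_weights.tsv", sep="\t")
    model.H.to_csv(out / "nmf_sample_weights.tsv", sep="\t")
    exemplars = microdissect.exemplar_genes(model.W)
    with open(out / "nmf_meta.json", "w", encoding="utf-8") as handle:
        json.dump(
            {
                "k": model.k,
                "kl_error": model.approximation_error,
                "run_seed": model.run_seed,
                "converged": model.converged,
                "exemplars": exemplars,
            },
            handle, indent=2,
        )
    summary["nmf_kl_error"] = model.approximation_error
    summary["nmf_exemplars"] = {f: len(g) for f, g in exemplars.items()}


def _stage_til(config, ctx, out, summary):
    cfg = config["til"]
    seed = _stage_seed(config, "til")
    size = cfg["image_size"]
    test_img, test_truth = simulate_histology_image(
        size, size, cfg["n_lymphocytes"], cfg["n_other"], seed=seed + 1
    )
    model = imaging.train_default_classifier(seed=seed % 1000, n_images=4)
    cands = imaging.tile_process(test_img, model)
    lymph, _non, large = imaging.filter_lymphocytes(cands)
    quant = imaging.compute_density(len(lymph), test_img,
                                    large_cell_count=len(large))
    ctx.til = quant
    report = {
        "lymphocyte_count": quant.lymphocyte_count,
        "planted_lymphocytes": int((test_truth["cell_type"] == "lymphocyte").sum()),
        "large_cell_count": quant.large_cell_count,
        "tissue_area_mm2": quant.tissue_area_mm2,
        "density_per_mm2": quant.density_per_mm2,
        "um_per_px": quant.um_per_px,
    }
    with open(out / "til_report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2)
    pd.DataFrame(
        [{"x": c.x, "y": c.y, "area": c.area, "prob": c.probability, "label": c.label}
         for c in cands]
    ).to_csv(out / "til_cells.csv", index=False)
    summary["til"] = report


def _stage_outcome(config, ctx, out, summary):
    if ctx.fractions is None:
        raise CohortError("deconvolve stage must run before outcome")
    cfg = config["outcome"]
    clin = ctx.clinical.set_index("sample_id")
    frac_cols = deconv.fraction_columns(ctx.fractions)[:5]
    rows = {}
    for patient, group in ctx.clinical.groupby("patient_id"):
        row = {"pcr": group["pcr"].iloc[0]}
        for time in ("T1", "T2"):
            match = group[group["time"] == time]
            if match.empty:
                continue
            sample = match["sample_id"].iloc[0]
            row[f"purity_{time}"] = float(match["purity"].iloc[0])
            if ctx.cyt is not None and sample in ctx.cyt.index:
                row[f"CYT_{time}"] = float(ctx.cyt[sample])
            for c in frac_cols:
                row[f"{c}_{time}"] = float(ctx.fractions.loc[sample, c])
        rows[patient] = row
    panel = pd.DataFrame.from_dict(rows, orient="index").dropna()
    features = [c for c in panel.columns if c not in ("pcr",)]
    if panel["pcr"].nunique() < 2 or len(panel) < 20:
        logger.warning("outcome panel too small or degenerate; skipped")
        summary["outcome"] = None
        return
    usage = elasticnet_bootstrap(
        panel, features, "pcr",
        n_boot=cfg["n_boot"], alpha=cfg["alpha"], n_folds=cfg["n_folds"],
        n_cs=cfg["n_cs"], seed=_stage_seed(config, "outcome"),
    )
    ctx.usage = usage
    usage.to_csv(out / "variable_usage.csv")
    summary["outcome"] = {
        "top_feature": usage.index[0],
        "top_usage_pct": float(usage["usage_pct"].iloc[0]),
        "n_boot": cfg["n_boot"],
    }
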