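"""Config-driven orchestration of the full analysis chain.

Stage order mirrors the analysis: (simulate?) -> mutations -> express ->
score -> immune -> clinical. A manifest records the config hash, the seed,
the package version and per-stage row counts; rerunning an identical config
produces a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    ExpressionMatrix,
    FamilyAnnotation,
    GeneSet,
    ValidationError,
    load_bundled_family_annotation,
    load_bundled_immune_regulators,
    read_clinical,
    read_expression,
    read_family_annotation,
    read_feature_table,
    read_maf_like,
    write_expression,
    write_result_table,
)
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)

STAGES = ("mutations", "express", "score", "immune", "clinical")

#: Default thresholds; every value equals the published analysis default.
DEFAULT_THRESHOLDS = {
    "fdr": 0.05, "scc": 0.75, "E": 2.0, "k_min": 3,
    "minprop": 0.1, "alpha": 0.25,
}

_RUN_KEYS = {"seed", "output_dir", "stages", "thresholds", "inputs", "simulate"}
_INPUT_KEYS = {"family", "maf", "fpkm", "meta", "clinical", "features",
               "categories"}


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    stages: tuple = STAGES
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    inputs: dict = field(default_factory=dict)
    simulate: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - _RUN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data or "output_dir" not in data:
            raise ValidationError("config requires 'seed' and 'output_dir'")
        inputs = dict(data.get("inputs") or {})
        bad = set(inputs) - _INPUT_KEYS
        if bad:
            raise ValidationError(f"unknown input keys: {sorted(bad)}")
        thresholds = dict(DEFAULT_THRESHOLDS)
        extra = set(data.get("thresholds") or {}) - set(thresholds)
        if extra:
            raise ValidationError(f"unknown threshold keys: {sorted(extra)}")
        thresholds.update(data.get("thresholds") or {})
        stages = tuple(data.get("stages") or STAGES)
        bad_stages = set(stages) - set(STAGES)
        if bad_stages:
            raise ValidationError(f"unknown stages: {sorted(bad_stages)}")
        sim = None
        if data.get("simulate") is not None:
            sim_dict = dict(data["simulate"])
            sim_dict.setdefault("seed", data["seed"])
            sim = SimulationConfig.from_dict(sim_dict)
        if sim is None and not inputs:
            raise ValidationError("config needs either 'inputs' or a 'simulate' block")
        return cls(seed=int(data["seed"]), output_dir=Path(data["output_dir"]),
                   stages=stages, thresholds=thresholds, inputs=inputs,
                   simulate=sim)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _config_hash(config: RunConfig) -> str:
    payload = {
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": config.thresholds,
        "inputs": {k: str(v) for k, v in sorted(config.inputs.items())},
        "simulate": config.simulate.to_dict() if config.simulate else None,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also on disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    try:
        ctx = _load_or_simulate_inputs(config, out, manifest)
        for stage in STAGES:
            if stage not in config.stages:
                continue
            runner = globals()[f"_stage_{stage}"]
            manifest["stages"][stage] = runner(ctx, config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    if "truth" in ctx:
        (out / "truth.json").write_text(
            json.dumps(ctx["truth"], indent=2, sort_keys=True))
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_or_simulate_inputs(config: RunConfig, out: Path, manifest: dict) -> dict:
    from . import synthetic_data as sim

    inputs = config.inputs
    annotation = (
        read_family_annotation(inputs["family"])
        if "family" in inputs
        else load_bundled_family_annotation()
    )
    ctx: dict = {"annotation": annotation}
    if config.simulate is not None:
        sim_dir = out / "simulated"
        sim_dir.mkdir(exist_ok=True)
        mutations, mut_truth = sim.simulate_mutations(annotation, config.simulate)
        matrix, expr_truth = sim.simulate_expression(annotation, config.simulate)
        write_result_table(mutations, sim_dir / "mutations.tsv")
        write_expression(matrix, sim_dir / "fpkm.tsv", sim_dir / "sample_meta.tsv")
        truth = {"mutations": mut_truth.to_dict(), "expression": expr_truth.to_dict()}
        ctx.update(mutations=mutations, matrix=matrix, truth=truth,
                   sim_config=config.simulate, sim_dir=sim_dir)
        manifest["simulated"] = {"n_mutations": len(mutations),
                                 "n_genes": matrix.n_genes,
                                 "n_samples": len(matrix.samples)}
    else:
        if "maf" in inputs:
            ctx["mutations"] = read_maf_like(inputs["maf"])
        if "fpkm" in inputs and "meta" in inputs:
            ctx["matrix"] = read_expression(inputs["fpkm"], inputs["meta"])
        if "clinical" in inputs:
            ctx["clinical"] = read_clinical(inputs["clinical"])
        if "features" in inputs:
            ctx["features"] = read_feature_table(inputs["features"])
    return ctx


def _stage_mutations(ctx: dict, config: RunConfig, out: Path) -> dict:
    from . import mutation_enrichment as me

    mutations = ctx["mutations"]
    annotation = ctx["annotation"]
    sub_rows, dom_rows = [], []
    for cancer in sorted(mutations["cancer"].unique()):
        sub_rows.extend(me.subtype_mutation_frequency(mutations, annotation, cancer))
        dom_rows.extend(me.domain_mutation_frequency(mutations, annotation, cancer))
    enrichment = me.prioritize_enriched_domains(mutations, annotation)
    impact = me.compare_impact_scores(mutations, annotation)
    tally = me.residue_mutation_tally(mutations, annotation)
    write_result_table(sub_rows, out / "subtype_freq.tsv")
    write_result_table(dom_rows, out / "domain_freq.tsv")
    write_result_table(enrichment, out / "domain_enrichment.tsv")
    write_result_table(impact, out / "impact_comparison.tsv")
    write_result_table(tally, out / "residue_tally.tsv")
    return {"subtype_rows": len(sub_rows), "domain_rows": len(dom_rows),
            "enrichment_rows": len(enrichment), "impact_rows": len(impact),
            "tally_rows": len(tally)}


def _stage_express(ctx: dict, config: RunConfig, out: Path) -> dict:
    from . import expression_analysis as ea

    processed = ea.preprocess_expression(ctx["matrix"])
    ctx["processed"] = processed
    de = ea.differential_expression(processed, ctx["annotation"])
    write_result_table(de, out / "de_results.tsv")
    co_rows, pair_frames = [], []
    for cancer in sorted(processed.sample_meta["cancer"].unique()):
        try:
            summary = ea.subclass_coexpression(processed, ctx["annotation"], cancer)
        except ValueError as exc:
            logger.info("coexpression skipped for %s: %s", cancer, exc)
            continue
        co_rows.append({"cancer": cancer,
                        "n_within": len(summary.within_scc),
                        "n_between": len(summary.between_scc),
                        "comparison_p": summary.comparison_p,
                        "n_strong_pairs": len(summary.strong_pairs)})
        if len(summary.strong_pairs):
            pair_frames.append(summary.strong_pairs.assign(cancer=cancer))
    write_result_table(pd.DataFrame(co_rows), out / "coexpression_summary.tsv")
    pairs = (pd.concat(pair_frames, ignore_index=True) if pair_frames
             else pd.DataFrame(columns=["gene1", "gene2", "pair_class", "scc",
                                        "p_value", "padj", "cancer"]))
    write_result_table(pairs, out / "coexpression_pairs.tsv")
    return {"de_rows": len(de), "coexpression_cancers": len(co_rows),
            "strong_pairs": len(pairs), "n_genes": processed.n_genes}


def _stage_score(ctx: dict, config: RunConfig, out: Path) -> dict:
    from . import expression_analysis as ea
    from . import family_score as fs

    processed = ctx.get("processed") or ea.preprocess_expression(ctx["matrix"])
    ctx["processed"] = processed
    annotation: FamilyAnnotation = ctx["annotation"]
    gene_set = GeneSet("FAMILY", frozenset(annotation.genes))
    scores = fs.score_cohort(processed, gene_set,
                             alpha=config.thresholds["alpha"])
    scores = fs.dichotomize_scores(scores, method="median")
    ctx["scores"] = scores
    table = pd.DataFrame({"es": scores.scores, "group": scores.groups})
    table.index.name = "sample"
    write_result_table(table.reset_index(), out / "scores.tsv")
    return {"n_samples": len(scores.scores),
            "n_high": int((scores.groups == "high").sum())}


def _stage_immune(ctx: dict, config: RunConfig, out: Path) -> dict:
    from . import immune_association as ia
    from . import synthetic_data as sim

    scores = ctx["scores"]
    if "features" not in ctx and ctx.get("sim_config") is not None:
        features, truth = sim.simulate_immune_features(scores, ctx["sim_config"])
        ctx["features"] = features
        ctx.setdefault("truth", {})["immune"] = truth.to_dict()
        write_result_table(features.reset_index(),
                           ctx["sim_dir"] / "immune_features.tsv")
    features = ctx["features"]
    categories = load_bundled_immune_regulators()
    corr = ia.correlate_score_with_features(scores, features, categories)
    comp = ia.compare_feature_groups(features, scores.groups)
    write_result_table(corr, out / "immune_correlation.tsv")
    write_result_table(comp, out / "immune_group_comparison.tsv")
    return {"n_features": len(corr)}


def _stage_clinical(ctx: dict, config: RunConfig, out: Path) -> dict:
    from . import clinical_endpoints as ce
    from . import synthetic_data as sim

    scores = ctx["scores"]
    if "clinical" not in ctx and ctx.get("sim_config") is not None:
        clinical, truth = sim.simulate_clinical(scores, ctx["sim_config"])
        ctx["clinical"] = clinical
        ctx.setdefault("truth", {})["clinical"] = truth.to_dict()
        write_result_table(clinical.reset_index(), ctx["sim_dir"] / "clinical.tsv")
    clinical = ctx["clinical"]
    meta = ctx["processed"].sample_meta
    roc_rows = []
    if set(meta["status"]) == {"tumor", "normal"}:
        shared = scores.scores.index.intersection(meta.index)
        roc = ce.roc_auc(scores.scores.loc[shared], meta.loc[shared, "status"])
        roc.curve.to_csv(out / "roc_curve.tsv", sep="\t", index=False)
        roc_rows.append({"cancer": "all", "auc": roc.auc,
                         "n_pos": roc.n_pos, "n_neg": roc.n_neg})
    write_result_table(pd.DataFrame(roc_rows), out / "roc.tsv")

    surv_rows = []
    tumor_meta = meta.loc[meta["status"] == "tumor"]
    for cancer in sorted(tumor_meta["cancer"].unique()):
        samples = tumor_meta.index[tumor_meta["cancer"] == cancer]
        samples = scores.scores.index.intersection(samples).intersection(clinical.index)
        if len(samples) < 10:
            continue
        try:
            assoc = ce.survival_association(
                scores.scores.loc[samples], clinical.loc[samples],
                minprop=config.thresholds["minprop"])
        except ValueError as exc:
            logger.info("survival association skipped for %s: %s", cancer, exc)
            continue
        surv_rows.append({"cancer": cancer, **assoc.__dict__})
    write_result_table(pd.DataFrame(surv_rows), out / "survival_association.tsv")

    km_frames, resp_rows = [], []
    shared = scores.scores.index.intersection(clinical.index)
    groups = scores.groups.loc[shared]
    km = ce.km_estimate(clinical.loc[shared, "time"],
                        clinical.loc[shared, "event"], groups)
    km_frames.append(km)
    write_result_table(pd.concat(km_frames, ignore_index=True), out / "km_curves.tsv")
    if (clinical.loc[shared, "response"] != "NA").any():
        resp = ce.response_association(groups, clinical.loc[shared, "response"])
        resp_rows.append({"fisher_p": resp.fisher_p,
                          "definition": resp.responder_definition})
    write_result_table(pd.DataFrame(resp_rows), out / "response_association.tsv")
    return {"survival_rows": len(surv_rows), "roc_rows": len(roc_rows),
            "response_rows": len(resp_rows)}
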