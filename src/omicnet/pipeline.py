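"""Config-driven orchestration of the full analysis.

`run_pipeline` takes a configuration (dict or YAML path) and executes the
requested stages in dependency order, writing per-stage TSV/JSON artifacts and
a manifest (config echo, config hash, seeds, input checksums). A ``simulate``
stanza makes the run fully self-contained; otherwise protein/metabolite/
metadata paths must be given. Identical config + seeds give identical
artifacts (manifests differ only in timestamp).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import TaskSpec, run_task
from .cohort import cohort_table
from .correlation import concordance_table, group_mean_zscores, spearman_by_subgroup
from .differential import differential_features
from .diffusion import rwr, top_n_features
from .enrichment import AnnotationCollection, fisher_enrichment
from .io import (
    SampleMetadata,
    SmokingMode,
    encode_design,
    load_feature_table,
    merge_omics,
    preprocess_metabolites,
    preprocess_proteins,
)
from .network import infer_network
from .simulate import SyntheticConfig, PlantedEffect, generate_cohort

STAGES = ("preprocess", "differential", "correlate", "enrich",
          "network", "diffuse", "classify", "cohort_table")
_DEPENDS = {"diffuse": "network"}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def run_pipeline(config, outdir: str | Path) -> dict:
    """Run the requested stages; returns {stage: artifact paths}.

    config keys: ``simulate`` (SyntheticConfig fields, with ``planted`` given
    as [feature_id, [groups...], target_d] triples) or ``paths``
    (proteins/metabolites/metadata TSVs); ``stages`` (subset of STAGES, in any
    order); ``seed``; optional stage-specific blocks ``differential``,
    ``network``, ``diffusion``, ``classify``, ``enrichment``.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for st in stages:
        dep = _DEPENDS.get(st)
        if dep and dep not in stages:
            raise ValueError(f"stage {st!r} requires stage {dep!r}; run it first")

    artifacts: dict[str, dict] = {}

    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        planted = tuple(
            PlantedEffect(fid, tuple(groups), float(d))
            for fid, groups, d in sim.pop("planted", [])
        )
        prot, met, meta, truth = generate_cohort(
            SyntheticConfig(planted=planted, **sim)
        )
        truth.to_json(outdir / "ground_truth.json")
        artifacts["simulate"] = {"ground_truth": str(outdir / "ground_truth.json")}
    elif "paths" in cfg:
        paths = cfg["paths"]
        prot = load_feature_table(paths["proteins"], "protein",
                                  exclusion_list=paths.get("exclusions"))
        met = load_feature_table(paths["metabolites"], "metabolite")
        meta = SampleMetadata.from_tsv(paths["metadata"])
    else:
        raise ValueError("config needs either a 'simulate' stanza or 'paths'")

    # preprocessing is upstream of everything downstream
    pcfg = cfg.get("preprocess", {})
    met_ready, qc_report = preprocess_metabolites(
        met,
        max_missing_frac=pcfg.get("max_missing_frac", 0.20),
        log=pcfg.get("log_metabolites", True),
    )
    log_prot = pcfg.get("log_proteins", True)
    prot_ready = preprocess_proteins(prot, log=log_prot)
    merged = merge_omics(prot_ready, met_ready)
    if "preprocess" in stages:
        (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        merged.to_tsv(outdir / "merged_abundances.tsv")
        artifacts["preprocess"] = {
            "qc_report": str(outdir / "qc_report.json"),
            "merged": str(outdir / "merged_abundances.tsv"),
        }

    if "differential" in stages:
        dcfg = cfg.get("differential", {})
        frames = [
            differential_features(
                merged, meta, comp,
                p_thr=dcfg.get("p_thr", 0.01), d_thr=dcfg.get("d_thr", 0.5),
            )
            for comp in ("ACPA_NEG_vs_CTRL", "ACPA_POS_vs_CTRL")
        ]
        diff = pd.concat(frames, ignore_index=True)
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        artifacts["differential"] = {"results": str(outdir / "differential.tsv")}

    if "correlate" in stages:
        tabs = []
        for marker in ("ESR", "CRP", "DAS28CRP"):
            corr = spearman_by_subgroup(merged, meta, marker)
            tabs.append(corr)
            concordance_table(corr).to_csv(
                outdir / f"concordance_{marker}.tsv", sep="\t", index=False
            )
        pd.concat(tabs, ignore_index=True).to_csv(
            outdir / "correlations.tsv", sep="\t", index=False
        )
        group_mean_zscores(merged, meta).to_csv(
            outdir / "group_mean_zscores.tsv", sep="\t"
        )
        artifacts["correlate"] = {"correlations": str(outdir / "correlations.tsv")}

    if "enrich" in stages:
        ecfg = cfg.get("enrichment", {})
        if "annotations" not in ecfg:
            raise ValueError("enrich stage needs enrichment.annotations (TSV path)")
        ann = AnnotationCollection.from_tsv(ecfg["annotations"])
        if "differential" not in artifacts:
            raise ValueError("stage 'enrich' requires stage 'differential'; "
                             "run it first")
        diff = pd.read_csv(artifacts["differential"]["results"], sep="\t")
        hits = set(diff.loc[diff["passes_relaxed"], "feature_id"])
        universe = set(merged.feature_ids)
        res = fisher_enrichment(hits & universe, universe, ann,
                                mode=ecfg.get("mode", "standard"))
        res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        artifacts["enrich"] = {"results": str(outdir / "enrichment.tsv")}

    network = None
    if "network" in stages:
        ncfg = cfg.get("network", {})
        design = encode_design(
            meta, include={"sex", "age", "bmi", "smoking", "meds", "phenotype"},
            smoking_mode=SmokingMode.UNKNOWN_LEVEL,
        )
        design = design.loc[:, design.nunique() > 1]
        network = infer_network(merged, design, seed=seed,
                                merge_rule=ncfg.get("merge_rule", "union"))
        network.to_tsv(outdir / "network_edges.tsv")
        artifacts["network"] = {"edges": str(outdir / "network_edges.tsv")}

    if "diffuse" in stages:
        dcfg = cfg.get("diffusion", {})
        seeds = [n for n in network.nodes if n.startswith("group_")]
        ranking = rwr(network, seeds, r=dcfg.get("restart", 0.5),
                      tol=dcfg.get("tol", 1e-4))
        ranking.scores.rename("score").to_csv(outdir / "rwr_scores.tsv", sep="\t")
        sub = top_n_features(network, ranking, dcfg.get("top_n", 50))
        pd.DataFrame(sub.edges, columns=["node_u", "node_v"]).to_csv(
            outdir / "subnetwork_edges.tsv", sep="\t", index=False
        )
        artifacts["diffuse"] = {
            "scores": str(outdir / "rwr_scores.tsv"),
            "subnetwork": str(outdir / "subnetwork_edges.tsv"),
        }

    if "classify" in stages:
        ccfg = cfg.get("classify", {})
        specs = ccfg.get("tasks", [{}])
        summaries = {}
        for i, kw in enumerate(specs):
            spec = TaskSpec(cv_seed=seed, **kw)
            result = run_task(prot, met_ready, meta, spec, log_proteins=log_prot)
            key = f"{spec.task}_{spec.modality}_{spec.selector}"
            result.per_fold.to_csv(outdir / f"cv_{key}.tsv", sep="\t", index=False)
            summaries[key] = {
                "best_n": result.best_n if result.best_n is not None else "all",
                "mean_auc": result.mean_auc(),
                "summary": {
                    m: {"mean": row["mean"], "sd": row["sd"]}
                    for m, row in result.summary.iterrows()
                },
            }
        (outdir / "classification_summary.json").write_text(
            json.dumps(summaries, indent=1, default=float)
        )
        artifacts["classify"] = {
            "summary": str(outdir / "classification_summary.json")
        }

    if "cohort_table" in stages:
        table = cohort_table(meta)
        table.to_csv(outdir / "cohort_table.tsv", sep="\t", index=False)
        artifacts["cohort_table"] = {"table": str(outdir / "cohort_table.tsv")}

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "artifacts": artifacts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    artifacts["manifest"] = {"path": str(outdir / "manifest.json")}
    return artifacts
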