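"""End-to-end pipeline orchestration with a manifest and seed registry.

All randomness flows from the config seed, fanned out deterministically
per stage via ``numpy.random.SeedSequence``; identical config + seed gives
byte-identical numeric outputs.  Stage outputs are plain TSV/CSV/JSON so
every number is diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cmt, diff_abundance, diversity, prediction, topics
from .config import AnalysisConfig
from .count_matrix import (CountMatrix, agglomerate, filter_samples,
                           filter_taxa, read_count_table, write_count_table)
from .simulate import GeneratorParams, generate_cohort, write_cohort

log = logging.getLogger("vagitopics")

_STAGE_NAMES = ["filter", "diversity", "cmt", "topics", "diff_abundance",
                "associations", "prediction"]


@dataclass
class PipelineRun:
    """Record of one pipeline execution: outputs, seeds, config hash."""

    outdir: Path
    config: AnalysisConfig
    manifest: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path):
        self.manifest.setdefault(stage, []).append(str(path))


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seeds(root_seed: int) -> dict:
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(_STAGE_NAMES) + 1)
    seeds = {name: int(child.generate_state(1)[0] % (2 ** 31 - 1))
             for name, child in zip(["simulate"] + _STAGE_NAMES, children)}
    return seeds


def make_fixtures(seed: int = 0, outdir="fixtures", params: GeneratorParams | None = None):
    """Write the default synthetic cohort (counts TSV, metadata CSV, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or GeneratorParams(seed=seed)
    cohort = generate_cohort(params)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    write_cohort(cohort, paths["counts"], paths["metadata"], paths["truth"])
    return paths


def run_pipeline(config: AnalysisConfig, outdir="pipeline_out") -> PipelineRun:
    """Execute filter -> diversity -> CMT -> topics -> DA -> associations ->
    prediction, writing each stage's outputs plus a summary and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(outdir=outdir, config=config)
    run.seeds = _stage_seeds(config.seed)
    chash = _config_hash(config)
    stages = config.stages

    def _fail(stage, err):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # ---- input ----
    if config.simulate or config.counts_path is None:
        params = GeneratorParams(seed=run.seeds["simulate"],
                                 n_topics=config.n_topics)
        cohort = generate_cohort(params)
        cm = cohort.cm
        write_cohort(cohort, outdir / "counts.tsv", outdir / "metadata.csv",
                     outdir / "truth.json")
        run.record("input", outdir / "counts.tsv")
        run.record("input", outdir / "metadata.csv")
    else:
        cm = read_count_table(config.counts_path, config.metadata_path)

    # ---- filter ----
    if stages.get("filter", True):
        try:
            cm = filter_samples(cm, config.min_sample_reads)
            cm = filter_taxa(cm, config.taxon_min_count, config.taxon_min_prevalence)
            cm = agglomerate(cm, config.agglomeration_rank)
        except Exception as err:
            _fail("filter", err)
        write_count_table(cm, outdir / "filtered_counts.tsv")
        run.record("filter", outdir / "filtered_counts.tsv")
        run.summary["n_taxa"] = cm.n_taxa
        run.summary["n_samples"] = cm.n_samples
    clinical = cm.metadata
    fever = clinical["fever_status"].astype(int)

    # ---- diversity ----
    if stages.get("diversity", True):
        try:
            alpha = diversity.alpha_diversity_table(cm)
            d = diversity.dissimilarity_matrix(cm, metric="bray_curtis")
            ord_res = diversity.nmds(d, k=2, seed=run.seeds["diversity"])
            stat, p = diversity.alpha_group_test(alpha["shannon"], fever)
        except Exception as err:
            _fail("diversity", err)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        with open(outdir / "nmds.tsv", "w") as fh:
            fh.write(f"# stress = {ord_res.stress:.6f}\n")
            ord_res.coordinates.to_csv(fh, sep="\t")
        run.record("diversity", outdir / "alpha_diversity.tsv")
        run.record("diversity", outdir / "nmds.tsv")
        run.summary["nmds_stress"] = round(ord_res.stress, 6)
        run.summary["shannon_fever_p"] = round(p, 6)

    # ---- CMT ----
    if stages.get("cmt", True):
        try:
            assignment = cmt.refine_cmt(cm, k=config.n_cmt, alpha=config.cmt_alpha,
                                        method=config.cmt_linkage)
            chi2, p_cmt = cmt.cmt_outcome_test(assignment.labels, fever,
                                               seed=run.seeds["cmt"])
        except Exception as err:
            _fail("cmt", err)
        assignment.labels.to_frame().to_csv(outdir / "cmt_labels.csv")
        assignment.kw_table.to_csv(outdir / "cmt_kw_selection.tsv", sep="\t")
        run.record("cmt", outdir / "cmt_labels.csv")
        run.record("cmt", outdir / "cmt_kw_selection.tsv")
        run.summary["cmt_fever_p"] = round(p_cmt, 6)
        run.summary["n_selected_taxa"] = int(len(assignment.selected_taxa))
    else:
        assignment = None

    # ---- topics ----
    if stages.get("topics", True):
        try:
            K = config.n_topics
            if config.select_k:
                sel = topics.select_k_elbow(cm, range(config.k_min, config.k_max + 1),
                                            seed=run.seeds["topics"])
                sel.curve.to_csv(outdir / "k_selection.tsv", sep="\t", index=False)
                run.record("topics", outdir / "k_selection.tsv")
                K = sel.k
            gom = topics.fit_gom(cm, K, seed=run.seeds["topics"])
        except Exception as err:
            _fail("topics", err)
        gom.omega.to_csv(outdir / "omega.tsv", sep="\t")
        gom.theta.to_csv(outdir / "theta.tsv", sep="\t")
        gom.zscore().to_csv(outdir / "theta_zscore.tsv", sep="\t")
        for name in ("omega.tsv", "theta.tsv", "theta_zscore.tsv"):
            run.record("topics", outdir / name)
        run.summary["n_topics"] = int(K)
        run.summary["gom_loglik"] = round(gom.loglik, 2)
    else:
        gom = None

    # ---- differential abundance ----
    if stages.get("diff_abundance", True):
        try:
            res_unadj = diff_abundance.nb_wald_test(cm, fever)
            covs = {"site": clinical["site"].to_numpy()}
            if assignment is not None:
                covs["cmt"] = assignment.labels.to_numpy()
            res_adj = diff_abundance.nb_wald_test(cm, fever, covariates=covs)
        except Exception as err:
            _fail("diff_abundance", err)
        for res, name in ((res_unadj, "da_unadjusted.tsv"), (res_adj, "da_adjusted.tsv")):
            tab = res.table.copy()
            tab["class"] = diff_abundance.volcano_classify(res)
            tab.to_csv(outdir / name, sep="\t")
            run.record("diff_abundance", outdir / name)
        run.summary["da_bonferroni_hits"] = int(
            (res_unadj.table["p_bonferroni"] < 0.05).sum())

    # ---- associations ----
    if stages.get("associations", True) and gom is not None:
        try:
            scan = association.topic_clinical_scan(gom, clinical)
        except Exception as err:
            _fail("associations", err)
        scan.to_csv(outdir / "topic_clinical_scan.tsv", sep="\t", index=False)
        run.record("associations", outdir / "topic_clinical_scan.tsv")
        run.summary["scan_min_p_adjusted"] = round(float(scan["p_adjusted"].min()), 6)

    # ---- prediction ----
    if stages.get("prediction", True) and gom is not None and assignment is not None:
        try:
            ft = prediction.build_feature_table(clinical, gom, assignment)
            reports = {}
            for fs in ("all", "clinical", "microbial"):
                reports[fs] = prediction.rf_resample_evaluate(
                    ft, fs, n_rounds=config.rf_rounds,
                    n_train=min(config.n_train, cm.n_samples - config.n_test),
                    n_test=config.n_test,
                    rf_params={"n_estimators": config.rf_trees},
                    seed=run.seeds["prediction"])
        except Exception as err:
            _fail("prediction", err)
        with open(outdir / "prediction.json", "w") as fh:
            json.dump({fs: r.to_dict() for fs, r in reports.items()}, fh, indent=1)
        prediction.feature_importance_report(reports["all"]).to_csv(
            outdir / "feature_importances.tsv", sep="\t")
        run.record("prediction", outdir / "prediction.json")
        run.record("prediction", outdir / "feature_importances.tsv")
        for fs, r in reports.items():
            run.summary[f"auc_{fs}"] = round(r.mean_auc, 4)

    # ---- manifest + summary ----
    manifest = {
        "config_hash": chash,
        "seeds": run.seeds,
        "stages": run.manifest,
        "config": config.to_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(run.summary, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s stages -> %s", len(run.manifest), outdir)
    return run
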