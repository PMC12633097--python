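"""End-to-end orchestration from a structured config.

Stages run in method order — simulate/ingest -> preprocess -> TAMPOR ->
regression -> network -> associations -> enrichment -> preservation — each
writing its artifact (TSV/JSON) plus parameters and derived seeds, and the
run finishes with a machine-readable report of counts.  Unknown config keys
are rejected before any computation; a fixed root seed makes the whole run
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .association import (me_trait_association, proteomewide_scan,
                          protein_trait_bicor)
from .datatypes import AbundanceMatrix, SampleManifest
from .enrichment import fisher_set_enrichment, permutation_module_enrichment
from .network import NetworkParams, build_network
from .preprocess import filter_missing, log2_transform, pca_outlier_flag, sum_scale
from .preservation import module_preservation
from .regress import RegressionSpec, bootstrap_regress, variance_explained
from .synthio import SynthConfig, TraitLink, generate_dataset
from .tampor import tampor_correct

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "tampor", "regress", "network",
          "associate", "enrich", "preserve")


@dataclass
class ScanSpec:
    outcome: str
    model: str = "linear"
    covariates: list[str] = field(default_factory=list)
    adjust: str = "bonferroni"


@dataclass
class RunConfig:
    """Whole-pipeline configuration; defaults are the reference analysis
    parameters (power 8, deepSplit 3, min size 10, merge height 0.07, mean
    TOM denominator, kME rules 0.10/0.30/30, 10,000 enrichment and 500
    preservation permutations, 1000 bootstrap fits)."""

    seed: int = 0
    outdir: str = "vascnet_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs: simulated unless an abundance/manifest pair is given
    abundance_path: str | None = None
    manifest_path: str | None = None
    gmt_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    max_missing_frac: float = 0.5
    pca_components: int = 2
    pca_sd_threshold: float = 4.0
    remove_outliers: bool = True
    use_all_non_gis: bool = False
    tampor_tol: float = 1e-8
    tampor_max_iterations: int = 250
    regression: RegressionSpec = field(default_factory=RegressionSpec)
    network: NetworkParams = field(default_factory=NetworkParams)
    me_traits: list[str] = field(default_factory=lambda: [
        "caa_severity", "cerad", "braak", "apoe4", "wmh",
        "microbleeds", "infarcts"])
    scans: list[ScanSpec] = field(default_factory=lambda: [
        ScanSpec("caa_severity", "ordinal", ["age", "sex"], "bonferroni"),
        ScanSpec("microbleeds", "logistic", ["age", "sex"], "BH"),
        ScanSpec("wmh", "linear", ["age", "sex"], "BH"),
    ])
    enrich_trait: str = "caa_severity"
    enrich_n_perm: int = 10000
    enrich_transform: str = "neglog10p"
    preserve_target: str = "self"      # "self" or a TSV path
    preserve_n_perm: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(dc_cls, data, ctx):
            names = {f.name: f for f in dataclasses.fields(dc_cls)}
            unknown = set(data) - set(names)
            if unknown:
                raise ValueError(f"unknown config keys in {ctx}: {sorted(unknown)}")
            kwargs = {}
            for k, v in data.items():
                ftype = names[k].type
                if k == "synth" and isinstance(v, dict):
                    if "trait_links" in v:
                        v = dict(v)
                        v["trait_links"] = [TraitLink(**tl) for tl in v["trait_links"]]
                    kwargs[k] = build(SynthConfig, v, "synth")
                elif k == "regression" and isinstance(v, dict):
                    kwargs[k] = build(RegressionSpec, v, "regression")
                elif k == "network" and isinstance(v, dict):
                    kwargs[k] = build(NetworkParams, v, "network")
                elif k == "scans":
                    kwargs[k] = [build(ScanSpec, s, "scans") for s in v]
                else:
                    kwargs[k] = v
            return dc_cls(**kwargs)

        return build(cls, raw, "top level")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31 so stages can be rerun
    in isolation."""
    h = np.random.SeedSequence([root_seed, STAGES.index(stage)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the machine-readable run
    report (also written to <outdir>/run_report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {},
                    "parameters": {"network": dataclasses.asdict(config.network),
                                   "regression": dataclasses.asdict(config.regression)}}
    truth = None

    # ---- input -----------------------------------------------------------
    if "simulate" in config.stages and config.abundance_path is None:
        synth = dataclasses.replace(config.synth,
                                    seed=stage_seed(config.seed, "simulate"))
        X, manifest, truth = generate_dataset(synth)
        vio.write_abundance(X, outdir / "abundance_raw.tsv")
        vio.write_manifest(manifest, outdir / "manifest.tsv")
        vio.write_json(truth.to_jsonable(), outdir / "truth.json")
        report["stages"]["simulate"] = {
            "seed": synth.seed, "n_proteins": X.n_proteins,
            "n_samples": int((~manifest.is_gis).sum()),
            "n_gis": int(manifest.is_gis.sum())}
    else:
        X = vio.read_abundance(config.abundance_path)
        manifest = vio.read_manifest(config.manifest_path)
        report["stages"]["ingest"] = {"n_proteins": X.n_proteins,
                                      "n_samples": X.n_samples}

    # ---- preprocess ------------------------------------------------------
    if "preprocess" in config.stages:
        n0 = X.n_proteins
        X = sum_scale(X)
        X = filter_missing(X, config.max_missing_frac)
        X = log2_transform(X)
        outliers = pca_outlier_flag(X, config.pca_components,
                                    config.pca_sd_threshold)
        if config.remove_outliers and outliers:
            keep = [s for s in X.sample_ids if s not in set(outliers)]
            X = X.subset_samples(keep)
        vio.write_abundance(X, outdir / "abundance_log2.tsv")
        report["stages"]["preprocess"] = {
            "proteins_in": n0, "proteins_out": X.n_proteins,
            "outliers_flagged": outliers,
            "outliers_removed": bool(config.remove_outliers)}

    # ---- TAMPOR ----------------------------------------------------------
    if "tampor" in config.stages:
        X, state = tampor_correct(X, manifest,
                                  use_all_non_gis=config.use_all_non_gis,
                                  tol=config.tampor_tol,
                                  max_iterations=config.tampor_max_iterations)
        vio.write_abundance(X, outdir / "abundance_tampor.tsv")
        report["stages"]["tampor"] = {
            "iterations": state.iteration, "converged": state.converged,
            "dropped_proteins": len(state.dropped_proteins),
            "use_all_non_gis": config.use_all_non_gis}

    # ---- regression ------------------------------------------------------
    if "regress" in config.stages:
        # GIS channels are technical standards, not analysis samples; TAMPOR
        # drops them, but the toggle-free path must too
        gis = manifest.table.reindex(X.sample_ids)["is_gis"].fillna(False)
        if gis.any():
            X = X.subset_samples(X.sample_ids[~gis.to_numpy()])
        spec = dataclasses.replace(config.regression,
                                   seed=stage_seed(config.seed, "regress"))
        ve_before = variance_explained(X, manifest, ["batch"])
        X = bootstrap_regress(X, manifest, spec)
        ve_after = variance_explained(X, manifest, ["batch"])
        vio.write_abundance(X, outdir / "abundance_regressed.tsv")
        report["stages"]["regress"] = {
            "seed": spec.seed, "n_bootstrap": spec.n_bootstrap,
            "covariates_removed": spec.covariates_to_remove,
            "median_batch_r2_before": float(ve_before["batch"].median()),
            "median_batch_r2_after": float(ve_after["batch"].median())}

    # ---- network ---------------------------------------------------------
    net = None
    if "network" in config.stages:
        net = build_network(X, config.network)
        vio.write_labels(net.labels, outdir / "module_labels.tsv")
        net.eigenproteins.to_csv(outdir / "eigenproteins.tsv", sep="\t")
        net.kme.to_csv(outdir / "kme.tsv", sep="\t")
        sizes = net.module_sizes
        report["stages"]["network"] = {
            "n_modules": int(len(sizes)), "n_grey": int((net.labels == 0).sum()),
            "module_sizes": {f"M{m}": int(s) for m, s in sizes.items()},
            "reassign_iterations": net.reassign_iterations,
            "reassign_converged": net.reassign_converged}

    # ---- associations ----------------------------------------------------
    scan_results: dict[str, pd.DataFrame] = {}
    if "associate" in config.stages and net is not None:
        traits = [t for t in config.me_traits if t in manifest.table.columns]
        me_assoc = me_trait_association(net.eigenproteins, manifest, traits)
        me_assoc.to_csv(outdir / "me_trait_association.tsv", sep="\t", index=False)
        stats = {}
        for spec in config.scans:
            res = proteomewide_scan(X, manifest, spec.outcome, spec.model,
                                    spec.covariates, spec.adjust)
            res.to_csv(outdir / f"scan_{spec.outcome}_{spec.model}.tsv",
                       sep="\t", index=False)
            scan_results[spec.outcome] = res
            stats[spec.outcome] = {
                "model": spec.model, "n_tested": res.attrs["n_tested"],
                "n_significant_adj": int((res["p_adj"] < 0.05).sum()),
                "bonferroni_cutoff": res.attrs["bonferroni_cutoff"]}
        bic = protein_trait_bicor(X, manifest, config.enrich_trait)
        bic.to_csv(outdir / f"bicor_{config.enrich_trait}.tsv", sep="\t",
                   index=False)
        report["stages"]["associate"] = {
            "me_significant": int((me_assoc["p"] < 0.05).sum()),
            "scans": stats,
            "bicor_positive_significant": bic.attrs["n_positive_significant"],
            "bicor_negative_significant": bic.attrs["n_negative_significant"]}

    # ---- enrichment ------------------------------------------------------
    if "enrich" in config.stages and net is not None and scan_results:
        outcome = config.enrich_trait
        if outcome not in scan_results:
            outcome = next(iter(scan_results))
        res = scan_results[outcome]
        gene_stats = pd.Series(res["p"].to_numpy(), index=res["id"])
        enr = permutation_module_enrichment(
            gene_stats, net.labels, n_perm=config.enrich_n_perm,
            transform=config.enrich_transform,
            seed=stage_seed(config.seed, "enrich"))
        enr.to_csv(outdir / "module_enrichment.tsv", sep="\t", index=False)
        entry = {"trait": outcome, "n_perm": config.enrich_n_perm,
                 "n_modules_fdr10": int((enr["p_fdr"] <= 0.10).sum())}
        if config.gmt_path:
            sets = vio.read_gmt(config.gmt_path)
            fish = fisher_set_enrichment(net.labels, sets)
            fish.to_csv(outdir / "fisher_enrichment.tsv", sep="\t", index=False)
            entry["fisher_sets"] = len(sets)
        report["stages"]["enrich"] = entry

    # ---- preservation ----------------------------------------------------
    if "preserve" in config.stages and net is not None:
        if config.preserve_target == "self":
            test = X
        else:
            test = vio.read_abundance(config.preserve_target,
                                      scale_tag=X.scale_tag)
        pres = module_preservation(X, test, net.labels,
                                   n_perm=config.preserve_n_perm,
                                   seed=stage_seed(config.seed, "preserve"))
        pres.to_csv(outdir / "module_preservation.tsv", sep="\t", index=False)
        report["stages"]["preserve"] = {
            "target": config.preserve_target, "n_perm": config.preserve_n_perm,
            "classification": dict(zip(
                (f"M{m}" for m in pres["module"]), pres["classification"]))}

    vio.write_json(report, outdir / "run_report.json")
    return report
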