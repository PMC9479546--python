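"""End-to-end orchestration: simulate -> deg -> enrich -> network -> qpcr -> stats.

Stages communicate only through documented files in the output directory, so
each stage can be re-run individually and inspected with any TSV tooling.
A JSON manifest records the resolved configuration, the seed, SHA-256
digests of every output and per-stage wall status; identical config + seed
reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import SampleDesign
from .diffexpr import (
    CROSS_SEX_CONTRASTS,
    Contrast,
    build_contrast_scheme,
    compute_fpkm,
    run_all_contrasts,
)
from .enrich import hypergeom_enrich
from .groupstats import compound_log2fc, duncan_mrt, duncan_table, one_way_anova
from .netcore import (
    NetParams,
    assemble_candidates,
    build_graph,
    node_degree,
    pearson_edges,
    rms_lfc,
    select_hubs,
)
from .qpcr import delta_delta_ct, platform_concordance, stage_log2fc
from .synthdata import SimConfig, simulate_annotation, simulate_compounds, simulate_counts, simulate_ct
from . import ioforms

log = logging.getLogger("floranet")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def sim_config_from_dict(cfg: dict, seed: int) -> SimConfig:
    """Build a SimConfig from the flat run configuration."""
    kwargs = {}
    for key in ("n_genes", "replicates_per_stage", "dispersion", "n_pathways",
                "annotated_fraction", "latent_wobble_sd"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return SimConfig(seed=seed, **kwargs)


def net_params_from_dict(cfg: dict) -> NetParams:
    return NetParams(
        r_min=cfg.get("r_min", 0.8),
        alpha_edge=cfg.get("alpha_edge", 0.05),
        degree_quantile=cfg.get("degree_quantile", 0.60),
        score_quantile=cfg.get("score_quantile", 0.60),
    )


def _truth_json(truth) -> dict:
    return {
        "de_genes": {c: dict(sorted(genes.items())) for c, genes in truth.de_genes.items()},
        "hub_features": sorted(truth.hub_features),
        "background_features": sorted(truth.background_features),
        "latent_profiles": truth.latent_profiles,
        "linked_analytes": sorted(truth.linked_analytes),
        "pathway_of_contrast": dict(sorted(truth.pathway_of_contrast.items())),
    }


def stage_simulate(cfg: dict, out: Path, seed: int) -> list[str]:
    sim = sim_config_from_dict(cfg, seed)
    counts, truth = simulate_counts(sim)
    design = sim.design()
    compounds = simulate_compounds(sim, truth)
    annotation = simulate_annotation(sim, truth)
    fpkm = compute_fpkm(counts)

    # qPCR panel: strongly planted, decently expressed genes (the study
    # validated high-fold-change genes across comparisons)
    planted = {}
    for contrast, genes in truth.de_genes.items():
        for gene, lfc in genes.items():
            planted[gene] = max(abs(lfc), planted.get(gene, 0.0))
    mean_counts = counts.counts.mean(axis=1)
    eligible = [g for g, a in sorted(planted.items(), key=lambda kv: -kv[1])
                if abs(a) >= 2.0 and mean_counts[g] >= 100]
    qpcr_genes = eligible[: cfg.get("n_qpcr_genes", 15)]
    ct = simulate_ct(fpkm, sim, qpcr_genes, reference_gene=cfg.get("reference_gene", "ZaUBQ"))

    ioforms.write_counts(counts, out / "counts.tsv")
    ioforms.write_design(design, out / "design.tsv")
    ioforms.write_compounds(compounds, out / "compounds.tsv")
    ioforms.write_annotation(annotation, out / "annotation.tsv")
    ioforms.write_ct(ct, out / "ct.tsv")
    ioforms.write_json(_truth_json(truth), out / "truth.json")
    (out / "candidates.txt").write_text("\n".join(truth.candidate_features) + "\n",
                                        newline="\n")
    log.info("simulate: %d genes, %d samples, %d analytes, %d qPCR genes",
             sim.n_genes, len(design.sample_ids), len(compounds.analytes), len(qpcr_genes))
    return ["counts.tsv", "design.tsv", "compounds.tsv", "annotation.tsv", "ct.tsv",
            "truth.json", "candidates.txt"]


def stage_deg(cfg: dict, out: Path) -> list[str]:
    counts = ioforms.read_counts(out / "counts.tsv")
    design = ioforms.read_design(out / "design.tsv")
    design.cross_validate_samples(counts.sample_ids)
    fpkm = compute_fpkm(counts)
    scheme = build_contrast_scheme(design)
    results = run_all_contrasts(
        fpkm, scheme,
        epsilon=cfg.get("epsilon", 1.0),
        lfc_min=cfg.get("lfc_min", 1.0),
        alpha=cfg.get("alpha", 0.05),
    )
    written = []
    for name, result in results.items():
        path = out / f"deg_{name}.tsv"
        ioforms.write_contrast_result(result, path)
        written.append(path.name)
        log.info("deg %s: %d up, %d down", name, result.n_up, result.n_down)
    return written


def stage_enrich(cfg: dict, out: Path) -> list[str]:
    annotation_path = out / "annotation.tsv"
    if not annotation_path.exists():
        raise PipelineError(f"enrich: annotation file {annotation_path} not found")
    annotation = ioforms.read_annotation(annotation_path)
    written = []
    for deg_path in sorted(out.glob("deg_*.tsv")):
        contrast = deg_path.stem[len("deg_"):]
        table = pd.read_csv(deg_path, sep="\t")
        up = set(table.loc[table["call"] == "up", "gene"])
        rows = hypergeom_enrich(up, annotation, alpha=cfg.get("enrich_alpha", 0.05))
        path = out / f"enrichment_{contrast}.tsv"
        rows.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        written.append(path.name)
    return written


def stage_network(cfg: dict, out: Path) -> list[str]:
    counts = ioforms.read_counts(out / "counts.tsv")
    design = ioforms.read_design(out / "design.tsv")
    compounds = ioforms.read_compounds(out / "compounds.tsv")
    candidates = [line.strip() for line in (out / "candidates.txt").read_text().splitlines()
                  if line.strip()]
    fpkm = compute_fpkm(counts)
    features = assemble_candidates(fpkm, compounds, candidates)
    params = net_params_from_dict(cfg)
    edges = pearson_edges(features, params)

    scheme = {c.name: c for c in build_contrast_scheme(design)}
    lfc_tables = {}
    for name in ("M3vsF3", "M4vsF4"):
        deg = pd.read_csv(out / f"deg_{name}.tsv", sep="\t").set_index("gene")
        lfc_tables[name] = deg["log2FC"]
    compound_lfc = {
        name: compound_log2fc(compounds, design, scheme[name]) for name in ("M3vsF3", "M4vsF4")
    }
    scores = {}
    for fid in features.feature_ids:
        if features.kinds[fid] == "gene":
            scores[fid] = rms_lfc(lfc_tables["M3vsF3"][fid], lfc_tables["M4vsF4"][fid])
        else:
            scores[fid] = rms_lfc(compound_lfc["M3vsF3"][fid], compound_lfc["M4vsF4"][fid])
    hub_table = select_hubs(features, edges, pd.Series(scores), params)
    graph = build_graph(features, edges, hub_table)
    ioforms.export_network(graph, out / "network.sif", "sif")
    ioforms.export_network(graph, out / "network.graphml", "graphml")
    ioforms.write_hub_table(hub_table, out / "hubs.tsv")
    log.info("network: %d candidates, %d edges, %d hubs",
             len(candidates), len(edges), int(hub_table["is_hub"].sum()))
    return ["network.sif", "network.graphml", "hubs.tsv"]


def stage_qpcr(cfg: dict, out: Path) -> list[str]:
    ct = ioforms.read_ct(out / "ct.tsv")
    design = ioforms.read_design(out / "design.tsv")
    rel = delta_delta_ct(ct)
    rq = rel.rq.reset_index().rename(columns={"index": "sample"})
    rq.to_csv(out / "qpcr_rq.tsv", sep="\t", index=False, float_format="%.6g",
              lineterminator="\n")

    scheme = build_contrast_scheme(design)
    pairs_q, pairs_r = [], []
    for contrast in scheme:
        deg = pd.read_csv(out / f"deg_{contrast.name}.tsv", sep="\t").set_index("gene")
        qlfc = stage_log2fc(rel, design, contrast)
        for gene in rel.rq.columns:
            if gene in deg.index:
                pairs_q.append(float(qlfc[gene]))
                pairs_r.append(float(deg.loc[gene, "log2FC"]))
    r, r2 = platform_concordance(pairs_q, pairs_r)
    summary = pd.DataFrame([{"n_pairs": len(pairs_q), "pearson_r": r, "r_squared": r2}])
    summary.to_csv(out / "qpcr_concordance.tsv", sep="\t", index=False,
                   float_format="%.6g", lineterminator="\n")
    log.info("qpcr: %d (gene, contrast) pairs, R^2 = %.4f", len(pairs_q), r2)
    return ["qpcr_rq.tsv", "qpcr_concordance.tsv"]


def stage_stats(cfg: dict, out: Path) -> list[str]:
    compounds = ioforms.read_compounds(out / "compounds.tsv")
    design = ioforms.read_design(out / "design.tsv")
    written = []
    anova_rows = []
    for analyte in compounds.analytes:
        groups = compounds.stage_values(analyte, design)
        thin = [s for s, v in groups.items() if len(v) < 2]
        if thin:
            log.warning("stats: %s skipped (stage(s) %s have <2 values)", analyte, thin)
            continue
        anova = one_way_anova(groups)
        anova_rows.append({"analyte": analyte, "F": anova.f, "p": anova.p,
                           "MSE": anova.mse, "df_error": anova.df_error})
        result = duncan_mrt(groups, alpha=cfg.get("alpha", 0.05), analyte=analyte)
        path = out / f"duncan_{analyte.replace('/', '_')}.tsv"
        duncan_table(result).to_csv(path, sep="\t", index=False, float_format="%.6g",
                                    lineterminator="\n")
        written.append(path.name)
    pd.DataFrame(anova_rows).to_csv(out / "anova_summary.tsv", sep="\t", index=False,
                                    float_format="%.6g", lineterminator="\n")
    written.append("anova_summary.tsv")
    return written


STAGES = ("simulate", "deg", "enrich", "network", "qpcr", "stats")


def run_all(config: dict, out_dir, seed: int = 0) -> dict:
    """Run every stage and write the manifest; fail-fast with stage named."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.get("enrich", True) and not config.get("simulate", True):
        if "annotation" not in config and not (out / "annotation.tsv").exists():
            raise PipelineError("enrich enabled but no annotation path configured")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dict(sorted(config.items())),
        "stages": {},
        "outputs": {},
    }
    for stage_name in STAGES:
        if not config.get(stage_name.replace("-", "_"), True):
            manifest["stages"][stage_name] = {"status": "skipped"}
            continue
        runner = {
            "simulate": lambda: stage_simulate(config, out, seed),
            "deg": lambda: stage_deg(config, out),
            "enrich": lambda: stage_enrich(config, out),
            "network": lambda: stage_network(config, out),
            "qpcr": lambda: stage_qpcr(config, out),
            "stats": lambda: stage_stats(config, out),
        }[stage_name]
        started = time.perf_counter()
        try:
            files = runner()
        except Exception as exc:
            manifest["stages"][stage_name] = {"status": "failed", "error": str(exc)}
            ioforms.write_json(manifest, out / "manifest.json")
            raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc
        manifest["stages"][stage_name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - started, 3),
            "files": files,
        }
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    tmp = out / "manifest.json.tmp"
    ioforms.write_json(manifest, tmp)
    tmp.replace(out / "manifest.json")  # atomic rewrite
    return manifest
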