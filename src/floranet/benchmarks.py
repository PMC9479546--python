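"""Synthetic-truth recovery benchmarks.

Each benchmark simulates data with planted structure, runs the corresponding
analysis stage, and scores recovery against the recorded ground truth. They
are used by the test suite and the reproduction script; problem sizes are
arguments so callers can trade runtime for precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import build_contrast_scheme, compute_fpkm, log2_fold_change, run_contrast
from .netcore import NetParams, assemble_candidates, pearson_edges, rms_lfc, select_hubs
from .qpcr import delta_delta_ct, platform_concordance, stage_log2fc
from .synthdata import CtModel, DESpec, HubSpec, SimConfig, simulate_counts, simulate_ct


def de_recovery(
    n_seeds: int = 20,
    n_genes: int = 5000,
    base_seed: int = 0,
    contrast: str = "M3vsM1",
    planted_fraction: float = 0.05,
    lfc_low: float = 3.0,
    lfc_high: float = 4.0,
    min_base_mean: float = 100.0,
) -> dict[str, float]:
    """Sensitivity / sign accuracy for strongly planted genes and the false
    call rate on null genes, averaged over seeds.

    Sensitivity counts a planted gene (|planted lfc| >= 3, observed mean
    count >= ``min_base_mean``) as recovered only when it is called in the
    planted direction. Null genes are all genes without a planted effect;
    a "false call" is any up/down call on them.
    """
    sens, null_rates, abs_err = [], [], []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes,
            de_spec=(DESpec(contrast, planted_fraction, lfc_low, lfc_high),),
            hub_spec=HubSpec(0, 0.9, 0),
            seed=base_seed + i,
        )
        counts, truth = simulate_counts(cfg)
        fpkm = compute_fpkm(counts)
        scheme = {c.name: c for c in build_contrast_scheme(cfg.design())}
        result = run_contrast(fpkm, scheme[contrast])
        planted = truth.de_genes[contrast]
        used = list(scheme[contrast].group_a + scheme[contrast].group_b)
        mean_counts = counts.counts[used].mean(axis=1)
        strong = [g for g, lfc in planted.items()
                  if abs(lfc) >= 3.0 and mean_counts[g] >= min_base_mean]
        calls = result.table["call"]
        recovered = sum(
            1 for g in strong
            if calls[g] == ("up" if planted[g] > 0 else "down")
        )
        sens.append(recovered / len(strong) if strong else np.nan)
        nulls = result.table.index.difference(list(planted))
        null_rates.append(float((calls[nulls] != "ns").mean()))
        est = result.table["log2FC"]
        if strong:
            abs_err.append(float(np.mean([abs(est[g] - planted[g]) for g in strong])))
    return {
        "sensitivity": float(np.nanmean(sens)),
        "null_call_rate": float(np.mean(null_rates)),
        "mean_abs_lfc_error": float(np.mean(abs_err)) if abs_err else float("nan"),
        "n_seeds": n_seeds,
        "n_genes": n_genes,
    }


def hub_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_hubs: int = 10,
    n_background: int = 90,
    loading: float = 0.9,
    params: NetParams | None = None,
) -> dict[str, float]:
    """Precision/recall of the composite hub rule on planted hub blocks.

    Each replicate simulates ``n_hubs`` latent-driven hub genes (planted
    cross-sex |lfc| >= 2) among ``n_background`` independent null genes, all
    treated as network candidates, and applies the default pipeline:
    edges -> degrees -> RMS lfc -> composite selection.
    """
    if params is None:
        params = NetParams()
    precisions, recalls = [], []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_hubs + n_background,
            de_spec=(),
            hub_spec=HubSpec(n_hubs, loading, n_background),
            seed=base_seed + i,
        )
        counts, truth = simulate_counts(cfg)
        fpkm = compute_fpkm(counts)
        scheme = {c.name: c for c in build_contrast_scheme(cfg.design())}
        candidates = sorted(truth.hub_features) + sorted(truth.background_features)
        features = assemble_candidates(fpkm, None, candidates)
        edges = pearson_edges(features, params)
        lfc1 = log2_fold_change(fpkm, scheme["M3vsF3"])
        lfc2 = log2_fold_change(fpkm, scheme["M4vsF4"])
        scores = pd.Series({f: rms_lfc(lfc1[f], lfc2[f]) for f in features.feature_ids})
        table = select_hubs(features, edges, scores, params)
        selected = set(table.loc[table["is_hub"], "feature"])
        tp = len(selected & truth.hub_features)
        precisions.append(tp / len(selected) if selected else 0.0)
        recalls.append(tp / n_hubs)
    return {
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "n_seeds": n_seeds,
        "n_features": n_hubs + n_background,
    }


def qpcr_concordance_benchmark(
    seed: int = 0,
    sigma_ct: float = 0.2,
    n_genes: int = 2000,
    n_panel: int = 15,
) -> dict[str, float]:
    """R^2 between qPCR-recovered and planted log2 fold changes.

    Simulates a study, picks up to ``n_panel`` strongly planted,
    well-expressed genes (the usual validation panel), generates Ct tables
    at the given noise level and scores platform concordance over all
    contrasts against the planted truth.
    """
    cfg = SimConfig(n_genes=n_genes, seed=seed,
                    ct_model=CtModel(sigma_ct=sigma_ct))
    counts, truth = simulate_counts(cfg)
    fpkm = compute_fpkm(counts)
    design = cfg.design()
    scheme = build_contrast_scheme(design)
    strength: dict[str, float] = {}
    for genes in truth.de_genes.values():
        for g, lfc in genes.items():
            strength[g] = max(abs(lfc), strength.get(g, 0.0))
    mean_counts = counts.counts.mean(axis=1)
    panel = [g for g, a in sorted(strength.items(), key=lambda kv: -kv[1])
             if a >= 2.0 and mean_counts[g] >= 100][:n_panel]
    ct = simulate_ct(fpkm, cfg, panel)
    rel = delta_delta_ct(ct)
    pairs_q, pairs_true = [], []
    for contrast in scheme:
        qlfc = stage_log2fc(rel, design, contrast)
        true_lfc = truth.true_lfc(contrast.name)
        for g in panel:
            pairs_q.append(float(qlfc[g]))
            pairs_true.append(float(true_lfc[g]))
    r, r2 = platform_concordance(pairs_q, pairs_true)
    return {"pearson_r": r, "r_squared": r2, "n_pairs": len(pairs_q),
            "n_panel_genes": len(panel)}
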