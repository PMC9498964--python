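"""End-to-end analysis workflows over synthetic study data.

Each function generates data at the study conditions (seeded), runs the
corresponding analysis module, and returns a dictionary of result tables
and headline metrics.  The numbered scripts under ``analysis/`` and the
acceptance script are thin drivers over these functions.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from . import screen, tracing
from .assays import bioenergetic_metrics, bli_burden, ddct_fold_change, nad_summary
from .enrichment import preranked_enrichment, rank_genes, volcano_table, pathway_overlay
from .pathways import GLYCOLYSIS_NODES
from .pca import delta_pc, fit_pca
from .simulate import (
    AssaySimConfig,
    ScreenSimConfig,
    TracingSimConfig,
    simulate_assays,
    simulate_expression,
    simulate_isotopologues,
    simulate_metastasis_counts,
    simulate_screen_counts,
    simulate_timecourse_counts,
)
from .stats import dunnett_vs_control, group_compare

MAIN_CLASSES = ("control", "glycolytic", "mito_respiratory")


def run_screen_analysis(seed: int = 0, context: str = "flank") -> dict[str, Any]:
    """Quantify representation for one in vivo context and compare classes."""
    cfg = ScreenSimConfig(context=context, seed=seed)
    table, annotation, truth = simulate_screen_counts(cfg)
    agg = screen.quantify(table, annotation, tumor_context=context)
    groups = {
        k: v for k, v in screen.macro_class_values(agg).items() if k in MAIN_CLASSES
    }
    comparison = group_compare(groups, method="anova_tukey")
    ranking = screen.rank_depletion(agg)
    return {
        "config": cfg,
        "aggregated": agg,
        "group_means": agg.group_means,
        "comparison": comparison,
        "ranking": ranking,
        "truth": truth,
    }


def run_timecourse_analysis(seed: int = 0) -> dict[str, Any]:
    cfg = ScreenSimConfig(seed=seed)
    table, annotation, truth = simulate_timecourse_counts(cfg)
    dynamics = screen.timepoint_dynamics(table, annotation, days=[4, 7])
    return {"dynamics": dynamics, "truth": truth}


def run_metastasis_analysis(seed: int = 0) -> dict[str, Any]:
    cfg = ScreenSimConfig(context="orthotopic_primary", seed=seed)
    table, annotation, pairs, truth = simulate_metastasis_counts(cfg)
    freq = screen.control_normalized_frequency(
        table, annotation, screen.default_pseudocount(table)
    )
    # mice carrying two metastases support cross-metastasis correlations
    corr_pairs = []
    by_primary: dict[str, list[str]] = {}
    for met, prim in pairs:
        by_primary.setdefault(prim, []).append(met)
    for mets in by_primary.values():
        if len(mets) >= 2:
            corr_pairs.append((mets[0], mets[1]))
    out = screen.metastasis_analysis(freq, annotation, pairs, correlation_pairs=corr_pairs)
    out["pairs"] = pairs
    out["truth"] = truth
    return out


def run_tracing_analysis(seed: int = 0) -> dict[str, Any]:
    """Correct isotopologues, summarize labeling, compute flux ratios."""
    cfg = TracingSimConfig(seed=seed)
    observed, truth = simulate_isotopologues(cfg)
    corrected = [tracing.correct_natural_abundance(v, cfg.p13) for v in observed]
    summaries = pd.DataFrame(
        [
            {
                "metabolite": v.metabolite.name,
                "genotype": v.genotype,
                "condition": v.condition,
                "replicate": v.replicate,
                "tracer": v.tracer,
                "relative_amount": s.relative_amount,
                "percent_labeled": s.percent_labeled,
            }
            for v in corrected
            for s in [tracing.summarize_tracing(v)]
        ]
    )
    ratios = tracing.flux_ratios_by_genotype([v for v in corrected if v.condition == "dg2"])
    ratio_values = {g: [r.ratio for r in rs] for g, rs in ratios.items()}
    dunnett = dunnett_vs_control(ratio_values, control="control")
    return {
        "config": cfg,
        "corrected": corrected,
        "summaries": summaries,
        "flux_ratios": ratio_values,
        "dunnett": dunnett,
        "truth": truth,
    }


def fractional_labeling_matrix(summaries: pd.DataFrame) -> pd.DataFrame:
    """Samples x metabolites matrix of percent labeled, from tracing summaries."""
    wide = summaries.pivot_table(
        index=["genotype", "condition", "replicate"],
        columns="metabolite",
        values="percent_labeled",
    )
    wide.index = [f"{g}_{c}_r{r}" for g, c, r in wide.index]
    return wide


def run_pca_analysis(seed: int = 0) -> dict[str, Any]:
    """PCA of the fractional-labeling matrix plus per-genotype shifts."""
    trace = run_tracing_analysis(seed)
    X = fractional_labeling_matrix(trace["summaries"])
    result = fit_pca(X, scaling="unit")
    labels = pd.DataFrame(
        [s.rsplit("_", 2) for s in X.index],
        index=X.index,
        columns=["genotype", "condition", "replicate"],
    )
    shifts = delta_pc(
        result, labels["genotype"], labels["condition"], control="basal", treatment="dg2"
    )
    return {"matrix": X, "pca": result, "shifts": shifts, "tracing": trace}


def run_enrichment_analysis(seed: int = 0, n_genes: int = 5000) -> dict[str, Any]:
    """Volcano, preranked enrichment, and glycolysis pathway overlay."""
    expression, sets = simulate_expression(n_genes=n_genes, seed=seed)
    ranked = rank_genes(expression)
    results = preranked_enrichment(
        ranked, sets, n_perm=1000, min_size=10, max_size=500, weight=1.0, seed=seed
    )
    volcano = volcano_table(expression)
    overlay = pathway_overlay(expression, None, GLYCOLYSIS_NODES)
    return {
        "expression": expression,
        "sets": sets,
        "ranked": ranked,
        "results": sorted(results, key=lambda r: r.p_value),
        "volcano": volcano,
        "overlay": overlay,
    }


def run_assay_analysis(seed: int = 0) -> dict[str, Any]:
    """Bioenergetic metrics, NAD, ddCT and BLI burden on simulated assays."""
    cfg = AssaySimConfig(noise_cv=0.05, seed=seed)
    traces, triplets = simulate_assays(cfg)
    metrics = bioenergetic_metrics(traces)
    rng = np.random.default_rng(seed + 1)
    nad = nad_summary(rng.normal(300, 15, 6), rng.normal(100, 5, 6))
    # a silenced line with ~60% knockdown: ddCT = log2(1/0.4)
    fold = ddct_fold_change(
        ct_target=[25.3, 25.4, 25.2],
        ct_reference_gene=[18.0, 18.1, 17.9],
        ct_target_control=[24.0, 24.1, 23.9],
        ct_reference_control=[18.0, 18.1, 17.9],
    )
    burden = pd.DataFrame(
        [
            {
                "mouse_id": t.mouse_id,
                "left": t.left_third,
                "central": t.central_third,
                "right": t.right_third,
                "central_over_left": t.central_over_left,
                "right_over_left": t.right_over_left,
            }
            for t in triplets
        ]
    )
    return {"config": cfg, "metrics": metrics, "nad": nad, "ddct_fold": fold, "bli": burden}
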