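"""Synthetic data generators with the statistical structure of the study.

Every generator is a pure function of (config, seed): the same inputs give
bit-identical outputs.  Each returns the ground truth it simulated from, so
the analysis modules can be checked by parameter recovery and null
calibration without any external data.

Screen counts: a ~400-guide CRISPRi library (one fifth nontargeting, 2-4
guides per target gene) drawn from a Dirichlet day-0 pool; engraftment is a
multinomial founder bottleneck, in vivo growth multiplies each guide's
abundance by its class fitness effect, and sequencing is negative-binomial
around frequency x read depth.

Isotopologues: true labeling simplexes convolved with natural 13C abundance
and multiplied by lognormal noise.  Expression: null genes with
Normal(0, sigma) log2 fold changes and z-derived p-values, signal gene sets
shifted by a configured effect.  Assays: phase-structured OCR/ECAR traces
with genotype-specific scaling, and chest-thirds radiance triplets with
configurable metastasis/primary ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assays import FluxTrace, RadianceTriplet
from .pathways import GLYCOLYSIS_GENES
from .enrichment import GeneSet
from .screen import CountTable, GuideAnnotation
from .tracing import IsotopologueVector, get_metabolite, convolve_natural_abundance, NATURAL_P13

__all__ = [
    "ScreenSimConfig",
    "simulate_screen_counts",
    "simulate_timecourse_counts",
    "simulate_metastasis_counts",
    "TracingSimConfig",
    "default_labeling_truth",
    "simulate_isotopologues",
    "simulate_expression",
    "AssaySimConfig",
    "simulate_assays",
]


# ---------------------------------------------------------------------------
# screen


#: in vivo fitness effects per macro class, per growth context — the
#: depletion structure the screen analysis is expected to recover
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "flank": {"control": 1.0, "glycolytic": 0.63, "mito_respiratory": 0.42, "other": 0.85},
    "orthotopic_primary": {"control": 1.0, "glycolytic": 0.72, "mito_respiratory": 0.48, "other": 0.85},
    # metastases are seeded from the primary; mito-respiratory knockdowns
    # are not additionally depleted there
    "metastasis": {"control": 1.0, "glycolytic": 1.0, "mito_respiratory": 1.0, "other": 1.0},
}

#: early-timepoint effects (day-d vs day-0): mito-respiratory guides
#: transiently enrich at day 4 before depleting by day 7
DEFAULT_DAY_EFFECTS: dict[int, dict[str, float]] = {
    4: {"control": 1.0, "glycolytic": 0.95, "mito_respiratory": 1.25, "other": 1.0},
    7: {"control": 1.0, "glycolytic": 0.90, "mito_respiratory": 0.70, "other": 0.95},
}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study-condition parameters for the pooled-screen generator."""

    n_guides: int = 400
    control_fraction: float = 0.2
    guides_per_gene: tuple[int, ...] = (2, 3, 4)
    #: proportions of the targeting guides per functional class
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "glycolytic": 0.30,
            "mito_protein_synthesis": 0.25,
            "respiratory_chain": 0.25,
            "other_mito": 0.20,
        }
    )
    read_depth: float = 1_000_000
    dispersion: float = 0.1
    dirichlet_concentration: float = 5.0
    context: str = "flank"
    effects: Mapping[str, float] | None = None  # macro class -> fitness effect
    founder_population: float = math.inf  # N_b founders at engraftment
    n_experiments: int = 2
    tumors_per_experiment: int = 6
    day0_replicates: int = 2
    day: int = 28
    seed: int = 0

    def resolved_effects(self) -> dict[str, float]:
        if self.effects is not None:
            eff = dict(self.effects)
        else:
            eff = dict(DEFAULT_EFFECTS[self.context])
        if any(e <= 0 for e in eff.values()):
            raise ValueError("fitness effects must be positive")
        return eff


def _build_library(config: ScreenSimConfig, rng: np.random.Generator) -> GuideAnnotation:
    n_controls = int(round(config.n_guides * config.control_fraction))
    props = dict(config.class_proportions)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    n_targeting = config.n_guides - n_controls

    rows = []
    for i in range(n_controls):
        rows.append({"guide_id": f"nt_{i:03d}", "target_gene": None, "functional_class": "nontargeting"})

    quotas = {cls: int(round(p * n_targeting)) for cls, p in props.items()}
    # rounding drift goes to the largest class
    drift = n_targeting - sum(quotas.values())
    quotas[max(quotas, key=quotas.get)] += drift

    gene_idx = 0
    cycle = 0
    for cls, quota in quotas.items():
        assigned = 0
        while assigned < quota:
            per_gene = min(config.guides_per_gene[cycle % len(config.guides_per_gene)], quota - assigned)
            gene = f"GENE{gene_idx:03d}_{cls[:4].upper()}"
            for g in range(per_gene):
                rows.append(
                    {"guide_id": f"sg_{gene}_{g}", "target_gene": gene, "functional_class": cls}
                )
            assigned += per_gene
            gene_idx += 1
            cycle += 1
    table = pd.DataFrame(rows).set_index("guide_id")
    return GuideAnnotation(table)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws via gamma-Poisson mixing; Poisson at dispersion 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _tumor_frequencies(
    rng: np.random.Generator,
    p0: np.ndarray,
    effect: np.ndarray,
    founder_population: float,
) -> np.ndarray:
    """Founder bottleneck then multiplicative in vivo growth."""
    if math.isinf(founder_population):
        q = p0
    else:
        founders = rng.multinomial(int(founder_population), p0)
        q = founders / founders.sum()
    w = q * effect
    return w / w.sum()


def simulate_screen_counts(
    config: ScreenSimConfig = ScreenSimConfig(),
) -> tuple[CountTable, GuideAnnotation, pd.DataFrame]:
    """Day-0 plus in vivo tumor counts with known per-guide fitness effects.

    Returns the count table, the guide annotation, and the truth table of
    per-guide effects (the quantity representation analysis should recover
    as class mean representation -> 100 x effect at high depth).
    """
    rng = np.random.default_rng(config.seed)
    annotation = _build_library(config, rng)
    n = len(annotation.guide_ids)
    effects_map = config.resolved_effects()
    effect = annotation.macro_class().map(effects_map).to_numpy(dtype=float)

    p0 = rng.dirichlet(np.full(n, config.dirichlet_concentration))

    counts: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    for r in range(config.day0_replicates):
        sid = f"day0_rep{r + 1}"
        counts[sid] = _nb_counts(rng, p0 * config.read_depth, config.dispersion)
        meta_rows[sid] = {
            "context": "in_vitro_day0", "site": "culture", "day": 0,
            "mouse_id": None, "experiment_id": f"exp{r % config.n_experiments + 1}",
            "matched_primary": None,
        }
    for e in range(config.n_experiments):
        for t in range(config.tumors_per_experiment):
            sid = f"{config.context}_e{e + 1}_m{t + 1}"
            p_tumor = _tumor_frequencies(rng, p0, effect, config.founder_population)
            counts[sid] = _nb_counts(rng, p_tumor * config.read_depth, config.dispersion)
            meta_rows[sid] = {
                "context": config.context, "site": config.context, "day": config.day,
                "mouse_id": f"e{e + 1}m{t + 1}", "experiment_id": f"exp{e + 1}",
                "matched_primary": None,
            }

    count_df = pd.DataFrame(counts, index=annotation.guide_ids).astype(np.int64)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").rename_axis("sample_id")
    truth = pd.DataFrame(
        {"macro_class": annotation.macro_class(), "effect": effect},
        index=annotation.guide_ids,
    )
    return CountTable(count_df, meta), annotation, truth


def simulate_timecourse_counts(
    config: ScreenSimConfig = ScreenSimConfig(),
    day_effects: Mapping[int, Mapping[str, float]] | None = None,
    replicates_per_day: Mapping[int, int] | None = None,
) -> tuple[CountTable, GuideAnnotation, pd.DataFrame]:
    """Early-timepoint flank samples (day 0 reference plus later days)."""
    rng = np.random.default_rng(config.seed)
    annotation = _build_library(config, rng)
    n = len(annotation.guide_ids)
    day_effects = dict(day_effects or DEFAULT_DAY_EFFECTS)
    replicates_per_day = dict(replicates_per_day or {4: 3, 7: 2})
    p0 = rng.dirichlet(np.full(n, config.dirichlet_concentration))

    counts: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    for r in range(3):
        sid = f"day0_rep{r + 1}"
        counts[sid] = _nb_counts(rng, p0 * config.read_depth, config.dispersion)
        meta_rows[sid] = {
            "context": "in_vitro_day0", "site": "culture", "day": 0,
            "mouse_id": None, "experiment_id": "tc", "matched_primary": None,
        }
    truth_rows = []
    for day, eff_map in day_effects.items():
        effect = annotation.macro_class().map(dict(eff_map)).to_numpy(dtype=float)
        truth_rows.append(pd.Series(effect, index=annotation.guide_ids, name=f"day{day}"))
        for r in range(replicates_per_day.get(day, 3)):
            sid = f"day{day}_m{r + 1}"
            p_tumor = _tumor_frequencies(rng, p0, effect, config.founder_population)
            counts[sid] = _nb_counts(rng, p_tumor * config.read_depth, config.dispersion)
            meta_rows[sid] = {
                "context": "flank", "site": "flank", "day": day,
                "mouse_id": f"tc_m{day}_{r + 1}", "experiment_id": "tc",
                "matched_primary": None,
            }
    count_df = pd.DataFrame(counts, index=annotation.guide_ids).astype(np.int64)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").rename_axis("sample_id")
    truth = pd.concat(truth_rows, axis=1)
    truth["macro_class"] = annotation.macro_class()
    return CountTable(count_df, meta), annotation, truth


def simulate_metastasis_counts(
    config: ScreenSimConfig = ScreenSimConfig(context="orthotopic_primary"),
    n_mice: int = 4,
    mets_per_mouse: Sequence[int] = (2, 2, 2, 1),
    met_founders: int = 200,
    met_effects: Mapping[str, float] | None = None,
) -> tuple[CountTable, GuideAnnotation, list[tuple[str, str]], pd.DataFrame]:
    """Matched primary tumors and their seeded metastases.

    Each metastasis is a chained founder bottleneck from its primary's guide
    frequencies (the spec's sequential-bottleneck option) followed by
    metastasis-context growth.  Returns the pairs list
    (metastasis sample, matched primary sample); mice with two metastases
    support the cross-metastasis class correlations.
    """
    rng = np.random.default_rng(config.seed)
    annotation = _build_library(config, rng)
    n = len(annotation.guide_ids)
    primary_effect = annotation.macro_class().map(config.resolved_effects()).to_numpy(dtype=float)
    met_effect = annotation.macro_class().map(
        dict(met_effects or DEFAULT_EFFECTS["metastasis"])
    ).to_numpy(dtype=float)
    p0 = rng.dirichlet(np.full(n, config.dirichlet_concentration))

    counts: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    pairs: list[tuple[str, str]] = []
    sites = ("contralateral_lung", "bone", "mediastinum")
    for m in range(n_mice):
        prim_id = f"primary_m{m + 1}"
        p_prim = _tumor_frequencies(rng, p0, primary_effect, config.founder_population)
        counts[prim_id] = _nb_counts(rng, p_prim * config.read_depth, config.dispersion)
        meta_rows[prim_id] = {
            "context": "orthotopic_primary", "site": "left_lung", "day": config.day,
            "mouse_id": f"m{m + 1}", "experiment_id": "mets", "matched_primary": None,
        }
        for k in range(mets_per_mouse[m % len(mets_per_mouse)]):
            met_id = f"met_m{m + 1}_{sites[k % len(sites)]}"
            p_met = _tumor_frequencies(rng, p_prim, met_effect, met_founders)
            counts[met_id] = _nb_counts(rng, p_met * config.read_depth, config.dispersion)
            meta_rows[met_id] = {
                "context": "metastasis", "site": sites[k % len(sites)], "day": config.day,
                "mouse_id": f"m{m + 1}", "experiment_id": "mets", "matched_primary": prim_id,
            }
            pairs.append((met_id, prim_id))
    count_df = pd.DataFrame(counts, index=annotation.guide_ids).astype(np.int64)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").rename_axis("sample_id")
    truth = pd.DataFrame(
        {"macro_class": annotation.macro_class(), "met_effect": met_effect},
        index=annotation.guide_ids,
    )
    return CountTable(count_df, meta), annotation, pairs, truth


# ---------------------------------------------------------------------------
# isotope tracing


def _simplex(**mass: float) -> dict[int, float]:
    total = sum(mass.values())
    return {k: v / total for k, v in mass.items()}


def default_labeling_truth() -> dict[tuple[str, str, str], dict[int, float]]:
    """True labeling simplexes per (metabolite, genotype, condition).

    Encodes the labeling structure the tracing analysis should see: TCA
    metabolites heavily glutamine-labeled at baseline (~85%), and
    mito-respiratory knockdown lines whose glycolytic-vs-respiratory
    label-incorporation ratio exceeds the control line's roughly four-fold.
    """
    truth: dict[tuple[str, str, str], dict[int, float]] = {}
    mito_lines = ("c14orf2", "MALSU1", "TMEM261")

    # F16BP, glucose tracer (6 carbons): mostly M0/M6 with minor partials
    truth[("F16BP", "control", "basal")] = _simplex(**{"0": 35, "3": 6, "6": 55, "1": 2, "5": 2})
    truth[("F16BP", "control", "dg2")] = _simplex(**{"0": 60, "3": 5, "6": 30, "1": 3, "5": 2})
    for g in mito_lines:
        truth[("F16BP", g, "basal")] = _simplex(**{"0": 32, "3": 6, "6": 56, "1": 3, "5": 3})
        truth[("F16BP", g, "dg2")] = _simplex(**{"0": 38, "3": 5, "6": 52, "1": 3, "5": 2})

    # glutamate, glutamine tracer (5 carbons): high baseline labeling
    truth[("glutamate", "control", "basal")] = _simplex(**{"0": 12, "2": 8, "3": 8, "5": 72})
    truth[("glutamate", "control", "dg2")] = _simplex(**{"0": 10, "2": 7, "3": 8, "5": 75})
    for g in mito_lines:
        truth[("glutamate", g, "basal")] = _simplex(**{"0": 25, "2": 8, "3": 9, "5": 58})
        truth[("glutamate", g, "dg2")] = _simplex(**{"0": 40, "2": 9, "3": 11, "5": 40})

    # a glutamine-labeled TCA intermediate with >=80% baseline labeling
    truth[("succinate", "control", "basal")] = _simplex(**{"0": 14, "2": 10, "4": 76})
    truth[("succinate", "control", "dg2")] = _simplex(**{"0": 20, "2": 12, "4": 68})
    for g in mito_lines:
        truth[("succinate", g, "basal")] = _simplex(**{"0": 18, "2": 11, "4": 71})
        truth[("succinate", g, "dg2")] = _simplex(**{"0": 45, "2": 15, "4": 40})
    return truth


@dataclass(frozen=True)
class TracingSimConfig:
    truth: Mapping[tuple[str, str, str], Mapping[int, float]] = field(
        default_factory=default_labeling_truth
    )
    p13: float = NATURAL_P13
    noise_cv: float = 0.05
    replicates: int = 4
    total_intensity: float = 1e6
    normalizer: float = 5e5  # cells per sample
    seed: int = 0


TRACER_OF_METABOLITE = {"F16BP": "U13C_glucose", "glutamate": "U13C_glutamine", "succinate": "U13C_glutamine"}


def simulate_isotopologues(
    config: TracingSimConfig = TracingSimConfig(),
) -> tuple[list[IsotopologueVector], dict[tuple[str, str, str, int], np.ndarray]]:
    """Observed isotopologue vectors: convolve truth with natural abundance,
    multiply by lognormal noise.  Truth (per-replicate true intensity
    vectors before convolution and noise) is returned for recovery tests."""
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    observed: list[IsotopologueVector] = []
    truth: dict[tuple[str, str, str, int], np.ndarray] = {}
    for (met_name, genotype, condition), simplex in config.truth.items():
        spec = get_metabolite(met_name)
        true = np.zeros(spec.n_carbons + 1)
        for k, frac in simplex.items():
            true[int(k)] = frac
        tracer = TRACER_OF_METABOLITE.get(met_name, "U13C_glucose")
        for rep in range(config.replicates):
            true_intensity = true * config.total_intensity
            obs = convolve_natural_abundance(true_intensity, config.p13)
            if sigma > 0:
                obs = obs * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=obs.size)
            observed.append(
                IsotopologueVector(
                    metabolite=spec,
                    intensities=obs,
                    tracer=tracer,
                    condition=condition,
                    genotype=genotype,
                    normalizer=config.normalizer,
                    replicate=rep,
                )
            )
            truth[(met_name, genotype, condition, rep)] = true_intensity
    return observed, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    n_genes: int = 5000,
    signal_sets: Mapping[str, float] | None = None,
    sigma: float = 0.5,
    n_decoy_sets: int = 20,
    decoy_size: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[GeneSet]]:
    """Per-gene (log2FC, p) table with a planted gene-set signal.

    Null genes draw log2FC ~ Normal(0, sigma); members of each signal set
    are shifted by ``effect`` (in units of sigma).  p-values come from the
    two-sided z test of log2FC / sigma, so under the null they are uniform.
    The default plants a +2 sigma overexpression signal on the canonical
    glycolysis genes.  Returns the table and the gene sets (signal + decoys)
    as GMT-ready objects.
    """
    if signal_sets is None:
        signal_sets = {"GLYCOLYSIS": 2.0}
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    # glycolysis symbols replace the head of the null universe when planted
    if "GLYCOLYSIS" in signal_sets:
        genes[: len(GLYCOLYSIS_GENES)] = GLYCOLYSIS_GENES
    log2fc = rng.normal(0.0, sigma, size=n_genes)

    sets: list[GeneSet] = []
    for set_id, effect in signal_sets.items():
        if set_id == "GLYCOLYSIS":
            members = list(GLYCOLYSIS_GENES)
        else:
            members = list(rng.choice(genes, size=decoy_size, replace=False))
        idx = [genes.index(m) for m in members]
        log2fc[idx] += effect * sigma
        sets.append(GeneSet(set_id, frozenset(members)))
    for d in range(n_decoy_sets):
        members = rng.choice(genes, size=decoy_size, replace=False)
        sets.append(GeneSet(f"DECOY_{d:02d}", frozenset(members)))

    p = 2.0 * stats.norm.sf(np.abs(log2fc) / sigma)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    table = pd.DataFrame({"log2fc": log2fc, "p": p}, index=pd.Index(genes, name="gene"))
    return table, sets


# ---------------------------------------------------------------------------
# assays


@dataclass(frozen=True)
class AssaySimConfig:
    #: per-genotype multiplicative scalings of mitochondrial OCR and ECAR
    genotype_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "control": {"ocr": 1.0, "ecar": 1.0},
            "c14orf2": {"ocr": 0.45, "ecar": 1.1},
            "MALSU1": {"ocr": 0.75, "ecar": 1.0},
            "TMEM261": {"ocr": 0.40, "ecar": 0.9},
        }
    )
    wells_per_genotype: int = 4
    n_experiments: int = 3
    cells_per_well: float = 30_000
    basal_ocr_per_cell: float = 1.0e-3  # arbitrary signal units per cell
    fccp_gain: float = 1.8
    nonmito_floor: float = 0.15  # fraction of control basal OCR
    basal_ecar_per_cell: float = 1.0e-3
    oligomycin_gain: float = 1.6
    noise_cv: float = 0.0
    #: radiance config: left third holds the primary tumor
    left_radiance: float = 1.0e6
    central_left_ratio: float = 0.2
    right_left_ratio: float = 0.1
    n_mice: int = 4
    day: int = 21
    seed: int = 0


def simulate_assays(
    config: AssaySimConfig = AssaySimConfig(),
) -> tuple[list[FluxTrace], list[RadianceTriplet]]:
    """Phase-structured OCR/ECAR traces and chest-thirds radiance triplets."""
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    def jitter() -> float:
        return rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0

    traces: list[FluxTrace] = []
    floor = config.nonmito_floor * config.basal_ocr_per_cell * config.cells_per_well
    for genotype, eff in config.genotype_effects.items():
        for e in range(config.n_experiments):
            for w in range(config.wells_per_genotype):
                cells = config.cells_per_well
                mito_basal = config.basal_ocr_per_cell * cells * eff["ocr"]
                traces.append(
                    FluxTrace(
                        well=f"{genotype}_ocr_e{e}_w{w}",
                        genotype=genotype,
                        modality="OCR",
                        phases={
                            "baseline": (mito_basal + floor) * jitter(),
                            "post_fccp": (config.fccp_gain * mito_basal + floor) * jitter(),
                            "post_rotenone": floor * jitter(),
                        },
                        cell_count=cells,
                    )
                )
                ecar_base = config.basal_ecar_per_cell * cells * eff["ecar"]
                traces.append(
                    FluxTrace(
                        well=f"{genotype}_ecar_e{e}_w{w}",
                        genotype=genotype,
                        modality="ECAR",
                        phases={
                            "baseline": ecar_base * jitter(),
                            "post_oligomycin": config.oligomycin_gain * ecar_base * jitter(),
                            "post_rotenone": 0.2 * ecar_base * jitter(),
                        },
                        cell_count=cells,
                    )
                )

    triplets = [
        RadianceTriplet(
            mouse_id=f"m{m + 1}",
            day=config.day,
            left_third=config.left_radiance * jitter(),
            central_third=config.left_radiance * config.central_left_ratio * jitter(),
            right_third=config.left_radiance * config.right_left_ratio * jitter(),
        )
        for m in range(config.n_mice)
    ]
    return traces, triplets
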