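"""Stable-isotope tracing: natural-abundance correction and label summaries.

Observed isotopologue distributions from a uniformly labeled 13C tracer are
contaminated by naturally occurring 13C (~1.07% per carbon): a molecule whose
tracer-derived labeling state is M_i can be *observed* at M_j (j >= i) when
j - i of its remaining n - i carbons happen to be naturally heavy.  The
forward model is a per-column binomial convolution; correction inverts it by
nonnegative least squares so that noisy data cannot produce negative
isotopologue intensities.

Downstream summaries: relative pool size (summed isotopologues per cell or
per ug protein), percent labeled (fraction of the pool carrying at least one
tracer carbon), and the glycolytic/respiratory flux-ratio statistic
(fully-labeled/unlabeled F16BP from a glucose tracer divided by
fully-labeled/unlabeled glutamate from a glutamine tracer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "NATURAL_P13",
    "MetaboliteSpec",
    "METABOLITES",
    "IsotopologueVector",
    "TracingSummary",
    "FluxRatio",
    "build_correction_matrix",
    "correct_natural_abundance",
    "summarize_tracing",
    "flux_ratio",
]

#: natural abundance of 13C per carbon atom
NATURAL_P13 = 0.0107

TRACERS = ("U13C_glucose", "U13C_glutamine", "U13C_pyruvate")
CONDITIONS = ("basal", "dg2", "oligomycin", "depletion")


@dataclass(frozen=True)
class MetaboliteSpec:
    name: str
    n_carbons: int
    pathway_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")


def _spec(name: str, n: int, *tags: str) -> MetaboliteSpec:
    return MetaboliteSpec(name, n, frozenset(tags))


#: carbon counts for the metabolites handled by the pipeline (versioned config)
METABOLITES: dict[str, MetaboliteSpec] = {
    s.name: s
    for s in [
        _spec("glucose", 6, "glycolysis"),
        _spec("G6P", 6, "glycolysis"),
        _spec("F16BP", 6, "glycolysis"),
        _spec("DHAP", 3, "glycolysis"),
        _spec("3PG", 3, "glycolysis"),
        _spec("PEP", 3, "glycolysis"),
        _spec("pyruvate", 3, "glycolysis"),
        _spec("lactate", 3, "glycolysis"),
        _spec("citrate", 6, "TCA"),
        _spec("aconitate", 6, "TCA"),
        _spec("aKG", 5, "TCA"),
        _spec("succinate", 4, "TCA"),
        _spec("fumarate", 4, "TCA"),
        _spec("malate", 4, "TCA"),
        _spec("oxaloacetate", 4, "TCA"),
        _spec("glutamate", 5, "TCA", "amino_acid"),
        _spec("glutamine", 5, "amino_acid"),
        _spec("aspartate", 4, "amino_acid"),
        _spec("acetyl_coa", 2, "TCA"),
    ]
}


def get_metabolite(name: str) -> MetaboliteSpec:
    try:
        return METABOLITES[name]
    except KeyError:
        raise KeyError(
            f"unknown metabolite {name!r}: add it to the carbon-count table"
        ) from None


@dataclass
class IsotopologueVector:
    """Intensities M_0..M_n for one metabolite in one sample."""

    metabolite: MetaboliteSpec
    intensities: np.ndarray
    tracer: str = "U13C_glucose"
    condition: str = "basal"
    genotype: str = "control"
    normalizer: float = 1.0  # cell count or ug protein
    replicate: int = 0
    corrected: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (self.metabolite.n_carbons + 1,):
            raise ValueError(
                f"{self.metabolite.name}: expected {self.metabolite.n_carbons + 1} "
                f"isotopologues, got {arr.shape[0]}"
            )
        if (arr < 0).any():
            raise ValueError("intensities must be nonnegative")
        self.intensities = arr

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass
class TracingSummary:
    relative_amount: float
    percent_labeled: float
    isotopologue_fractions: np.ndarray
    valid: bool = True


@dataclass
class FluxRatio:
    """Glycolytic-to-respiratory label-incorporation ratio, per replicate."""

    numerator: float  # M6/M0 of F16BP, glucose tracer
    denominator: float  # M5/M0 of glutamate, glutamine tracer
    ratio: float


# ---------------------------------------------------------------------------
# natural-abundance correction


def build_correction_matrix(n_carbons: int, p13: float = NATURAL_P13) -> np.ndarray:
    """Binomial convolution matrix C with C[j, i] = P(observe M_j | true M_i).

    A molecule in true state M_i has n - i tracer-free carbons, each
    independently heavy with probability ``p13``; observing M_j requires
    exactly j - i of them to be heavy.  Columns sum to 1.
    """
    if not 0.0 <= p13 < 1.0:
        raise ValueError("p13 must be in [0, 1)")
    n = int(n_carbons)
    C = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        k = np.arange(0, n - i + 1)
        C[i + k, i] = stats.binom.pmf(k, n - i, p13)
    return C


def correct_natural_abundance(
    vec: IsotopologueVector, p13: float = NATURAL_P13
) -> IsotopologueVector:
    """Remove the natural-13C contribution from an observed distribution.

    Solves observed = C @ true for true >= 0 by nonnegative least squares.
    When the observed vector lies in the image of C the correction is the
    exact inverse; with noise, NNLS keeps the solution physical.
    """
    obs = vec.intensities
    if obs.sum() == 0:
        logger.warning("all-zero isotopologue vector for %s", vec.metabolite.name)
        return replace(vec, intensities=obs.copy(), corrected=True)
    C = build_correction_matrix(vec.metabolite.n_carbons, p13)
    true, _ = optimize.nnls(C, obs)
    return replace(vec, intensities=true, corrected=True)


def convolve_natural_abundance(true: np.ndarray, p13: float = NATURAL_P13) -> np.ndarray:
    """Forward model: distribution observed for a known true labeling state."""
    true = np.asarray(true, dtype=float)
    return build_correction_matrix(true.size - 1, p13) @ true


# ---------------------------------------------------------------------------
# summaries


def summarize_tracing(vec: IsotopologueVector) -> TracingSummary:
    """Pool size, percent labeled and isotopologue fractions for one vector.

    relative_amount = sum of isotopologues / normalizer;
    percent_labeled = labeled signal (>= 1 tracer carbon) / total = 1 - f(M_0).
    """
    if vec.normalizer <= 0:
        raise ValueError("normalizer (cell count / protein) must be positive")
    total = vec.total
    if total == 0:
        logger.warning("zero total pool for %s; percent_labeled undefined", vec.metabolite.name)
        return TracingSummary(0.0, np.nan, np.zeros_like(vec.intensities), valid=False)
    fractions = vec.intensities / total
    return TracingSummary(
        relative_amount=total / vec.normalizer,
        percent_labeled=float(1.0 - fractions[0]),
        isotopologue_fractions=fractions,
    )


def flux_ratio(f16bp: IsotopologueVector, glu: IsotopologueVector) -> FluxRatio:
    """Glycolytic (M6/M0 F16BP, glucose tracer) over respiratory (M5/M0
    glutamate, glutamine tracer) label incorporation for one replicate pair.

    The statistic is invariant to a common rescaling of either vector.
    """
    if f16bp.metabolite.n_carbons != 6:
        raise ValueError("F16BP vector must have 6 carbons")
    if glu.metabolite.n_carbons != 5:
        raise ValueError("glutamate vector must have 5 carbons")
    if f16bp.tracer != "U13C_glucose" or glu.tracer != "U13C_glutamine":
        raise ValueError("flux ratio pairs a glucose-tracer F16BP with a glutamine-tracer glutamate")
    if f16bp.intensities[0] == 0 or glu.intensities[0] == 0:
        raise ValueError(
            "unlabeled (M0) intensity is zero; add a pseudo-intensity upstream "
            "or exclude the replicate"
        )
    num = f16bp.intensities[6] / f16bp.intensities[0]
    den = glu.intensities[5] / glu.intensities[0]
    if den == 0:
        raise ValueError("glutamate M5 is zero; respiratory flux term undefined")
    return FluxRatio(float(num), float(den), float(num / den))


def flux_ratios_by_genotype(
    vectors: Sequence[IsotopologueVector],
) -> dict[str, list[FluxRatio]]:
    """Pair F16BP/glutamate vectors by (genotype, replicate) and compute ratios."""
    keyed: dict[tuple[str, int], dict[str, IsotopologueVector]] = {}
    for v in vectors:
        if v.metabolite.name == "F16BP" and v.tracer == "U13C_glucose":
            keyed.setdefault((v.genotype, v.replicate), {})["f16bp"] = v
        elif v.metabolite.name == "glutamate" and v.tracer == "U13C_glutamine":
            keyed.setdefault((v.genotype, v.replicate), {})["glu"] = v
    out: dict[str, list[FluxRatio]] = {}
    for (genotype, _rep), pair in sorted(keyed.items()):
        if "f16bp" in pair and "glu" in pair:
            out.setdefault(genotype, []).append(flux_ratio(pair["f16bp"], pair["glu"]))
    return out
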