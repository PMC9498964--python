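"""Bioenergetic and tumor-burden readouts.

Extracellular-flux (Seahorse-style) traces are reduced to phase metrics:
an OCR run measures baseline, then FCCP-uncoupled, then rotenone-inhibited
oxygen consumption; an ECAR run measures baseline, then oligomycin-forced,
then rotenone-inhibited acidification.  Basal respiration is baseline minus
the rotenone (non-mitochondrial) floor, maximal is FCCP minus the floor,
spare capacity their difference; glycolytic reserve is the ECAR shift under
oligomycin.  All metrics are normalized per cell.

Also here: NAD+/NADH summaries from acid/non-acid plate fractions,
2^-ddCT qPCR fold changes, and chest-thirds bioluminescence burden ratios
(central/left and right/left radiance, the left third holding the primary
tumor in an orthotopic left-lung model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FluxTrace",
    "BioenergeticMetrics",
    "bioenergetic_metrics",
    "nad_summary",
    "ddct_fold_change",
    "bli_burden",
    "RadianceTriplet",
    "split_thirds",
]

OCR_PHASES = ("baseline", "post_fccp", "post_rotenone")
ECAR_PHASES = ("baseline", "post_oligomycin", "post_rotenone")


@dataclass
class FluxTrace:
    """Phase means for one well of an extracellular-flux run."""

    well: str
    genotype: str
    modality: str  # "OCR" or "ECAR"
    phases: dict[str, float]
    cell_count: float

    def __post_init__(self) -> None:
        if self.modality not in ("OCR", "ECAR"):
            raise ValueError(f"modality must be OCR or ECAR, got {self.modality!r}")
        if self.cell_count <= 0:
            raise ValueError(f"well {self.well}: cell_count must be positive")
        required = OCR_PHASES if self.modality == "OCR" else ECAR_PHASES
        for phase in required:
            if phase not in self.phases:
                raise ValueError(f"well {self.well}: missing phase {phase!r}")


@dataclass
class BioenergeticMetrics:
    genotype: str
    basal_respiration: float = np.nan
    maximal_respiration: float = np.nan
    spare_capacity: float = np.nan
    atp_linked_respiration: float = np.nan
    baseline_glycolysis: float = np.nan
    glycolytic_reserve: float = np.nan
    n_wells_ocr: int = 0
    n_wells_ecar: int = 0


def _per_cell(trace: FluxTrace, phase: str) -> float:
    return trace.phases[phase] / trace.cell_count


def bioenergetic_metrics(
    traces: Sequence[FluxTrace], subtract_nonmito: bool = True
) -> dict[str, BioenergeticMetrics]:
    """Derive per-genotype bioenergetic metrics from flux traces.

    With ``subtract_nonmito`` (default) the post-rotenone floor is removed
    from basal and maximal OCR — the field convention for isolating
    mitochondrial respiration; set False to report raw phase values.
    ATP-linked respiration needs an oligomycin phase in the OCR run and is
    NaN when absent.  Every value is per cell (well signal / cell count),
    averaged across a genotype's wells.
    """
    by_genotype: dict[str, dict[str, list[float]]] = {}
    for tr in traces:
        acc = by_genotype.setdefault(tr.genotype, {})
        if tr.modality == "OCR":
            floor = _per_cell(tr, "post_rotenone") if subtract_nonmito else 0.0
            acc.setdefault("basal", []).append(_per_cell(tr, "baseline") - floor)
            acc.setdefault("maximal", []).append(_per_cell(tr, "post_fccp") - floor)
            if "post_oligomycin" in tr.phases:
                acc.setdefault("atp_linked", []).append(
                    _per_cell(tr, "baseline") - _per_cell(tr, "post_oligomycin")
                )
            acc.setdefault("n_ocr", []).append(1.0)
        else:
            acc.setdefault("glycolysis", []).append(_per_cell(tr, "baseline"))
            acc.setdefault("reserve", []).append(
                _per_cell(tr, "post_oligomycin") - _per_cell(tr, "baseline")
            )
            acc.setdefault("n_ecar", []).append(1.0)

    out: dict[str, BioenergeticMetrics] = {}
    for genotype, acc in sorted(by_genotype.items()):
        basal = float(np.mean(acc["basal"])) if "basal" in acc else np.nan
        maximal = float(np.mean(acc["maximal"])) if "maximal" in acc else np.nan
        m = BioenergeticMetrics(
            genotype=genotype,
            basal_respiration=basal,
            maximal_respiration=maximal,
            spare_capacity=maximal - basal,
            atp_linked_respiration=float(np.mean(acc["atp_linked"])) if "atp_linked" in acc else np.nan,
            baseline_glycolysis=float(np.mean(acc["glycolysis"])) if "glycolysis" in acc else np.nan,
            glycolytic_reserve=float(np.mean(acc["reserve"])) if "reserve" in acc else np.nan,
            n_wells_ocr=len(acc.get("n_ocr", [])),
            n_wells_ecar=len(acc.get("n_ecar", [])),
        )
        if np.isfinite(maximal) and np.isfinite(basal) and maximal < basal:
            logger.warning("genotype %s: maximal OCR below basal; trace flagged", genotype)
        out[genotype] = m
    return out


def nad_summary(acid: Sequence[float], nonacid: Sequence[float]) -> pd.DataFrame:
    """Per-replicate NAD+/NADH ratio and pool from paired plate fractions.

    NAD+ survives the acid-treated fraction, NADH the non-acidified one.
    Replicates with NADH <= 0 are excluded with a warning; a summary row is
    appended with group means and SEM.
    """
    acid = np.asarray(acid, dtype=float)
    nonacid = np.asarray(nonacid, dtype=float)
    if acid.shape != nonacid.shape:
        raise ValueError("acid/nonacid fractions must be paired")
    keep = nonacid > 0
    if not keep.all():
        logger.warning("excluding %d replicate(s) with NADH <= 0", int((~keep).sum()))
    df = pd.DataFrame(
        {
            "nad_plus": acid[keep],
            "nadh": nonacid[keep],
            "ratio": acid[keep] / nonacid[keep],
            "pool": acid[keep] + nonacid[keep],
        }
    )
    df.attrs["mean"] = df.mean().to_dict()
    df.attrs["sem"] = df.sem(ddof=1).to_dict() if len(df) > 1 else {c: 0.0 for c in df}
    return df


def ddct_fold_change(
    ct_target: Sequence[float],
    ct_reference_gene: Sequence[float],
    ct_target_control: Sequence[float],
    ct_reference_control: Sequence[float],
) -> float:
    """2^-ddCT expression fold change of a target gene versus control cells.

    dCT = CT(target) - CT(reference gene, e.g. beta-actin), averaged over
    replicates in the sample and in the control line; ddCT is their
    difference and the fold change is 2 to the minus ddCT.
    """
    arrays = [np.asarray(a, dtype=float) for a in (ct_target, ct_reference_gene, ct_target_control, ct_reference_control)]
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValueError("CT values must be finite")
    dct_sample = arrays[0].mean() - arrays[1].mean()
    dct_control = arrays[2].mean() - arrays[3].mean()
    return float(2.0 ** -(dct_sample - dct_control))


@dataclass
class RadianceTriplet:
    """Chest-thirds radiance for one mouse on one day."""

    mouse_id: str
    day: int
    left_third: float
    central_third: float
    right_third: float
    central_over_left: float = np.nan
    right_over_left: float = np.nan

    def __post_init__(self) -> None:
        if min(self.left_third, self.central_third, self.right_third) < 0:
            raise ValueError("radiance must be nonnegative")
        if self.left_third > 0:
            self.central_over_left = self.central_third / self.left_third
            self.right_over_left = self.right_third / self.left_third
        else:
            logger.warning("mouse %s: left-third radiance is 0; ratios undefined", self.mouse_id)


def split_thirds(grid: np.ndarray) -> tuple[float, float, float]:
    """Sum a rectangular radiance grid over three equal-area column strips.

    Widths not divisible by 3 distribute the remainder columns left to
    right, so the partition is deterministic and conserves the total.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("expected a 2-D pixel grid")
    width = grid.shape[1]
    base, rem = divmod(width, 3)
    widths = [base + (1 if k < rem else 0) for k in range(3)]
    edges = np.cumsum([0, *widths])
    return tuple(float(grid[:, edges[k]:edges[k + 1]].sum()) for k in range(3))


def bli_burden(
    regions: np.ndarray | tuple[float, float, float],
    mouse_id: str = "",
    day: int = 0,
) -> RadianceTriplet:
    """Chest-thirds burden from either a pixel grid or three region sums.

    In the orthotopic left-lung model the left third contains the primary
    tumor; central/left and right/left ratios quantify mediastinal and
    contralateral-lung metastatic burden relative to it.
    """
    if isinstance(regions, np.ndarray) and regions.ndim == 2:
        left, central, right = split_thirds(regions)
    else:
        left, central, right = (float(v) for v in regions)
    return RadianceTriplet(mouse_id, day, left, central, right)
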