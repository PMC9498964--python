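"""Readers for the published supplementary data workbook.

The screen's source data ship as a multi-sheet XLSX workbook (read counts
per sgRNA for the in vitro and in vivo replicates, metabolomics
isotopologue and fractional-contribution sheets).  This module adapts those
sheets to the pipeline's in-memory types.  The workbook is not
redistributable with the package; place it at ``data/external/S1_Data.xlsx``
(or pass an explicit path) to run the published-data analyses.

Sheet layouts vary, so each loader takes explicit column roles: the guide-id
column, the functional-class column, which columns are pre-injection
reference replicates and which are tumors.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .screen import CountTable, GuideAnnotation, quantify

__all__ = ["DEFAULT_WORKBOOK", "load_screen_sheet", "screen_class_means", "load_feature_sheet"]

DEFAULT_WORKBOOK = Path("data/external/S1_Data.xlsx")

#: raw functional-class labels seen in screen annotation tables -> pipeline enum
CLASS_ALIASES = {
    "nontargeting": "nontargeting",
    "non-targeting": "nontargeting",
    "control": "nontargeting",
    "negative control": "nontargeting",
    "glycolytic": "glycolytic",
    "glycolysis": "glycolytic",
    "mito protein synth": "mito_protein_synthesis",
    "mitochondrial protein synthesis": "mito_protein_synthesis",
    "resp chain": "respiratory_chain",
    "respiratory chain": "respiratory_chain",
    "other mito": "other_mito",
    "other mitochondrial function": "other_mito",
}


def _normalize_class(label: str) -> str:
    key = str(label).strip().lower()
    if key not in CLASS_ALIASES:
        raise ValueError(f"unrecognized functional class label {label!r}")
    return CLASS_ALIASES[key]


def load_screen_sheet(
    workbook: str | Path,
    sheet: str | int,
    guide_col: str,
    class_col: str,
    reference_cols: Sequence[str],
    tumor_cols: Sequence[str],
    gene_col: str | None = None,
    experiment_of: dict[str, str] | None = None,
) -> tuple[CountTable, GuideAnnotation]:
    """Read one screen sheet of the workbook into pipeline types."""
    workbook = Path(workbook)
    if not workbook.exists():
        raise FileNotFoundError(
            f"supplementary workbook not found at {workbook}; download the "
            "published S1 Data file and place it there"
        )
    raw = pd.read_excel(workbook, sheet_name=sheet)
    raw = raw.set_index(guide_col)
    ann = pd.DataFrame(
        {
            "target_gene": raw[gene_col] if gene_col else None,
            "functional_class": raw[class_col].map(_normalize_class),
        },
        index=raw.index.rename("guide_id"),
    )
    annotation = GuideAnnotation(ann)
    cols = [*reference_cols, *tumor_cols]
    counts = raw[cols].round().astype("int64")
    meta = pd.DataFrame(
        {
            "context": ["in_vitro_day0"] * len(reference_cols) + ["flank"] * len(tumor_cols),
            "site": None,
            "day": [0] * len(reference_cols) + [28] * len(tumor_cols),
            "mouse_id": None,
            "experiment_id": [
                (experiment_of or {}).get(c, "exp1") for c in cols
            ],
            "matched_primary": None,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return CountTable(counts, meta), annotation


def screen_class_means(
    table: CountTable,
    annotation: GuideAnnotation,
    tumor_context: str = "flank",
) -> pd.Series:
    """Macro-class group means of percent representation for one screen."""
    return quantify(table, annotation, tumor_context=tumor_context).group_means


def load_feature_sheet(
    workbook: str | Path,
    sheet: str | int,
    sample_col: str,
) -> pd.DataFrame:
    """Read a metabolite feature sheet (samples x metabolites) for PCA."""
    workbook = Path(workbook)
    if not workbook.exists():
        raise FileNotFoundError(
            f"supplementary workbook not found at {workbook}; download the "
            "published S1 Data file and place it there"
        )
    raw = pd.read_excel(workbook, sheet_name=sheet)
    return raw.set_index(sample_col).apply(pd.to_numeric, errors="coerce")
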