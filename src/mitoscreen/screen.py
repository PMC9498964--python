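"""sgRNA representation analysis for pooled in vivo CRISPRi screens.

A tumor's guide composition is compared against the pre-injection culture:
each guide's read count is normalized to the summed reads of the
nontargeting (negative-control) guides in the same sample, and the ratio of
that control-normalized frequency in the tumor to its frequency in the
reference pool — expressed as a percentage — is the guide's *representation*.
100% means no change; values below 100% indicate in vivo depletion, i.e. a
fitness cost of the knockdown.

Guides carry a functional class (nontargeting / glycolytic / mitochondrial
protein synthesis / respiratory chain / other mitochondrial), which collapses
to a macro class (control / glycolytic / mito-respiratory / other) for the
group-level comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import GroupComparison, group_compare

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_CLASSES",
    "MACRO_CLASS_OF",
    "GuideAnnotation",
    "CountTable",
    "RepresentationTable",
    "load_count_table",
    "control_normalized_frequency",
    "representation_percent",
    "aggregate_representation",
    "timepoint_dynamics",
    "metastasis_analysis",
    "rank_depletion",
]

FUNCTIONAL_CLASSES = (
    "nontargeting",
    "glycolytic",
    "mito_protein_synthesis",
    "respiratory_chain",
    "other_mito",
)

#: functional class -> macro class used for group comparisons
MACRO_CLASS_OF = {
    "nontargeting": "control",
    "glycolytic": "glycolytic",
    "mito_protein_synthesis": "mito_respiratory",
    "respiratory_chain": "mito_respiratory",
    "other_mito": "other",
}

CONTEXTS = ("in_vitro_day0", "flank", "orthotopic_primary", "metastasis")


@dataclass
class GuideAnnotation:
    """Guide identities and functional classes.

    ``table`` is indexed by ``guide_id`` with columns ``target_gene``
    (null for nontargeting controls) and ``functional_class``; a derived
    ``macro_class`` column is added on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dupes = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate guide ids: {dupes}")
        bad = set(t["functional_class"]) - set(FUNCTIONAL_CLASSES)
        if bad:
            raise ValueError(f"unknown functional classes: {sorted(bad)}")
        t = t.copy()
        t["macro_class"] = t["functional_class"].map(MACRO_CLASS_OF)
        nt = t["functional_class"] == "nontargeting"
        t.loc[nt, "target_gene"] = None
        self.table = t

    @property
    def guide_ids(self) -> pd.Index:
        return self.table.index

    @property
    def nontargeting(self) -> pd.Index:
        return self.table.index[self.table["functional_class"] == "nontargeting"]

    def macro_class(self) -> pd.Series:
        return self.table["macro_class"]

    def composition(self) -> pd.Series:
        """Guide counts per functional class (controls first)."""
        return self.table["functional_class"].value_counts().reindex(
            FUNCTIONAL_CLASSES, fill_value=0
        )


@dataclass
class CountTable:
    """Integer read counts (guides x samples) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``context`` (one of
    ``in_vitro_day0``/``flank``/``orthotopic_primary``/``metastasis``),
    ``site``, ``day``, ``mouse_id``, ``experiment_id`` and
    ``matched_primary`` (sample id of the matched primary tumor for
    metastasis samples, else null).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            r, s = np.argwhere(c.values < 0)[0]
            raise ValueError(
                f"negative count at guide {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        missing = [col for col in c.columns if col not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        bad_ctx = set(self.samples["context"]) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown sample contexts: {sorted(bad_ctx)}")

    def samples_in_context(self, context: str) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        return list(meta.index[meta["context"] == context])

    def subset(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)], self.samples)


@dataclass
class RepresentationTable:
    """Per-guide percent representation (tumor vs reference), guides x samples."""

    representation: pd.DataFrame
    annotation: GuideAnnotation
    samples: pd.DataFrame | None = None
    per_guide: pd.DataFrame | None = field(default=None, repr=False)
    group_means: pd.Series | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# loading


def load_count_table(
    path: str | Path,
    annotation_path: str | Path,
    sample_meta: str | Path | pd.DataFrame | None = None,
) -> tuple[CountTable, GuideAnnotation]:
    """Read a delimited count matrix and guide annotation table.

    The count file's first column names the guide, remaining columns are
    samples.  The annotation file has columns ``guide_id``, ``target_gene``,
    ``functional_class``.  ``sample_meta`` may be a YAML file mapping sample
    id to metadata fields, or a prebuilt DataFrame; when omitted, every
    sample defaults to the pre-injection culture context.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in raw.columns:
        vals = raw[col]
        nonint = vals != np.floor(vals)
        if nonint.any():
            g = vals.index[nonint][0]
            raise ValueError(f"non-integer count at guide {g!r}, sample {col!r}")
    counts = raw.astype(np.int64)

    asep = "\t" if annotation_path.suffix in (".tsv", ".txt") else ","
    ann_df = pd.read_csv(annotation_path, sep=asep).set_index("guide_id")
    annotation = GuideAnnotation(ann_df)

    unannotated = counts.index.difference(annotation.guide_ids)
    if len(unannotated):
        raise ValueError(f"guides missing annotation: {list(unannotated)}")

    if sample_meta is None:
        meta = pd.DataFrame(
            {
                "context": "in_vitro_day0",
                "site": None,
                "day": 0,
                "mouse_id": None,
                "experiment_id": "exp1",
                "matched_primary": None,
            },
            index=pd.Index(counts.columns, name="sample_id"),
        )
    elif isinstance(sample_meta, pd.DataFrame):
        meta = sample_meta
    else:
        import yaml

        with open(sample_meta) as fh:
            meta = pd.DataFrame.from_dict(yaml.safe_load(fh), orient="index")
        meta.index.name = "sample_id"

    comp = annotation.composition()
    logger.info(
        "loaded %d guides x %d samples; class composition: %s (%.0f%% controls)",
        counts.shape[0],
        counts.shape[1],
        comp.to_dict(),
        100 * comp["nontargeting"] / comp.sum(),
    )
    return CountTable(counts, meta), annotation


def write_count_table(table: CountTable, annotation: GuideAnnotation, directory: str | Path) -> dict[str, Path]:
    """Write counts/annotation/metadata as TSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "annotation": directory / "annotation.tsv",
        "samples": directory / "samples.tsv",
    }
    table.counts.rename_axis("guide_id").to_csv(paths["counts"], sep="\t")
    annotation.table.drop(columns="macro_class").rename_axis("guide_id").to_csv(
        paths["annotation"], sep="\t"
    )
    table.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# representation


def control_normalized_frequency(
    table: CountTable,
    annotation: GuideAnnotation,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Each guide's count divided by the summed nontargeting-guide counts.

    f_gs = (c_gs + pseudocount) / sum over nontargeting g' of (c_g's + pseudocount)

    Scale-invariant per sample: multiplying all counts in a sample by a
    constant leaves frequencies unchanged (exactly so at pseudocount 0).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    nt = annotation.nontargeting.intersection(table.counts.index)
    if len(nt) == 0:
        raise ValueError("no nontargeting guides present")
    shifted = table.counts.astype(float) + pseudocount
    denom = shifted.loc[nt].sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(
            f"nontargeting read sum is zero in sample(s) {list(zero.index)}; "
            "use a positive pseudocount"
        )
    return shifted / denom


def default_pseudocount(table: CountTable) -> float:
    """1 when any sample contains zero-count guides, else 0."""
    return 1.0 if (table.counts.values == 0).any() else 0.0


def representation_percent(
    freq_tumor: pd.DataFrame,
    freq_reference: pd.DataFrame,
    annotation: GuideAnnotation,
    samples: pd.DataFrame | None = None,
) -> RepresentationTable:
    """Percent representation: tumor frequency relative to the reference pool.

    The reference is the mean control-normalized frequency across the
    pre-injection replicate samples (the culture is a common pool, so
    replicates are averaged rather than paired).  R_gs = 100 * f_gs / f_g(ref).
    """
    missing = freq_tumor.index.difference(freq_reference.index)
    if len(missing):
        raise ValueError(f"guides absent from reference: {list(missing)}")
    ref = freq_reference.loc[freq_tumor.index].mean(axis=1)
    zero = ref.index[ref == 0]
    if len(zero):
        raise ValueError(
            f"zero reference frequency for guides {list(zero)}; "
            "recompute frequencies with a positive pseudocount"
        )
    rep = 100.0 * freq_tumor.div(ref, axis=0)
    return RepresentationTable(rep, annotation, samples)


def aggregate_representation(
    rep: RepresentationTable,
    by: str = "experiment_then_guide",
) -> RepresentationTable:
    """Per-guide mean/SEM across tumors and macro-class group means.

    ``experiment_then_guide`` (default) first averages tumors within each
    experiment, then averages the per-experiment means — matching a design
    with independent replicate experiments.  ``pooled`` averages all tumor
    samples directly.
    """
    if by not in ("experiment_then_guide", "pooled"):
        raise ValueError(f"unknown aggregation mode {by!r}")
    R = rep.representation
    if by == "experiment_then_guide" and rep.samples is not None:
        exp = rep.samples.loc[list(R.columns), "experiment_id"]
        per_exp = R.T.groupby(exp.values).mean().T  # guides x experiments
        mean = per_exp.mean(axis=1)
        sem = per_exp.sem(axis=1, ddof=1) if per_exp.shape[1] > 1 else pd.Series(0.0, index=R.index)
    else:
        mean = R.mean(axis=1)
        sem = R.sem(axis=1, ddof=1) if R.shape[1] > 1 else pd.Series(0.0, index=R.index)
    sem = sem.fillna(0.0)

    macro = rep.annotation.macro_class().reindex(R.index)
    per_guide = pd.DataFrame({"mean": mean, "sem": sem, "macro_class": macro})
    group_means = per_guide.groupby("macro_class")["mean"].mean()
    unknown = per_guide["macro_class"].isna()
    if unknown.any():
        raise ValueError(f"guides with unknown macro class: {list(per_guide.index[unknown])}")
    return RepresentationTable(R, rep.annotation, rep.samples, per_guide, group_means)


def macro_class_values(rep: RepresentationTable) -> dict[str, np.ndarray]:
    """Per-guide mean representation grouped by macro class (for group tests)."""
    if rep.per_guide is None:
        rep = aggregate_representation(rep)
    pg = rep.per_guide
    return {
        cls: pg.loc[pg["macro_class"] == cls, "mean"].to_numpy()
        for cls in pg["macro_class"].unique()
    }


def rank_depletion(rep: RepresentationTable) -> pd.DataFrame:
    """Guides ordered from most to least depleted (ascending mean representation).

    Ties break lexicographically on guide id so the ordering is deterministic.
    """
    if rep.per_guide is None:
        rep = aggregate_representation(rep)
    pg = rep.per_guide.copy()
    pg["target_gene"] = rep.annotation.table["target_gene"].reindex(pg.index)
    # stable sort on guide_id first so equal means keep lexicographic order
    return pg.sort_index(kind="mergesort").sort_values("mean", kind="mergesort")


def quantify(
    table: CountTable,
    annotation: GuideAnnotation,
    tumor_context: str = "flank",
    reference_context: str = "in_vitro_day0",
    pseudocount: float | None = None,
    by: str = "experiment_then_guide",
) -> RepresentationTable:
    """End-to-end representation quantification for one tumor context.

    Control-normalizes counts, references the pre-injection pool, and
    aggregates per guide and per macro class.  ``pseudocount=None`` applies
    the default policy (1 only when zero counts are present).
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    freq = control_normalized_frequency(table, annotation, pseudocount)
    tumors = table.samples_in_context(tumor_context)
    reference = table.samples_in_context(reference_context)
    if not tumors or not reference:
        raise ValueError(
            f"need samples in both {tumor_context!r} and {reference_context!r}"
        )
    rep = representation_percent(freq[tumors], freq[reference], annotation, table.samples)
    return aggregate_representation(rep, by=by)


# ---------------------------------------------------------------------------
# timepoints and metastases


def timepoint_dynamics(
    table: CountTable,
    annotation: GuideAnnotation,
    days: Sequence[int],
    pseudocount: float | None = None,
) -> dict[int, dict]:
    """Day-d representation normalized to day 0, with per-guide and class tests.

    For each requested day the day-0 replicate pool serves as the reference.
    Per guide, a two-sided one-sample t test asks whether the replicate
    ratios differ from 100%; across classes, one-way ANOVA with Tukey HSD
    compares the per-guide mean ratios.
    """
    from scipy import stats as sps

    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    meta = table.samples.loc[list(table.counts.columns)]
    day0 = list(meta.index[meta["day"] == 0])
    if not day0:
        raise ValueError("no day-0 samples present")
    freq = control_normalized_frequency(table, annotation, pseudocount)
    out: dict[int, dict] = {}
    for day in days:
        day_samples = list(meta.index[meta["day"] == day])
        if not day_samples:
            raise ValueError(f"no samples at day {day}")
        rep = representation_percent(freq[day_samples], freq[day0], annotation, table.samples)
        agg = aggregate_representation(rep, by="pooled")
        R = rep.representation
        if R.shape[1] >= 2:
            t_res = sps.ttest_1samp(R, popmean=100.0, axis=1)
            guide_tests = pd.DataFrame(
                {"t": t_res.statistic, "p": t_res.pvalue}, index=R.index
            )
        else:
            guide_tests = pd.DataFrame({"t": np.nan, "p": np.nan}, index=R.index)
        # class-level omnibus test needs >= 2 classes with >= 2 guides each
        class_values = {
            k: v for k, v in macro_class_values(agg).items() if len(v) >= 2
        }
        comparison = (
            group_compare(class_values, method="anova_tukey")
            if len(class_values) >= 2
            else None
        )
        out[day] = {
            "representation": agg,
            "guide_tests": guide_tests,
            "class_comparison": comparison,
        }
    return out


def metastasis_analysis(
    freq: pd.DataFrame,
    annotation: GuideAnnotation,
    pairs: Sequence[tuple[str, str]],
    correlation_pairs: Sequence[tuple[str, str]] = (),
) -> dict:
    """Metastasis representation normalized to the matched primary tumor.

    ``pairs`` lists (metastasis sample, matched primary sample) from the same
    animal; per guide, R = 100 * f(met) / f(primary).  For two metastases
    from one animal (``correlation_pairs``), a Pearson correlation of the
    normalized values is computed separately within each functional class.
    """
    from scipy import stats as sps

    for met, prim in pairs:
        if prim is None:
            raise ValueError(f"metastasis sample {met!r} has no matched primary")
        if met not in freq.columns or prim not in freq.columns:
            raise ValueError(f"sample missing from frequency matrix: {met!r}/{prim!r}")
    rep = pd.DataFrame(
        {met: 100.0 * freq[met] / freq[prim] for met, prim in pairs}
    )
    rep_table = RepresentationTable(rep, annotation)
    agg = aggregate_representation(rep_table, by="pooled")

    correlations: dict[tuple[str, str], pd.DataFrame] = {}
    fclass = annotation.table["functional_class"].reindex(rep.index)
    for a, b in correlation_pairs:
        rows = []
        for cls in FUNCTIONAL_CLASSES:
            idx = fclass.index[fclass == cls]
            if len(idx) < 3:
                continue
            r, p = sps.pearsonr(rep.loc[idx, a], rep.loc[idx, b])
            rows.append({"functional_class": cls, "r": float(r), "p": float(p), "n": len(idx)})
        correlations[(a, b)] = pd.DataFrame(rows)
    return {"representation": agg, "correlations": correlations}
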