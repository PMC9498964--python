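"""Preranked gene-set enrichment with a gene-permutation null, volcano
summaries, and joint gene + metabolite pathway overlay tables.

The enrichment statistic is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranked list, hits increment the sum by
|metric|^weight (normalized over the set's hits) and misses decrement it by
1/(N - N_h); the enrichment score ES is the maximum deviation from zero.
The null is built by drawing random gene sets of the same size from the
ranked universe ("gene permutation"); when the number of distinct subsets is
small enough, all of them are enumerated so the nominal p-value is exact.
NES normalizes ES by the mean magnitude of same-sign permuted scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "GeneSet",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "preranked_enrichment",
    "volcano_table",
    "pathway_overlay",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSet:
    set_id: str
    genes: frozenset[str]


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    size: int  # effective size after intersecting with the universe


@dataclass
class RankedGeneList:
    """Genes sorted descending by metric (log2 fold change vs control)."""

    table: pd.DataFrame  # index gene, column 'metric'

    @property
    def genes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def metrics(self) -> np.ndarray:
        return self.table["metric"].to_numpy()


def rank_genes(expression: pd.DataFrame, metric_col: str = "log2fc") -> RankedGeneList:
    """Collapse to unique genes (keeping the entry with max |metric|) and sort
    descending by metric with a lexicographic gene-id tie-break."""
    df = expression[[metric_col]].rename(columns={metric_col: "metric"}).copy()
    df["absmetric"] = df["metric"].abs()
    df = df.sort_values("absmetric", kind="mergesort")
    df = df.groupby(level=0).tail(1).drop(columns="absmetric")
    df = df.sort_index(kind="mergesort").sort_values(
        "metric", ascending=False, kind="mergesort"
    )
    return RankedGeneList(df)


def enrichment_score(
    ranked_genes: Sequence[str],
    metrics: np.ndarray,
    member_mask: np.ndarray,
    weight: float = 1.0,
) -> float:
    """ES for one set: signed maximum deviation of the weighted running sum."""
    n = len(ranked_genes)
    n_hits = int(member_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict, nonempty subset of the universe")
    weights = np.abs(metrics) ** weight if weight != 0 else np.ones(n)
    hit_w = np.where(member_mask, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member metrics are zero: fall back to uniform hits
        hit_w = member_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~member_mask) / (n - n_hits)
    running = np.cumsum(steps)
    peak = np.argmax(np.abs(running))
    return float(running[peak])


def _null_scores(
    metrics: np.ndarray,
    size: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation null: ES of random same-size gene sets.

    All C(N, size) subsets are enumerated when there are no more of them
    than ``n_perm``, making the nominal p-value exact on small universes.
    """
    n = metrics.size
    genes = np.arange(n)
    total = comb(n, size)
    scores = []
    if total <= n_perm:
        for combo in combinations(range(n), size):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            scores.append(enrichment_score(genes, metrics, mask, weight))
    else:
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=size, replace=False)] = True
            scores.append(enrichment_score(genes, metrics, mask, weight))
    return np.asarray(scores)


def preranked_enrichment(
    ranked: RankedGeneList,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 500,
    weight: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked enrichment over a collection of gene sets.

    Set membership is intersected with the ranked universe before the
    size filter; sets outside [min_size, max_size] are skipped.  The nominal
    p-value uses the same-sign tail of the permutation ES distribution and
    NES divides ES by the mean |permuted ES| of that sign.  Deterministic
    given ``seed``.
    """
    if ranked.table.empty:
        raise ValueError("ranked gene list is empty")
    genes = ranked.genes
    metrics = ranked.metrics
    universe = set(genes)
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for gene_set in sets:
        members = gene_set.genes & universe
        if not members:
            warnings.warn(f"set {gene_set.set_id!r} has no genes in the universe; skipped", stacklevel=2)
            continue
        size = len(members)
        if size < min_size or size > max_size:
            logger.info("set %s excluded by size filter (%d)", gene_set.set_id, size)
            continue
        mask = np.isin(genes, list(members))
        es = enrichment_score(genes, metrics, mask, weight)
        null = _null_scores(metrics, size, weight, n_perm, rng)
        same_sign = null >= 0 if es >= 0 else null <= 0
        n_sign = int(same_sign.sum())
        if n_sign == 0:
            p = 1.0 / (null.size + 1)
            nes = np.nan
        else:
            extreme = np.abs(null[same_sign]) >= abs(es)
            p = max(float(extreme.sum()) / n_sign, 1.0 / (null.size + 1))
            mean_mag = float(np.abs(null[same_sign]).mean())
            nes = es / mean_mag if mean_mag > 0 else np.nan
        results.append(EnrichmentResult(gene_set.set_id, es, float(nes), p, size))
    return results


def volcano_table(expression: pd.DataFrame) -> pd.DataFrame:
    """log2-transformed volcano columns from a per-gene (log2fc, p) table.

    p-values of exactly zero are clamped to the smallest positive float with
    a warning.  ``significant`` flags p < 0.05.
    """
    if ((expression["p"] <= 0) & (expression["p"] != 0)).any() or (expression["p"] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    p = expression["p"].to_numpy(dtype=float).copy()
    zero = p == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero p-values clamped to float tiny", stacklevel=2)
        p[zero] = np.nextafter(0, 1)
    out = pd.DataFrame(
        {
            "log2fc": expression["log2fc"],
            "log2_p": np.log2(p),
            "significant": p < 0.05,
        },
        index=expression.index,
    )
    for extra in ("targeted", "target_gene"):
        if extra in expression.columns:
            out[extra] = expression[extra]
    return out


def pathway_overlay(
    expression: pd.DataFrame,
    metabolites: pd.DataFrame | None,
    node_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Joint gene + compound overlay values for one pathway.

    ``node_map`` sends a pathway node id to the gene symbols or compound
    names it represents.  Each node's value is the mean replicate-averaged
    log2 fold change of its mapped members; genes and compounds are
    co-reported with a ``kind`` column and a ``direction`` flag.  Ids that
    map to nothing in either input table are listed with NaN values.
    """
    if not node_map:
        raise ValueError("empty pathway node map")
    gene_fc = expression["log2fc"] if expression is not None and not expression.empty else pd.Series(dtype=float)
    met_fc = (
        metabolites["log2fc"]
        if metabolites is not None and not metabolites.empty
        else pd.Series(dtype=float)
    )
    rows = []
    for node_id, members in node_map.items():
        gene_vals = [gene_fc[m] for m in members if m in gene_fc.index]
        met_vals = [met_fc[m] for m in members if m in met_fc.index]
        if gene_vals:
            kind, value = "gene", float(np.mean(gene_vals))
        elif met_vals:
            kind, value = "compound", float(np.mean(met_vals))
        else:
            kind, value = "unmapped", np.nan
        rows.append(
            {
                "node_id": node_id,
                "kind": kind,
                "log2fc": value,
                "direction": "up" if value > 0 else ("down" if value < 0 else "flat"),
                "members": ";".join(members),
            }
        )
    out = pd.DataFrame(rows).set_index("node_id")
    unmapped = list(out.index[out["kind"] == "unmapped"])
    if unmapped:
        logger.info("unmapped pathway nodes: %s", unmapped)
    return out


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.set_id, "na", *sorted(s.genes)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
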