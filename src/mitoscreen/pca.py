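"""PCA of metabolite feature matrices and per-genotype condition-shift vectors.

Samples (genotype x condition x environment) are rows, metabolites columns;
values are fractional labeling in [0, 1] or relative pool amounts.  With unit
scaling each feature is centered and divided by its standard deviation, so
the decomposition is of the correlation matrix and is invariant to positive
rescaling of any feature column.  A deterministic sign convention (the
largest-magnitude loading of each component is positive) makes scores
reproducible across runs and platforms.

The condition-shift vector for a genotype is the difference of mean scores
between two growth conditions within one fitted space,
dPC1 = mean PC1(control) - mean PC1(treated), and analogously for PC2 — a
compact summary of how a treatment moves the genotype's metabolic state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "DeltaPC", "prepare_feature_matrix", "fit_pca", "delta_pc"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_fraction: np.ndarray  # over all retained components, sums to 1


@dataclass
class DeltaPC:
    genotype: str
    treatment: str
    delta_pc1: float
    delta_pc2: float


def prepare_feature_matrix(
    X: pd.DataFrame, max_missing_fraction: float = 0.2
) -> pd.DataFrame:
    """Apply the missing-value policy: drop features missing in more than
    ``max_missing_fraction`` of samples, mean-impute the remainder."""
    missing = X.isna().mean(axis=0)
    dropped = list(missing.index[missing > max_missing_fraction])
    if dropped:
        logger.warning("dropping features with >%d%% missing: %s", int(100 * max_missing_fraction), dropped)
        X = X.drop(columns=dropped)
    return X.fillna(X.mean(axis=0))


def fit_pca(X: pd.DataFrame, scaling: str = "unit") -> PCAResult:
    """Centered PCA of a samples-x-metabolites matrix.

    ``scaling='unit'`` divides each centered feature by its standard
    deviation (ddof=1), i.e. PCA of the correlation matrix; ``'none'`` uses
    the covariance matrix.  Zero-variance features are dropped with a
    warning.  Variance fractions are reported over all components and sum
    to 1; components are ordered by nonincreasing variance.
    """
    if scaling not in ("unit", "none"):
        raise ValueError("scaling must be 'unit' or 'none'")
    X = prepare_feature_matrix(X)
    sd = X.std(axis=0, ddof=1)
    zero_var = list(sd.index[(sd == 0) | sd.isna()])
    if zero_var:
        warnings.warn(f"dropping zero-variance features: {zero_var}", stacklevel=2)
        X = X.drop(columns=zero_var)
        sd = sd.drop(index=zero_var)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 usable features for PCA")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")

    values = X.to_numpy(dtype=float)
    centered = values - values.mean(axis=0)
    if scaling == "unit":
        centered = centered / sd.to_numpy()

    n_comp = min(centered.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(centered)
    loadings = model.components_.T  # features x components

    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    frac = model.explained_variance_ratio_
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        variance_fraction=frac,
    )


def delta_pc(
    result: PCAResult,
    genotypes: pd.Series,
    conditions: pd.Series,
    control: str = "basal",
    treatment: str = "dg2",
) -> list[DeltaPC]:
    """Per-genotype shift of mean PC1/PC2 scores between two conditions.

    Both condition groups must come from the same fitted space; genotypes
    missing either condition are skipped with a warning.
    """
    genotypes = genotypes.reindex(result.scores.index)
    conditions = conditions.reindex(result.scores.index)
    out: list[DeltaPC] = []
    for genotype in pd.unique(genotypes.dropna()):
        sel = genotypes == genotype
        ctl = result.scores[sel & (conditions == control)]
        trt = result.scores[sel & (conditions == treatment)]
        if ctl.empty or trt.empty:
            warnings.warn(
                f"genotype {genotype!r} lacks samples in one of "
                f"{control!r}/{treatment!r}; skipped",
                stacklevel=2,
            )
            continue
        out.append(
            DeltaPC(
                genotype=str(genotype),
                treatment=treatment,
                delta_pc1=float(ctl["PC1"].mean() - trt["PC1"].mean()),
                delta_pc2=float(ctl["PC2"].mean() - trt["PC2"].mean()),
            )
        )
    return out
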