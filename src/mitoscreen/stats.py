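"""Group-comparison statistics shared by the screen and tracing analyses.

Thin, typed wrappers around scipy's omnibus tests and multiple-comparison
procedures (one-way ANOVA with Tukey HSD or Dunnett contrasts, plain t and
Mann-Whitney tests).  Everything is two-sided unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "group_compare",
    "dunnett_vs_control",
]


@dataclass
class GroupComparison:
    """Result of a between-group test.

    ``statistic`` is F for ANOVA-based methods, t for ``t_test`` and U for
    ``mann_whitney``.  ``pairwise`` carries ``(group_a, group_b, adjusted_p)``
    tuples and is populated only by the omnibus methods.
    """

    method: str
    statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)


_METHODS = ("anova_tukey", "anova_dunnett", "t_test", "mann_whitney")


def _as_clean_arrays(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[str(name)] = arr
    return out


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "anova_tukey",
    control: str | None = None,
) -> GroupComparison:
    """Compare per-guide (or per-replicate) values between groups.

    Parameters
    ----------
    values_by_group
        Mapping from group label to the per-member values.
    method
        One of ``anova_tukey``, ``anova_dunnett``, ``t_test``, ``mann_whitney``.
        The two-sample methods require exactly two groups.
    control
        Control group label, required for ``anova_dunnett``.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    groups = _as_clean_arrays(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    arrays = [groups[n] for n in names]

    if method in ("t_test", "mann_whitney"):
        if len(arrays) != 2:
            raise ValueError(f"{method} requires exactly two groups")
        if method == "t_test":
            res = stats.ttest_ind(arrays[0], arrays[1])
        else:
            res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupComparison(method, float(res.statistic), float(res.pvalue))

    if any(a.size < 2 for a in arrays):
        raise ValueError("omnibus methods need at least two values per group")
    f_res = stats.f_oneway(*arrays)
    pairwise: list[tuple[str, str, float]] = []

    if method == "anova_tukey":
        tk = stats.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairwise.append((names[i], names[j], float(tk.pvalue[i, j])))
    else:
        if control is None or control not in groups:
            raise ValueError("anova_dunnett requires a valid control group label")
        others = [n for n in names if n != control]
        # fixed rng: the multivariate-t CDF behind the adjusted p-values is
        # evaluated by quasi-Monte-Carlo and must be reproducible
        dn = stats.dunnett(
            *[groups[n] for n in others],
            control=groups[control],
            rng=np.random.default_rng(1729),
        )
        for name, p in zip(others, dn.pvalue):
            pairwise.append((name, control, float(p)))

    return GroupComparison(method, float(f_res.statistic), float(f_res.pvalue), pairwise)


def dunnett_vs_control(
    values_by_genotype: Mapping[str, Sequence[float]], control: str
) -> GroupComparison:
    """One-way ANOVA with Dunnett's many-to-one contrasts against ``control``.

    Mirrors the treated-vs-control design used for flux-ratio comparisons:
    each non-control genotype yields one adjusted p-value.
    """
    if control not in values_by_genotype:
        raise ValueError(f"control genotype {control!r} not present")
    return group_compare(values_by_genotype, method="anova_dunnett", control=control)
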