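"""Partition ↔ metadata and partition ↔ microbiome association statistics.

Quantitative variables are compared across partitions with tie-corrected
Kruskal-Wallis tests followed by all-pairs Mann-Whitney post-hoc tests
(BH-adjusted within the variable); categorical associations use Pearson's
chi-squared without continuity correction.  Cohort summary tables report
n (%) per stratum with percentages computed among subjects whose value is
known — the convention that reproduces the published cohort margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffabund import bh_adjust
from .preprocess import CountTable

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "mann_whitney",
    "chi_squared",
    "prevalence",
    "summarize_metadata",
    "format_percent",
    "classify_partitions_by_health",
]


@dataclass
class GroupComparison:
    """A Kruskal-Wallis comparison with all-pairs post-hoc results."""

    variable: str
    group_n: dict[str, int]
    statistic: float
    p: float
    posthoc: dict[tuple, tuple[float, float, float]] = field(default_factory=dict)
    # pair -> (U statistic, p, BH-adjusted q)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both samples have n <= 8 and no ties cross the
    groups; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact_ok = len(x) <= 8 and len(y) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if exact_ok else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(values_by_group: Mapping[str, "np.ndarray"], variable: str = "") -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with BH-adjusted Mann-Whitney post-hocs.

    Raises when fewer than two groups are supplied, a group is empty, or all
    observations are identical (the tie-corrected statistic is undefined).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate(list(groups.values()))
    if np.unique(pooled).size == 1:
        raise ValueError("all observations are identical; H undefined under tie correction")
    H, p = sps.kruskal(*groups.values())

    pairs = list(combinations(sorted(groups), 2))
    stats_p = [mann_whitney(groups[a], groups[b]) for a, b in pairs]
    qs = bh_adjust([p_ for _, p_ in stats_p])
    posthoc = {pair: (u, p_, q) for pair, (u, p_), q in zip(pairs, stats_p, qs)}
    return GroupComparison(
        variable=variable,
        group_n={g: int(v.size) for g, v in groups.items()},
        statistic=float(H),
        p=float(p),
        posthoc=posthoc,
    )


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared on an r × c count table (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("chi-squared undefined with a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def prevalence(table: CountTable, groups: Mapping[str, str]) -> pd.DataFrame:
    """Taxon × group detection prevalence (fraction of samples with count > 0)."""
    ser = pd.Series({s: groups[s] for s in table.samples})
    out = {}
    for g, idx in ser.groupby(ser).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {g}")
        sub = table.counts.loc[:, idx]
        out[g] = (sub > 0).mean(axis=1)
    if not out:
        raise ValueError("groups are empty")
    return pd.DataFrame(out)


def format_percent(pct: float) -> str:
    """Display convention of the cohort table: integers at >= 10%, one decimal below."""
    if pct >= 10:
        return f"{pct:.0f}%"
    return f"{pct:.1f}%"


def summarize_metadata(
    metadata: pd.DataFrame,
    variables: list[str],
    strata: Mapping[str, pd.Series] | None = None,
    unknown_values: tuple = ("unknown",),
) -> pd.DataFrame:
    """Cohort-style n (%) summary per stratum.

    Percent denominators exclude rows whose value for that variable is
    unknown/missing — the convention under which the published margins
    reproduce.  `strata` maps stratum name to a boolean mask over the rows;
    the full cohort is always included as ``all``.
    """
    if strata is None:
        strata = {}
    all_strata: dict[str, pd.Series] = {"all": pd.Series(True, index=metadata.index)}
    all_strata.update(strata)

    rows = []
    for stratum, mask in all_strata.items():
        sub = metadata[np.asarray(mask, dtype=bool)]
        for var in variables:
            col = sub[var]
            known = col[~(col.isin(unknown_values) | col.isna())]
            denom = len(known)
            for level, n in col.value_counts(dropna=False).items():
                is_unknown = (level in unknown_values) or (isinstance(level, float) and np.isnan(level))
                pct = 100.0 * n / denom if denom and not is_unknown else np.nan
                rows.append(
                    {
                        "stratum": stratum,
                        "variable": var,
                        "level": level,
                        "n": int(n),
                        "percent": pct,
                        "display": format_percent(pct) if np.isfinite(pct) else "",
                    }
                )
    return pd.DataFrame(rows)


def classify_partitions_by_health(
    assignments: pd.Series,
    metadata: pd.DataFrame,
    threshold: float = 0.9,
) -> dict:
    """Label partitions health-associated when > `threshold` of known-status
    subjects are controls (strict inequality), else ``other``.

    Partitions with no known-status subjects are labelled other with a
    warning.
    """
    health = metadata.set_index("sample_id")["health_category"].reindex(assignments.index)
    out: dict = {}
    for part in pd.unique(assignments):
        idx = assignments.index[assignments == part]
        h = health.loc[idx]
        known = h[~(h.isna() | (h == "unknown"))]
        if len(known) == 0:
            warnings.warn(f"partition {part!r} has no known health status; labelled other")
            out[part] = "other"
            continue
        frac = (known == "control").mean()
        out[part] = "health_associated" if frac > threshold else "other"
    return out
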