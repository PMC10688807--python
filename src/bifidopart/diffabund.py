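"""Simplified negative-binomial differential abundance across partitions.

This is a deliberately transparent NB stage, not a DESeq2 clone: size
factors use the "poscounts" median-of-positive-ratios rule suited to sparse
tables, the per-taxon NB2 dispersion is a method-of-moments estimate on
normalised counts pooled within groups (no shrinkage, no independent
filtering), and the group effect is fitted by IRLS on a log-link NB GLM
with the size factor as offset.  Pairwise contrasts report Wald statistics
(log2 fold-change = beta / ln 2, estimate ± standard error); the global
partition effect uses a likelihood-ratio test against the intercept model.
Multiple testing is Benjamini-Hochberg across taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "NBTestResult",
    "bh_adjust",
    "poscounts_size_factors",
    "nb_wald_pairwise",
    "nb_lrt_global",
]

DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 10.0


@dataclass
class NBTestResult:
    """One taxon's result for one contrast (pairwise Wald or global LRT)."""

    taxon: str
    contrast: str
    log2fc: float
    se: float
    stat: float
    p: float
    q: float
    dispersion: float
    testable: bool = True


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    NaN entries (untestable taxa) are ignored for the family size and
    propagate as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(m)
    res[order] = q
    out[ok] = res
    return out


def poscounts_size_factors(table) -> pd.Series:
    """"poscounts" size factors for a sparse taxa × sample count table.

    The per-taxon reference is the geometric mean over *positive* counts
    with the zeros still counted in the denominator:
    r_i = exp( sum_{x_ij > 0} ln x_ij / n ).  Each sample's factor is the
    median of x_ij / r_i over taxa with r_i > 0 and x_ij > 0, and the
    factors are rescaled to have geometric mean one.
    """
    if hasattr(table, "counts"):
        table = table.counts
    X = np.asarray(table, dtype=float)
    taxa_ok = True
    n = X.shape[1]
    if n == 0:
        raise ValueError("no samples")
    if (X.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one positive count")
    with np.errstate(divide="ignore"):
        logx = np.where(X > 0, np.log(X), 0.0)
    r = np.exp(logx.sum(axis=1) / n)
    r = np.where(X.sum(axis=1) > 0, r, 0.0)

    s = np.empty(n)
    for j in range(n):
        mask = (r > 0) & (X[:, j] > 0)
        if not mask.any():
            raise ValueError(f"sample {j} shares no positive taxa with the reference")
        s[j] = np.median(X[mask, j] / r[mask])
    s = s / np.exp(np.mean(np.log(s)))
    if isinstance(table, pd.DataFrame):
        return pd.Series(s, index=table.columns, name="size_factor")
    return pd.Series(s, name="size_factor")


def _mom_dispersion(y: np.ndarray, labels: np.ndarray) -> float:
    """NB2 dispersion from within-group moments of normalised counts.

    For each group, alpha_g = (var - mean) / mean^2; the estimate is the
    df-weighted average, clipped to [1e-8, 10].
    """
    num = den = 0.0
    for g in np.unique(labels):
        v = y[labels == g]
        if v.size < 2:
            continue
        m = v.mean()
        if m <= 0:
            continue
        var = v.var(ddof=1)
        num += (v.size - 1) * (var - m) / m**2
        den += v.size - 1
    alpha = num / den if den > 0 else DISPERSION_FLOOR
    return float(np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CAP))


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    fam = sm.families.NegativeBinomial(alpha=alpha) if alpha > 1e-6 else sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam, offset=offset)
        return model.fit(maxiter=200, tol=1e-10)


def nb_wald_pairwise(
    table,
    size_factors: pd.Series,
    groups: Mapping[str, str],
    pair: tuple[str, str],
) -> list[NBTestResult]:
    """Per-taxon NB Wald test between two partitions.

    The second-listed partition of `pair` is the reference level, so the
    reported log2 fold-change is (first / second).  Taxa with all-zero
    counts in both groups are returned untestable (p = NaN).
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    a, b = pair
    samples = [s for s in counts.columns if groups.get(s) in (a, b)]
    if sum(groups[s] == a for s in samples) < 2 or sum(groups[s] == b for s in samples) < 2:
        raise ValueError("both groups need at least two samples")
    sub = counts.loc[:, samples]
    s = size_factors.reindex(samples).to_numpy(dtype=float)
    labels = np.array([groups[smp] for smp in samples])
    design = np.column_stack([np.ones(len(samples)), (labels == a).astype(float)])
    offset = np.log(s)

    results = []
    ynorm = sub.to_numpy(dtype=float) / s[None, :]
    for i, taxon in enumerate(sub.index):
        y = sub.iloc[i].to_numpy(dtype=float)
        if y.sum() == 0:
            results.append(
                NBTestResult(taxon, f"{a}_vs_{b}", np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
            )
            continue
        disp = _mom_dispersion(ynorm[i], labels)
        try:
            res = _fit_nb_glm(y, design, offset, disp)
            beta, se = float(res.params[1]), float(res.bse[1])
            z = beta / se if se > 0 else np.nan
            p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            results.append(
                NBTestResult(
                    taxon, f"{a}_vs_{b}", beta / np.log(2), se / np.log(2), z, p, np.nan, disp
                )
            )
        except Exception as exc:  # noqa: BLE001 - singular fits are data-dependent
            warnings.warn(f"NB fit failed for {taxon}: {exc}")
            results.append(
                NBTestResult(taxon, f"{a}_vs_{b}", np.nan, np.nan, np.nan, np.nan, np.nan, disp, False)
            )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q) if np.isfinite(q) else np.nan
    return results


def nb_lrt_global(
    table,
    size_factors: pd.Series,
    groups: Mapping[str, str],
) -> list[NBTestResult]:
    """Per-taxon likelihood-ratio test of any partition effect.

    Twice the log-likelihood gap between the group-mean NB model and the
    intercept-only model, referred to chi-squared with (g − 1) degrees of
    freedom; requires at least three groups.
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    samples = [s for s in counts.columns if s in groups]
    labels = np.array([groups[s] for s in samples])
    levels = sorted(set(labels))
    g = len(levels)
    if g < 3:
        raise ValueError("global LRT needs at least three groups")
    sub = counts.loc[:, samples]
    s = size_factors.reindex(samples).to_numpy(dtype=float)
    offset = np.log(s)
    design_full = np.column_stack(
        [np.ones(len(samples))] + [(labels == lev).astype(float) for lev in levels[1:]]
    )
    design_null = np.ones((len(samples), 1))

    results = []
    ynorm = sub.to_numpy(dtype=float) / s[None, :]
    for i, taxon in enumerate(sub.index):
        y = sub.iloc[i].to_numpy(dtype=float)
        if y.sum() == 0:
            results.append(NBTestResult(taxon, "global", np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        disp = _mom_dispersion(ynorm[i], labels)
        try:
            full = _fit_nb_glm(y, design_full, offset, disp)
            null = _fit_nb_glm(y, design_null, offset, disp)
            stat = max(0.0, 2.0 * (full.llf - null.llf))
            p = float(chi2_dist.sf(stat, g - 1))
            results.append(NBTestResult(taxon, "global", np.nan, np.nan, float(stat), p, np.nan, disp))
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"NB LRT failed for {taxon}: {exc}")
            results.append(NBTestResult(taxon, "global", np.nan, np.nan, np.nan, np.nan, np.nan, disp, False))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q) if np.isfinite(q) else np.nan
    return results


def results_to_frame(results: list[NBTestResult]) -> pd.DataFrame:
    """Tidy DataFrame (taxon/contrast/log2fc/se/stat/p/q) from test results."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "contrast": r.contrast,
                "log2fc": r.log2fc,
                "se": r.se,
                "stat": r.stat,
                "p": r.p,
                "q": r.q,
                "dispersion": r.dispersion,
                "testable": r.testable,
            }
            for r in results
        ]
    )
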