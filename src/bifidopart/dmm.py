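"""Dirichlet-multinomial mixture (DMM) community typing.

A sample's species counts x (length S, depth n) are modelled as a finite
mixture of Dirichlet-multinomial components::

    P(x) = sum_k pi_k * DM(x | alpha_k)

with DM(x|a) = n!/prod(x_j!) * G(A)/G(n+A) * prod_j G(x_j+a_j)/G(a_j),
A = sum_j a_j.  Fitting is by EM: responsibilities in the E-step, mixture
weights and per-component Dirichlet parameters in the M-step (Minka-style
fixed-point updates on the responsibility-weighted likelihood, a generalised
EM step).  A backtracking safeguard keeps the observed-data log-likelihood
non-decreasing at every iteration.

The number of components k is chosen by minimising BIC over a k range,
refitted under several seeds, with a majority vote of the per-seed argmin k
over a subset of seeds (ties favour the smaller k).  Samples with zero genus
counts never enter the fit; they are attached afterwards as a dedicated
``no_Bif`` class.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.special import gammaln, logsumexp, psi

__all__ = [
    "DMMFit",
    "PartitionAssignment",
    "ContributionMatrix",
    "NO_BIF_LABEL",
    "dirmult_logpmf",
    "fit_dmm",
    "select_k",
    "assign_partitions",
    "scaled_contributions",
    "name_partitions",
]

NO_BIF_LABEL = "no_Bif"

ALPHA_FLOOR = 1e-10  # positivity floor during optimisation (display mask is separate)


@dataclass
class DMMFit:
    """A fitted Dirichlet-multinomial mixture."""

    k: int
    pi: np.ndarray  # (k,)
    alpha: np.ndarray  # (k, S)
    loglik: float
    bic: float
    seed: int
    n_iter: int
    converged: bool
    species: list[str] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        # (k-1) free weights + k*S Dirichlet parameters
        return (self.k - 1) + self.k * self.alpha.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "pi": self.pi.tolist(),
            "alpha": self.alpha.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "species": self.species,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DMMFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            k=d["k"],
            pi=np.asarray(d["pi"]),
            alpha=np.asarray(d["alpha"]),
            loglik=d["loglik"],
            bic=d["bic"],
            seed=d["seed"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            species=d.get("species", []),
        )


@dataclass
class PartitionAssignment:
    """Per-sample partition labels (1..k, or ``no_Bif``) and posteriors."""

    labels: pd.Series  # sample -> int 1..k or NO_BIF_LABEL
    posterior: pd.DataFrame  # fitted samples x components (1..k)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"partition": self.labels.astype(str)})
        out = out.join(self.posterior.add_prefix("post_"), how="left")
        out.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class ContributionMatrix:
    """Per-species contributions scaled to [0, 1] by the species maximum."""

    scaled: pd.DataFrame  # components x species
    composition: pd.DataFrame  # expected within-component compositions
    mask: pd.DataFrame  # True where alpha below the display threshold

    def to_tsv(self, path) -> None:
        self.scaled.rename_axis("component").to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# densities


def dirmult_logpmf(x, alpha) -> float:
    """Log pmf of the Dirichlet-multinomial distribution.

    An empty observation (sum x = 0) has probability one.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValueError("x and alpha must have the same length")
    if (alpha <= 0).any():
        raise ValueError("alpha must be strictly positive")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    n = x.sum()
    if n == 0:
        return 0.0
    A = alpha.sum()
    return float(
        gammaln(n + 1)
        - gammaln(x + 1).sum()
        + gammaln(A)
        - gammaln(n + A)
        + (gammaln(x + alpha) - gammaln(alpha)).sum()
    )


def _dm_logpmf_matrix(X: np.ndarray, alpha: np.ndarray, logcoef: np.ndarray) -> np.ndarray:
    """(n, k) matrix of log DM(x_i | alpha_k); logcoef is the multinomial term."""
    A = alpha.sum(axis=1)  # (k,)
    n_i = X.sum(axis=1)  # (n,)
    ll = gammaln(X[:, None, :] + alpha[None, :, :]).sum(axis=2)
    ll -= gammaln(alpha).sum(axis=1)[None, :]
    ll += gammaln(A)[None, :] - gammaln(n_i[:, None] + A[None, :])
    return ll + logcoef[:, None]


# ---------------------------------------------------------------------------
# M-step


def _moment_alpha(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Method-of-moments Dirichlet start from responsibility-weighted compositions."""
    n_i = X.sum(axis=1)
    comp = X / n_i[:, None]
    W = w.sum()
    m = (w @ comp) / W
    v = (w @ (comp - m) ** 2) / max(W, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_hat = m * (1 - m) / v - 1.0
    a_hat = a_hat[np.isfinite(a_hat) & (a_hat > 0)]
    A0 = float(np.median(a_hat)) if a_hat.size else 10.0
    A0 = float(np.clip(A0, 0.5, 1e5))
    return np.maximum(m * A0, 1e-6)


def _fixed_point_alpha(
    X: np.ndarray,
    z: np.ndarray,
    alpha: np.ndarray,
    n_inner: int = 3,
    tol: float = 1e-10,
) -> np.ndarray:
    """Minka fixed-point update of all component alphas on weighted data.

    alpha_kj <- alpha_kj * num_kj / den_k with
    num_kj = sum_i z_ik [psi(x_ij + a_kj) - psi(a_kj)],
    den_k  = sum_i z_ik [psi(n_i + A_k) - psi(A_k)].
    Each sweep increases the weighted DM likelihood (generalised EM).
    """
    n_i = X.sum(axis=1)
    Z = z.sum(axis=0)  # (k,)
    for _ in range(n_inner):
        A = alpha.sum(axis=1)
        num = np.einsum("ik,ikj->kj", z, psi(X[:, None, :] + alpha[None, :, :]))
        num -= Z[:, None] * psi(alpha)
        den = np.einsum("ik,ik->k", z, psi(n_i[:, None] + A[None, :])) - Z * psi(A)
        den = np.maximum(den, 1e-300)
        new = alpha * num / den[:, None]
        new = np.maximum(new, ALPHA_FLOOR)
        if np.max(np.abs(np.log(new) - np.log(alpha))) < tol:
            alpha = new
            break
        alpha = new
    return alpha


# ---------------------------------------------------------------------------
# EM


def _init_responsibilities(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means on centred log-ratio compositions, one-hot with light smoothing."""
    n = X.shape[0]
    if k == 1:
        return np.ones((n, 1))
    comp = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    clr = np.log(comp)
    clr -= clr.mean(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, labels = kmeans2(clr, k, minit="++", seed=rng, missing="warn")
    # guard against empty clusters from degenerate inits
    for c in range(k):
        if not (labels == c).any():
            labels[rng.integers(0, n)] = c
    z = np.full((n, k), 0.02 / max(k - 1, 1))
    z[np.arange(n), labels] = 0.98
    return z


def _short_em(
    X: np.ndarray,
    logcoef: np.ndarray,
    pi: np.ndarray,
    alpha: np.ndarray,
    n_iter: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """A few unguarded EM sweeps; returns (loglik, pi, alpha)."""
    ll = -np.inf
    for _ in range(n_iter):
        logp = _dm_logpmf_matrix(X, alpha, logcoef)
        logw = np.log(np.maximum(pi, 1e-300))[None, :] + logp
        ll = float(logsumexp(logw, axis=1).sum())
        z = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        pi = z.mean(axis=0)
        alpha = _fixed_point_alpha(X, z, alpha)
    return ll, pi, alpha


def fit_dmm(
    counts,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-3,
    n_init: int = 4,
    species: list[str] | None = None,
) -> DMMFit:
    """Fit a k-component Dirichlet-multinomial mixture by EM.

    `counts` is a samples × species integer array (or DataFrame).  Every row
    must have a positive total; zero-count samples are handled outside the
    fit.  For k > 1 the EM is multi-started: `n_init` k-means
    initialisations each get a few short EM sweeps and the best one is
    continued (a standard small-EM strategy against local optima).
    Convergence is declared when the observed-data log-likelihood changes
    by less than `tol`.
    """
    if isinstance(counts, pd.DataFrame):
        species = species if species is not None else list(counts.columns)
        X = counts.to_numpy(dtype=float)
    else:
        X = np.asarray(counts, dtype=float)
        species = species if species is not None else [f"taxon_{j}" for j in range(X.shape[1])]
    if k < 1:
        raise ValueError("k must be >= 1")
    n, S = X.shape
    if n == 0:
        raise ValueError("empty count matrix")
    n_i = X.sum(axis=1)
    if (n_i <= 0).any():
        raise ValueError("every sample must have a positive total count")

    rng = np.random.default_rng(seed)
    logcoef = gammaln(n_i + 1) - gammaln(X + 1).sum(axis=1)

    def _one_init() -> tuple[np.ndarray, np.ndarray]:
        z0 = _init_responsibilities(X, k, rng)
        pi0 = z0.mean(axis=0)
        a0 = np.stack([_moment_alpha(X, z0[:, c]) for c in range(k)])
        return pi0, _fixed_point_alpha(X, z0, a0, n_inner=5)

    if k > 1 and n_init > 1:
        best_ll, best = -np.inf, None
        for _ in range(n_init):
            ll0, pi0, a0 = _short_em(X, logcoef, *_one_init(), n_iter=3)
            if ll0 > best_ll:
                best_ll, best = ll0, (pi0, a0)
        pi, alpha = best
    else:
        pi, alpha = _one_init()

    history: list[float] = []
    prev_pi, prev_alpha = pi.copy(), alpha.copy()
    reinit_used = np.zeros(k, dtype=bool)
    converged = False
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        logp = _dm_logpmf_matrix(X, alpha, logcoef)
        logw = np.log(np.maximum(pi, 1e-300))[None, :] + logp
        ll = float(logsumexp(logw, axis=1).sum())

        if ll < ll_prev - 1e-8:
            # Backtrack the generalised M-step toward the previous parameters
            # until the likelihood is no longer worse (guaranteed at step 0).
            ok = False
            for _ in range(30):
                alpha = np.sqrt(alpha * prev_alpha)
                pi = 0.5 * (pi + prev_pi)
                pi /= pi.sum()
                logp = _dm_logpmf_matrix(X, alpha, logcoef)
                logw = np.log(np.maximum(pi, 1e-300))[None, :] + logp
                ll = float(logsumexp(logw, axis=1).sum())
                if ll >= ll_prev - 1e-8:
                    ok = True
                    break
            if not ok:
                pi, alpha, ll = prev_pi, prev_alpha, ll_prev
                logp = _dm_logpmf_matrix(X, alpha, logcoef)
                logw = np.log(np.maximum(pi, 1e-300))[None, :] + logp
                converged = True
                history.append(ll)
                break
        history.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

        z = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))

        # empty-component handling: reseed once from a random sample, then
        # allow the component to die
        resp = z.sum(axis=0)
        for c in np.nonzero(resp < 1e-6 * n)[0]:
            if not reinit_used[c]:
                reinit_used[c] = True
                i = int(rng.integers(0, n))
                z[i, :] = 0.0
                z[i, c] = 1.0
                warnings.warn(f"component {c} empty; reinitialised from sample {i}")

        prev_pi, prev_alpha = pi.copy(), alpha.copy()
        pi = z.mean(axis=0)
        alpha = _fixed_point_alpha(X, z, alpha)

    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations (k={k}, seed={seed})")

    loglik = history[-1]
    p = (k - 1) + k * S
    bic = -2.0 * loglik + p * np.log(n)
    return DMMFit(
        k=k,
        pi=pi,
        alpha=alpha,
        loglik=loglik,
        bic=float(bic),
        seed=seed,
        n_iter=it,
        converged=converged,
        species=list(species),
        loglik_history=history,
    )


def select_k(
    counts,
    k_range: tuple[int, int] = (1, 30),
    n_fit_seeds: int = 5,
    n_vote_seeds: int = 3,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of components by the BIC / seed-vote protocol.

    For each of `n_fit_seeds` seeds every k in `k_range` (inclusive) is
    fitted and its BIC recorded.  The argmin-BIC k of the first
    `n_vote_seeds` seeds are collected and the mode returned (ties favour
    the smaller k).  The full per-seed BIC table is returned alongside.
    """
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 1 or k_hi < k_lo:
        raise ValueError("invalid k_range")
    if n_vote_seeds > n_fit_seeds:
        raise ValueError("n_vote_seeds cannot exceed n_fit_seeds")
    seeds = [(int(seed) + 1009 * i) % (2**31) for i in range(n_fit_seeds)]
    ks = list(range(k_lo, k_hi + 1))
    bic = pd.DataFrame(index=ks, columns=seeds, dtype=float)
    bic.index.name = "k"
    for s in seeds:
        for k in ks:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_dmm(counts, k, seed=s, **fit_kwargs)
            bic.loc[k, s] = fit.bic
    votes = [int(bic[s].idxmin()) for s in seeds[:n_vote_seeds]]
    tally = Counter(votes)
    best = max(tally.values())
    selected = min(k for k, c in tally.items() if c == best)
    return selected, bic


def vote_k(per_seed_argmin: list[int]) -> int:
    """Majority vote over per-seed argmin-BIC k values (ties -> smallest k)."""
    tally = Counter(per_seed_argmin)
    best = max(tally.values())
    return min(k for k, c in tally.items() if c == best)


def assign_partitions(fit: DMMFit, counts, zero_bif_ids: Iterable = ()) -> PartitionAssignment:
    """Assign fitted samples to argmax-posterior components; attach no_Bif ids.

    `counts` must be a DataFrame over the same species as the fit (samples as
    rows).  Ties go to the lowest component index.
    """
    if isinstance(counts, pd.DataFrame):
        if fit.species and list(counts.columns) != fit.species:
            counts = counts.loc[:, fit.species]
        X = counts.to_numpy(dtype=float)
        ids = list(counts.index)
    else:
        X = np.asarray(counts, dtype=float)
        ids = [f"sample_{i}" for i in range(X.shape[0])]
    n_i = X.sum(axis=1)
    if (n_i <= 0).any():
        bad = [ids[i] for i in np.nonzero(n_i <= 0)[0]]
        raise ValueError(f"zero-count samples must go through zero_bif_ids: {bad[:5]}")

    logcoef = gammaln(n_i + 1) - gammaln(X + 1).sum(axis=1)
    logp = _dm_logpmf_matrix(X, fit.alpha, logcoef)
    logw = np.log(np.maximum(fit.pi, 1e-300))[None, :] + logp
    post = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    labels = post.argmax(axis=1) + 1  # 1-based, argmax takes the lowest index on ties

    lab = pd.Series(list(labels), index=ids, dtype=object)
    for s in zero_bif_ids:
        lab.loc[s] = NO_BIF_LABEL
    posterior = pd.DataFrame(post, index=ids, columns=[c + 1 for c in range(fit.k)])
    return PartitionAssignment(labels=lab, posterior=posterior)


def scaled_contributions(fit: DMMFit, mask_threshold: float = 1e-5) -> ContributionMatrix:
    """Expected within-component compositions, scaled per species to [0, 1].

    c_kj = alpha_kj / sum_j alpha_kj; each species column is divided by its
    maximum over unmasked components so the dominant component scores 1.
    Entries with alpha below `mask_threshold` are masked (NaN in `scaled`).
    """
    comp = fit.alpha / fit.alpha.sum(axis=1, keepdims=True)
    species = fit.species or [f"taxon_{j}" for j in range(comp.shape[1])]
    idx = [c + 1 for c in range(fit.k)]
    composition = pd.DataFrame(comp, index=idx, columns=species)
    mask = pd.DataFrame(fit.alpha < mask_threshold, index=idx, columns=species)

    vis = composition.where(~mask)
    colmax = vis.max(axis=0)
    scaled = vis / colmax.replace(0.0, np.nan)
    return ContributionMatrix(scaled=scaled, composition=composition, mask=mask)


def _abbrev(species: str) -> str:
    """3-letter mnemonic from the species epithet (B. adolescentis -> ado)."""
    name = species.replace(".", "_").replace(" ", "_")
    parts = [p for p in name.split("_") if p]
    epithet = parts[-1] if len(parts) > 1 else parts[0]
    return epithet[:3].lower()


def name_partitions(
    contribs: ContributionMatrix,
    n_top: int = 3,
    floor: float = 0.05,
    include_no_bif: bool = True,
) -> dict:
    """Mnemonic names from the top species of each component.

    The top `n_top` species by within-component composition, truncated below
    a `floor` composition, are abbreviated to three letters and joined with
    underscores (e.g. ``ado_lon``).  The zero-count class is named
    ``no_Bif``.
    """
    names: dict = {}
    for comp_id, row in contribs.composition.iterrows():
        top = row.sort_values(ascending=False, kind="stable")
        picks = [sp for sp, v in top.head(n_top).items() if v >= floor]
        if not picks:
            picks = [top.index[0]]
        names[comp_id] = "_".join(_abbrev(sp) for sp in picks)
    if include_no_bif:
        names[NO_BIF_LABEL] = NO_BIF_LABEL
    return names
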