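"""Univariate Gaussian mixtures: regularized EM, BIC selection, densities.

The model is the finite mixture likelihood

    p(D) = prod_n  sum_i  pi_i N(x_n | mu_i, sigma_i^2)

fitted by expectation-maximization from kmeans++ initializations with
multiple restarts.  Likelihood singularities — a component collapsing all
of its variance onto a single observation, sending the likelihood to
infinity — are prevented by a regularization constant added to each
component variance at every M-step (the univariate reading of adding a
small value to the diagonal of a covariance matrix).  With the default
0.001 no fitted variance can fall below 0.001.

The number of components is chosen by the Bayesian information criterion,
``BIC = -2 loglik + p ln(n)`` with ``p = 3k - 1`` free parameters (k
means, k variances, k - 1 independent weights); lower is better, and a
difference of 10 or more on the natural-log scale is treated as strong
evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "MixtureComponent",
    "FitConfig",
    "GmmFit",
    "SelectionSweep",
    "kmeanspp_seed",
    "em_fit",
    "bic",
    "sweep_and_select",
    "responsibilities",
    "mixture_density",
    "mixture_cdf",
    "STRONG_EVIDENCE_DELTA_BIC",
]

STRONG_EVIDENCE_DELTA_BIC = 10.0

# numerical floor when regularization is disabled, to keep densities finite
_COLLAPSE_FLOOR = 1e-12


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    variance: float


@dataclass(frozen=True)
class FitConfig:
    """EM settings: component count, regularization, restarts, stopping rule."""

    k: int = 1
    regularization: float = 0.001
    restarts: int = 50
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DomainError("k must be >= 1")
        if self.restarts < 1:
            raise DomainError("restarts must be >= 1")
        if self.regularization < 0:
            raise DomainError("regularization must be >= 0")


@dataclass(frozen=True)
class GmmFit:
    """A fitted k-component mixture; components are sorted by mean."""

    components: tuple[MixtureComponent, ...]
    loglik: float
    bic: float
    converged: bool
    n_iterations: int
    seed: int
    n: int
    degenerate: bool = False
    # per-iteration log-likelihood of the winning restart (ascent diagnostic)
    loglik_trace: tuple[float, ...] = field(default=(), repr=False, compare=False)

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def variances(self) -> np.ndarray:
        return np.array([c.variance for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [
                {"weight": c.weight, "mean": c.mean, "variance": c.variance}
                for c in self.components
            ],
            "loglik": self.loglik,
            "bic": self.bic,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "n": self.n,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GmmFit":
        return cls(
            components=tuple(
                MixtureComponent(c["weight"], c["mean"], c["variance"])
                for c in payload["components"]
            ),
            loglik=payload["loglik"],
            bic=payload["bic"],
            converged=payload["converged"],
            n_iterations=payload["n_iterations"],
            seed=payload["seed"],
            n=payload["n"],
            degenerate=payload.get("degenerate", False),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GmmFit":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SelectionSweep:
    """BIC sweep over k = 1..kmax; the winner minimizes BIC."""

    fits: Mapping[int, GmmFit]
    winner_k: int
    delta_bic_runner_up: float

    @property
    def winner(self) -> GmmFit:
        return self.fits[self.winner_k]

    @property
    def strong_evidence(self) -> bool:
        return self.delta_bic_runner_up >= STRONG_EVIDENCE_DELTA_BIC

    def bic_curve(self) -> dict[int, float]:
        return {k: f.bic for k, f in sorted(self.fits.items())}

    def to_dict(self) -> dict:
        return {
            "winner_k": self.winner_k,
            "delta_bic_runner_up": self.delta_bic_runner_up,
            "strong_evidence": self.strong_evidence,
            "fits": {str(k): f.to_dict() for k, f in self.fits.items()},
        }


def kmeanspp_seed(data, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k initial centers from the data by the kmeans++ rule.

    The first center is uniform over observations; each subsequent center
    is an observation sampled with probability proportional to its squared
    distance to the nearest center already chosen.  If every remaining
    distance is zero (duplicated data), the next center falls back to a
    uniform draw.
    """
    x = np.asarray(data, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise DomainError("data must be non-empty")
    if k > n:
        raise DomainError(f"k = {k} exceeds number of observations n = {n}")
    centers = np.empty(k)
    centers[0] = x[rng.integers(n)]
    d2 = (x - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = x[rng.integers(n)]
        else:
            centers[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, (x - centers[j]) ** 2)
    return centers


def _log_mixture_matrix(x: np.ndarray, w, mu, var) -> np.ndarray:
    """log(pi_i N(x_n | mu_i, var_i)) for batched parameter arrays.

    ``x`` has shape (n,); parameter arrays share a leading batch shape
    ending in k.  Returns shape ``batch + (n, k)``.
    """
    w = np.asarray(w, float)[..., None, :]
    mu = np.asarray(mu, float)[..., None, :]
    var = np.asarray(var, float)[..., None, :]
    xe = x[:, None]
    with np.errstate(divide="ignore"):
        return (
            np.log(w)
            - 0.5 * np.log(2.0 * np.pi * var)
            - (xe - mu) ** 2 / (2.0 * var)
        )


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis)
    return out


def em_fit(data, config: FitConfig) -> GmmFit:
    """Fit a k-component mixture by multi-restart regularized EM.

    Runs ``config.restarts`` EM chains from independent kmeans++
    initializations (all restarts advance in lock-step as one batched
    computation) and returns the chain with the highest final
    log-likelihood; ties break toward the lowest restart index.  A chain
    stops when the relative log-likelihood improvement falls below
    ``tol``.  Because the additive variance regularizer is applied after
    the M-step, the likelihood could in principle slip at a fixed point
    by a vanishing amount; a chain whose log-likelihood fails to improve
    is therefore frozen at its previous (better) parameters, which keeps
    the recorded trace non-decreasing.
    """
    x = np.asarray(data, dtype=float).ravel()
    n = x.size
    k = config.k
    if n < k:
        raise DomainError(f"need at least k = {k} observations, got {n}")
    reg = config.regularization
    floor = reg if reg > 0 else _COLLAPSE_FLOOR
    R = config.restarts
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(R)]

    # initialization: kmeans++ centers, hard-assignment moments
    mu = np.empty((R, k))
    var = np.empty((R, k))
    w = np.full((R, k), 1.0 / k)
    overall_var = float(np.var(x)) + floor
    for r in range(R):
        centers = kmeanspp_seed(x, k, rngs[r])
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            mask = assign == j
            if mask.any():
                mu[r, j] = x[mask].mean()
                var[r, j] = x[mask].var() + floor
                w[r, j] = mask.mean()
            else:
                mu[r, j] = centers[j]
                var[r, j] = overall_var
                w[r, j] = 1.0 / n
        w[r] /= w[r].sum()

    active = np.ones(R, dtype=bool)
    converged = np.zeros(R, dtype=bool)
    iters = np.zeros(R, dtype=int)
    ll = np.full(R, -np.inf)
    traces: list[list[float]] = [[] for _ in range(R)]
    prev_params = [None] * R

    for _ in range(config.max_iter):
        log_mat = _log_mixture_matrix(x, w[active], mu[active], var[active])
        ll_n = _logsumexp(log_mat, axis=-1)  # (A, n)
        ll_new = ll_n.sum(axis=-1)
        idx_active = np.flatnonzero(active)
        resp = np.exp(log_mat - ll_n[..., None])  # (A, n, k)

        # bookkeeping + stopping decisions per active chain
        drop = []
        for a, r in enumerate(idx_active):
            if ll_new[a] < ll[r] - 1e-10:
                # likelihood slipped at a fixed point: freeze at previous params
                mu[r], var[r], w[r] = prev_params[r]
                converged[r] = True
                drop.append(r)
                continue
            traces[r].append(float(ll_new[a]))
            improved = ll_new[a] - ll[r]
            denom = max(abs(ll[r]), 1.0)
            ll[r] = ll_new[a]
            iters[r] += 1
            if np.isfinite(improved) and improved <= config.tol * denom:
                converged[r] = True
                drop.append(r)
        # M-step for chains still running
        nk = resp.sum(axis=1)  # (A, k)
        nk = np.maximum(nk, 1e-300)
        w_new = nk / n
        mu_new = (resp * x[None, :, None]).sum(axis=1) / nk
        var_new = (resp * (x[None, :, None] - mu_new[:, None, :]) ** 2).sum(axis=1) / nk
        var_new = var_new + reg
        var_new = np.maximum(var_new, floor)
        for a, r in enumerate(idx_active):
            prev_params[r] = (mu[r].copy(), var[r].copy(), w[r].copy())
            if r not in drop:
                mu[r], var[r], w[r] = mu_new[a], var_new[a], w_new[a]
        for r in drop:
            active[r] = False
        if not active.any():
            break

    best = int(np.argmax(ll))
    order = np.argsort(mu[best], kind="stable")
    w_b, mu_b, var_b = w[best][order], mu[best][order], var[best][order]
    w_b = w_b / w_b.sum()
    degenerate = bool(
        (reg == 0 and var_b.min() <= _COLLAPSE_FLOOR * 10)
        or (k > 1 and np.ptp(x) == 0)
        or not np.isfinite(ll[best])
    )
    loglik = float(ll[best])
    fit = GmmFit(
        components=tuple(
            MixtureComponent(float(wi), float(mi), float(vi))
            for wi, mi, vi in zip(w_b, mu_b, var_b)
        ),
        loglik=loglik,
        bic=_bic_value(loglik, k, n),
        converged=bool(converged[best]),
        n_iterations=int(iters[best]),
        seed=config.seed,
        n=n,
        degenerate=degenerate,
        loglik_trace=tuple(traces[best]),
    )
    return fit


def _bic_value(loglik: float, k: int, n: int) -> float:
    return -2.0 * loglik + (3 * k - 1) * np.log(n)


def bic(fit: GmmFit, n: int) -> float:
    """BIC of a fitted mixture at sample size n: -2 loglik + (3k-1) ln n."""
    if n < 1:
        raise DomainError("n must be >= 1")
    return float(_bic_value(fit.loglik, fit.k, n))


def sweep_and_select(data, kmax: int, config: FitConfig | None = None) -> SelectionSweep:
    """Fit k = 1..kmax mixtures and select the minimum-BIC model.

    All fits share the sweep's configuration; each k receives its own
    substream of the master seed so results are reproducible and fits for
    different k are independent.
    """
    if kmax < 1:
        raise DomainError("kmax must be >= 1")
    if config is None:
        config = FitConfig()
    x = np.asarray(data, dtype=float).ravel()
    kmax = min(kmax, x.size)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(kmax)]
    fits: dict[int, GmmFit] = {}
    for k in range(1, kmax + 1):
        fits[k] = em_fit(x, replace(config, k=k, seed=seeds[k - 1]))
    ks = sorted(fits)
    bics = np.array([fits[k].bic for k in ks])
    winner_k = ks[int(np.argmin(bics))]
    if len(ks) > 1:
        delta = float(np.partition(bics, 1)[1] - bics.min())
    else:
        delta = 0.0
    return SelectionSweep(fits=fits, winner_k=winner_k, delta_bic_runner_up=delta)


def responsibilities(fit: GmmFit, data) -> np.ndarray:
    """Posterior component-membership probabilities, one row per point.

    Rows sum to one; the argmax column gives the hard assignment used to
    cross-tabulate components against subfield and null labels.
    """
    x = np.asarray(data, dtype=float).ravel()
    log_mat = _log_mixture_matrix(x, fit.weights, fit.means, fit.variances)
    ll_n = _logsumexp(log_mat, axis=-1)
    return np.exp(log_mat - ll_n[..., None])


def mixture_density(fit: GmmFit, grid) -> np.ndarray:
    """Mixture density  sum_i pi_i N(x; mu_i, sigma_i^2)  on a grid."""
    g = np.asarray(grid, dtype=float)
    out = np.zeros_like(g)
    for c in fit.components:
        out += c.weight * stats.norm.pdf(g, loc=c.mean, scale=np.sqrt(c.variance))
    return out


def mixture_cdf(fit: GmmFit, x) -> np.ndarray:
    """Mixture CDF at x (vectorized)."""
    g = np.asarray(x, dtype=float)
    out = np.zeros_like(g)
    for c in fit.components:
        out += c.weight * stats.norm.cdf(g, loc=c.mean, scale=np.sqrt(c.variance))
    return out
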