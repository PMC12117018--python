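"""Seeded univariate Gaussian-mixture EM with information-criterion selection.

Doubling-time distributions are modelled as a mixture of K Gaussians; K is
chosen by minimising AIC (BIC available) over 1..max_K. The fit is
deterministic under a seed: initial means come from a k-means++-style
distance-weighted draw and the best of ``n_init`` restarts (by final
log-likelihood) is kept. The per-iteration log-likelihood trajectory is
exposed so the EM monotonicity guarantee can be checked directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_LOG2PI = np.log(2 * np.pi)
_SIGMA_FLOOR = 1e-6


@dataclass
class MixtureFit:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    cutoffs: np.ndarray  # K-1 posterior-equality boundaries between adjacent means
    criterion: str
    criterion_value: float
    log_likelihood: float
    loglik_trace: np.ndarray
    criterion_table: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False

    def posterior(self, x) -> np.ndarray:
        """Component posterior probabilities at points ``x`` (shape (n, K))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        logp = _log_weighted_pdf(x, self.means, self.sds, self.weights)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def classify(self, x) -> np.ndarray:
        """Maximum-posterior component index for each point."""
        return self.posterior(x).argmax(axis=1)


def _log_weighted_pdf(x, means, sds, weights):
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (z**2 + _LOG2PI)


def _loglik(x, means, sds, weights) -> float:
    lw = _log_weighted_pdf(x, means, sds, weights)
    m = lw.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(lw - m).sum(axis=1))).sum())


def _kmeanspp_means(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    means = [x[rng.integers(len(x))]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            means.append(x[rng.integers(len(x))])
        else:
            means.append(x[rng.choice(len(x), p=d2 / total)])
    return np.array(sorted(means))


def _em_once(x, k, rng, max_iter, tol, init=None):
    n = len(x)
    if init is None:
        means = _kmeanspp_means(x, k, rng)
        sds = np.full(k, max(x.std(), _SIGMA_FLOOR))
        weights = np.full(k, 1.0 / k)
    else:
        means, sds, weights = (np.array(v, dtype=float) for v in init)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        lw = _log_weighted_pdf(x, means, sds, weights)
        m = lw.max(axis=1, keepdims=True)
        p = np.exp(lw - m)
        norm = p.sum(axis=1, keepdims=True)
        ll = float((m[:, 0] + np.log(norm[:, 0])).sum())
        trace.append(ll)
        resp = p / norm
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    ll = _loglik(x, means, sds, weights)
    trace.append(ll)
    return means, sds, weights, ll, np.array(trace)


def _posterior_cutoffs(means, sds, weights) -> np.ndarray:
    """Boundary between adjacent components where weighted densities are equal."""
    cuts = []
    for i in range(len(means) - 1):
        lo, hi = means[i], means[i + 1]

        def diff(x, i=i):
            lx = np.array([x])
            lw = _log_weighted_pdf(lx, means, sds, weights)
            return lw[0, i] - lw[0, i + 1]

        a, b = lo + 1e-9, hi - 1e-9
        if hi - lo < 1e-12 or diff(a) * diff(b) > 0:
            cuts.append(0.5 * (lo + hi))
        else:
            cuts.append(float(optimize.brentq(diff, a, b)))
    return np.array(cuts)


def fit_gaussian_mixture(
    x,
    max_k: int = 3,
    criterion: str = "aic",
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> MixtureFit:
    """Fit mixtures for K = 1..max_k and keep the criterion-minimising one.

    Parameters per model: K means + K sds + (K-1) weights = 3K - 1.
    Degenerate samples (zero variance) return a flagged K=1 fit with a
    floored sigma.
    """
    x = np.asarray(x, dtype=float).ravel()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if len(x) < max_k * 5:
        raise ValueError(f"need >= {max_k * 5} observations for max_k={max_k}")
    n = len(x)
    if x.std() == 0:
        means = np.array([x[0]])
        sds = np.array([_SIGMA_FLOOR])
        ll = _loglik(x, means, sds, np.ones(1))
        return MixtureFit(
            k=1, means=means, sds=sds, weights=np.ones(1), cutoffs=np.array([]),
            criterion=criterion, criterion_value=np.nan, log_likelihood=ll,
            loglik_trace=np.array([ll]), degenerate=True,
        )
    rng = np.random.default_rng(seed)
    best = None
    table: dict[int, float] = {}
    for k in range(1, max_k + 1):
        # short EM runs from each seeded restart, then converge the best
        best_k = None
        for _ in range(n_init if k > 1 else 1):
            fit = _em_once(x, k, rng, min(30, max_iter), tol)
            if best_k is None or fit[3] > best_k[3]:
                best_k = fit
        means, sds, weights, ll, head = best_k
        means, sds, weights, ll, tail = _em_once(
            x, k, rng, max_iter, tol, init=(means, sds, weights)
        )
        trace = np.concatenate([head, tail])
        p = 3 * k - 1
        crit = 2 * p - 2 * ll if criterion == "aic" else p * np.log(n) - 2 * ll
        table[k] = float(crit)
        if best is None or crit < best[0]:
            best = (crit, k, means, sds, weights, ll, trace)
    crit, k, means, sds, weights, ll, trace = best
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    return MixtureFit(
        k=k, means=means, sds=sds, weights=weights,
        cutoffs=_posterior_cutoffs(means, sds, weights),
        criterion=criterion, criterion_value=float(crit), log_likelihood=ll,
        loglik_trace=trace, criterion_table=table,
    )


def mixture_pdf(fit: MixtureFit, x) -> np.ndarray:
    """Density of the fitted mixture at points ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.sum(
        fit.weights[None, :]
        * stats.norm.pdf(x[:, None], fit.means[None, :], fit.sds[None, :]),
        axis=1,
    )
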