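"""Ks age distributions and finite-mixture WGD peak dating.

A paranome's duplicate-pair Ks values form an age distribution: a decay
of small-scale duplications plus, after a whole-genome duplication, a
burst of similarly aged pairs that appears as a peak.  This module
truncates the distribution (Ks > 5 dropped as saturated, a small lower
bound dropping allelic/identical artifacts), fits log-normal mixtures —
Gaussian components on ln Ks, so each component's reported median is
``exp(mu)`` — by expectation-maximisation with random restarts, selects
the component count by BIC, and reports the component medians as peaks.

The EM implementation asserts its own log-likelihood monotonicity at
every iteration and is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

log = logging.getLogger(__name__)

KS_MAX_DEFAULT = 5.0
KS_MIN_DEFAULT = 0.01


class MixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class KsDistribution:
    """Truncated Ks values of retained duplicate pairs."""

    values: np.ndarray
    ks_min: float = KS_MIN_DEFAULT
    ks_max: float = KS_MAX_DEFAULT
    n_excluded: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size and ((v <= self.ks_min).any() or (v > self.ks_max).any()):
            raise ValueError("Ks values outside the truncation window")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class KsMixtureFit:
    """A fitted log-normal mixture over a truncated Ks distribution."""

    k: int
    weights: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    loglik: float
    bic: float
    n: int
    converged: bool
    seed: int
    loglik_trace: tuple = ()

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights do not sum to 1")
        if (self.sigma <= 0).any():
            raise ValueError("non-positive component sigma")

    @property
    def medians(self) -> np.ndarray:
        """Component medians on the Ks scale, ascending."""
        return np.sort(np.exp(self.mu))


def build_ks_distribution(
    estimates: pd.DataFrame,
    ks_min: float = KS_MIN_DEFAULT,
    ks_max: float = KS_MAX_DEFAULT,
) -> KsDistribution:
    """Filter a Ka/Ks table into a truncated Ks distribution.

    Retains ok-status estimates with ``ks_min < ks <= ks_max``; exclusion
    counts are kept by reason (saturated/undefined status, out of range).
    """
    if len(estimates) == 0:
        raise ValueError("no Ka/Ks estimates supplied")
    status = estimates["status"].to_numpy()
    ks = estimates["ks"].to_numpy(dtype=float)
    ok = status == "ok"
    in_range = ok & np.isfinite(ks) & (ks > ks_min) & (ks <= ks_max)
    excl = {
        "saturated": int((status == "saturated").sum()),
        "undefined": int((status == "undefined").sum()),
        "out_of_range": int((ok & ~in_range).sum()),
    }
    values = ks[in_range]
    if values.size == 0:
        raise ValueError(
            f"all {len(estimates)} estimates excluded ({excl}); "
            "review the Ks truncation thresholds"
        )
    log.info("Ks distribution: %d retained, excluded %s", values.size, excl)
    return KsDistribution(values, ks_min, ks_max, excl)


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, list[float]]:
    n = x.size
    mu = rng.choice(x, size=k, replace=False)
    sigma = np.full(k, max(x.std(), 1e-2))
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E step
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sigma)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        if ll < prev_ll - 1e-8:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
            )
        trace.append(ll)
        resp = np.exp(logp - norm[:, None])
        if not np.allclose(resp.sum(axis=1), 1.0, atol=1e-8):
            raise AssertionError("EM responsibilities do not normalise")
        # relative tolerance on the log-likelihood improvement
        if ll - prev_ll < tol * (1.0 + abs(ll)) and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        if (nk < 2.0) .any():
            raise MixtureError("empty component")
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(var)
        if (sigma < 1e-3).any():
            if k == 1:
                # a single component owning all data may legitimately be a
                # point mass; floor its scale instead of failing
                sigma = np.maximum(sigma, 1e-3)
            else:
                raise MixtureError("degenerate component (sigma < 1e-3)")
    return w, mu, sigma, trace[-1], converged, trace


def fit_mixture_em(
    dist: KsDistribution,
    k: int,
    seed: int,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> KsMixtureFit:
    """Fit a k-component log-normal mixture to a Ks distribution.

    The best of ``n_restarts`` random initialisations (by log-likelihood)
    is returned; restarts ending in a degenerate component are discarded.
    BIC uses ``3k - 1`` free parameters.
    """
    if dist.n < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}, have {dist.n}")
    x = np.log(dist.values)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        try:
            res = _em_once(x, k, rng, tol, max_iter)
        except MixtureError:
            continue
        if best is None or res[3] > best[3]:
            best = res
    if best is None:
        raise MixtureError(f"all {n_restarts} EM restarts degenerate for k={k}")
    w, mu, sigma, ll, converged, trace = best
    order = np.argsort(mu)
    bic = -2.0 * ll + (3 * k - 1) * np.log(dist.n)
    return KsMixtureFit(
        k, w[order], mu[order], sigma[order], ll, float(bic), dist.n,
        converged, seed, tuple(trace),
    )


def select_components(
    dist: KsDistribution,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[KsMixtureFit, pd.DataFrame]:
    """Fit every component count in ``k_range`` and return the minimal-BIC
    fit together with the full model table."""
    rows = []
    fits: dict[int, KsMixtureFit] = {}
    for k in k_range:
        if dist.n < 10 * k:
            log.warning("skipping k=%d: only %d values", k, dist.n)
            continue
        fit = fit_mixture_em(dist, k, seed=seed + k, n_restarts=n_restarts)
        fits[k] = fit
        rows.append((k, fit.loglik, fit.bic, fit.converged))
    if not fits:
        raise MixtureError("no component count could be fitted")
    table = pd.DataFrame(rows, columns=["k", "loglik", "bic", "converged"])
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    return fits[best_k], table


def report_peaks(fit: KsMixtureFit, min_weight: float = 0.05) -> pd.DataFrame:
    """Tabulate mixture components with weight >= ``min_weight`` as WGD
    peaks, ascending by median Ks."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge; peaks not reported")
    rows = [
        (float(np.exp(m)), float(w), float(m), float(s))
        for w, m, s in zip(fit.weights, fit.mu, fit.sigma)
        if w >= min_weight
    ]
    rows.sort(key=lambda r: r[0])
    return pd.DataFrame(rows, columns=["median_ks", "weight", "mu_ln", "sigma_ln"])
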