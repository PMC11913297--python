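"""Weighted EM for the minimum cross-entropy estimator (MCE).

Minimizing the approximate cross-entropy over a Gaussian mixture family is a
weighted maximum-likelihood problem: each sampled point carries its
importance weight w_i, and the objective

    ACE(theta) = -(1/n) sum_i w_i log q_theta(x_i)

is decreased monotonically by an EM iteration in which the E-step computes
responsibilities gamma_ij under the current mixture and the M-step uses the
combined masses m_ij = w_i * gamma_ij:

    pi_j    = sum_i m_ij / sum_i w_i
    mu_j    = sum_i m_ij x_i / sum_i m_ij
    Sigma_j = sum_i m_ij (x_i - mu_j)(x_i - mu_j)^T / sum_i m_ij

followed by an eigenvalue floor on each Sigma_j. With constant weights this
is exactly the classical EM for the MLE; with k = 1 a single step lands on
the closed-form weighted mean and covariance.

Rare-event targets concentrate almost all weight on a handful of points, so
component collapse (vanishing mass, or a covariance pinned at the floor) is
expected and handled by re-seeding the collapsed component; a restart that
keeps collapsing is abandoned.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .ace import SampleArchive, ace
from .errors import FitFailedError, InsufficientSupportError, InvalidArgumentError
from .model_space import (
    GaussianMixtureParams,
    _component_log_densities,
    floor_covariance,
    param_dimension,
)

__all__ = ["EMOptions", "EMTrace", "init_params", "em_step", "fit_mce"]

# component mass below this fraction of total weight counts as collapsed
_MASS_COLLAPSE_FRAC = 1e-12
# consecutive iterations with a floored covariance before re-seeding
_FLOOR_PATIENCE = 3
# re-seeds allowed per restart before abandoning it
_MAX_RESEEDS = 2


@dataclasses.dataclass(frozen=True)
class EMOptions:
    """Knobs for the EM optimizer.

    rel_tol is the relative change in ACE below which iteration stops;
    eps_cov scales the covariance eigenvalue floor relative to the weighted
    data variance.
    """

    max_iters: int = 500
    rel_tol: float = 1e-6
    n_restarts: int = 4
    seed: int = 0
    eps_cov: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iters < 1 or self.rel_tol <= 0 or self.n_restarts < 1 or self.eps_cov <= 0:
            raise InvalidArgumentError("invalid EM options")


@dataclasses.dataclass
class EMTrace:
    """Diagnostics of one accepted EM run: the per-iteration ACE path
    (non-increasing up to 1e-9), iteration count, convergence flag, and
    which restart won."""

    objective_path: np.ndarray
    n_iters: int
    converged: bool
    restart_index: int


def _weighted_moments(points: np.ndarray, weights: np.ndarray):
    wsum = weights.sum()
    mean = weights @ points / wsum
    dev = points - mean
    cov = (weights[:, None] * dev).T @ dev / wsum
    return mean, cov


def _cov_floor(points: np.ndarray, weights: np.ndarray, eps_cov: float) -> float:
    """Absolute eigenvalue floor: eps_cov times the mean weighted variance
    across coordinates, with a tiny absolute fallback for degenerate data."""
    _, cov = _weighted_moments(points, weights)
    scale = float(np.trace(cov)) / points.shape[1]
    return max(eps_cov * scale, 1e-12)


def init_params(
    points: np.ndarray,
    weights: np.ndarray,
    k: int,
    seed: "int | np.random.Generator",
    eps_cov: float = 1e-6,
) -> GaussianMixtureParams:
    """Initial mixture for EM by weighted k-means++-style seeding.

    Means are drawn (without replacement) from the positively weighted
    points: the first with probability proportional to its weight, each
    subsequent one proportional to weight times squared distance to the
    nearest already-chosen mean. All covariances start at the global
    weighted covariance (eigenvalue-floored); mixing weights start uniform.
    Deterministic given the seed.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    pos = np.flatnonzero(w > 0)
    if pos.size < k:
        raise InsufficientSupportError(
            f"need at least {k} positively weighted points, have {pos.size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xp, wp = x[pos], w[pos]

    floor = _cov_floor(x, w, eps_cov)
    if k == 1:
        # closed form: the weighted mean and covariance are the exact MCE
        mean, cov = _weighted_moments(x, w)
        return GaussianMixtureParams(
            weights=np.ones(1),
            means=mean[None, :],
            covariances=floor_covariance(cov, floor)[None, :, :],
        )

    chosen = [int(rng.choice(pos.size, p=wp / wp.sum()))]
    d2 = np.sum((xp - xp[chosen[0]]) ** 2, axis=1)
    for _ in range(1, k):
        score = wp * d2
        score[chosen] = 0.0
        if score.sum() <= 0:  # duplicate points: fall back to weight-only draw
            score = wp.copy()
            score[chosen] = 0.0
        nxt = int(rng.choice(pos.size, p=score / score.sum()))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((xp - xp[nxt]) ** 2, axis=1))

    _, gcov = _weighted_moments(x, w)
    gcov = floor_covariance(gcov, floor)
    p = x.shape[1]
    return GaussianMixtureParams(
        weights=np.full(k, 1.0 / k),
        means=xp[chosen].copy(),
        covariances=np.broadcast_to(gcov, (k, p, p)).copy(),
    )


def _e_step(params: GaussianMixtureParams, x: np.ndarray):
    """Responsibilities (n, k), computed in log space."""
    comp = _component_log_densities(params, x)
    with np.errstate(divide="ignore"):
        logits = comp + np.log(params.weights)[None, :]
    log_norm = logsumexp(logits, axis=1)
    # points where every component underflows get uniform responsibilities
    bad = np.isneginf(log_norm)
    gamma = np.exp(logits - np.where(bad, 0.0, log_norm)[:, None])
    if np.any(bad):
        gamma[bad] = 1.0 / params.k
    return gamma


def _m_step(x, w, gamma, floor):
    """Returns (params, masses, floored) — masses m_j = sum_i w_i gamma_ij,
    floored[j] True when Sigma_j hit the eigenvalue floor."""
    k = gamma.shape[1]
    p = x.shape[1]
    m = w[:, None] * gamma  # (n, k)
    masses = m.sum(axis=0)
    wsum = w.sum()
    pi = masses / wsum
    means = np.empty((k, p))
    covs = np.empty((k, p, p))
    floored = np.zeros(k, dtype=bool)
    for j in range(k):
        if masses[j] <= _MASS_COLLAPSE_FRAC * wsum:
            means[j] = 0.0
            covs[j] = np.eye(p) * floor
            floored[j] = True
            continue
        means[j] = m[:, j] @ x / masses[j]
        dev = x - means[j]
        cov = (m[:, j][:, None] * dev).T @ dev / masses[j]
        vals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
        floored[j] = vals[0] < floor
        covs[j] = floor_covariance(cov, floor)
    pi = np.maximum(pi, 0.0)
    pi = pi / pi.sum()
    return GaussianMixtureParams(weights=pi, means=means, covariances=covs), masses, floored


def em_step(
    params: GaussianMixtureParams,
    points: np.ndarray,
    weights: np.ndarray,
    eps_cov: float = 1e-6,
) -> GaussianMixtureParams:
    """One E+M iteration of weighted EM; never increases the ACE."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise InvalidArgumentError("weights must have positive sum")
    floor = _cov_floor(x, w, eps_cov)
    gamma = _e_step(params, x)
    new_params, _, _ = _m_step(x, w, gamma, floor)
    return new_params


class _RestartCollapsed(Exception):
    pass


def _ace_arrays(params: GaussianMixtureParams, x, w, n) -> float:
    from .model_space import gmm_log_density

    logq = gmm_log_density(params, x)
    pos = w > 0
    if np.any(np.isneginf(logq[pos])):
        return float("inf")
    return float(-np.sum(w[pos] * logq[pos]) / n)


def _run_one_restart(x, w, n, k, options: EMOptions, rng) -> tuple:
    floor = _cov_floor(x, w, options.eps_cov)
    params = init_params(x, w, k, rng, options.eps_cov)
    path = [_ace_arrays(params, x, w, n)]
    wsum = w.sum()
    floor_streak = np.zeros(k, dtype=int)
    n_reseeds = 0
    converged = False
    it = 0
    for it in range(1, options.max_iters + 1):
        gamma = _e_step(params, x)
        new_params, masses, floored = _m_step(x, w, gamma, floor)

        floor_streak = np.where(floored, floor_streak + 1, 0)
        collapsed = (masses <= _MASS_COLLAPSE_FRAC * wsum) | (floor_streak >= _FLOOR_PATIENCE)
        if np.any(collapsed):
            n_reseeds += int(np.sum(collapsed))
            if n_reseeds > _MAX_RESEEDS:
                raise _RestartCollapsed()
            new_params = _reseed_components(
                new_params, np.flatnonzero(collapsed), x, w, gamma, floor
            )
            floor_streak[collapsed] = 0
            params = new_params
            # re-seeding may raise the objective; restart the recorded path so
            # the reported trace covers the final monotone descent only
            path = [_ace_arrays(params, x, w, n)]
            continue

        params = new_params
        obj = _ace_arrays(params, x, w, n)
        prev = path[-1]
        path.append(obj)
        if np.isfinite(obj) and np.isfinite(prev):
            denom = max(abs(prev), 1e-12)
            if abs(prev - obj) <= options.rel_tol * denom:
                converged = True
                break
    return params, np.asarray(path), it, converged


def _reseed_components(params, dead, x, w, gamma, floor):
    """Re-seed collapsed components at the highest-weight points whose best
    responsibility currently lies elsewhere."""
    best = np.argmax(gamma, axis=1)
    weights = params.weights.copy()
    means = params.means.copy()
    covs = params.covariances.copy()
    claimed: set = set()
    _, gcov = _weighted_moments(x, w)
    gcov = floor_covariance(gcov, floor)
    for j in dead:
        candidates = np.flatnonzero((best != j) & (w > 0))
        candidates = [c for c in candidates if c not in claimed]
        if not candidates:
            candidates = [int(np.argmax(w))]
        pick = candidates[int(np.argmax(w[candidates]))]
        claimed.add(pick)
        means[j] = x[pick]
        covs[j] = gcov
        weights[j] = 1.0 / len(weights)
    weights = weights / weights.sum()
    return GaussianMixtureParams(weights=weights, means=means, covariances=covs)


def fit_mce(
    archive: SampleArchive,
    k: int,
    options: EMOptions,
    stages: Optional[Sequence[int]] = None,
    stream_key: tuple = (),
) -> tuple:
    """Fit the k-component mixture minimizing the (cumulative) ACE.

    Runs ``options.n_restarts`` independently seeded initializations, each
    iterated to tolerance, and returns ``(params, trace)`` for the restart
    with the lowest final ACE (ties broken by lowest restart index). The
    final ACE in ``trace.objective_path[-1]`` equals
    ``ace(archive, params, stages)``.

    `stream_key` namespaces the random streams so that fits for different
    (stage, k) pairs draw independent randomness from one root seed.

    Raises ``InsufficientSupportError`` when fewer than k points carry
    positive weight, and ``FitFailedError`` when every restart collapses.
    """
    x, w, n = archive.concat(stages)
    if np.flatnonzero(w > 0).size < k:
        raise InsufficientSupportError(
            f"need at least {k} positively weighted points for k={k}"
        )
    best = None
    for restart in range(options.n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(options.seed, spawn_key=tuple(stream_key) + (k, restart))
        )
        try:
            params, path, n_iters, converged = _run_one_restart(x, w, n, k, options, rng)
        except (_RestartCollapsed, InsufficientSupportError):
            continue
        final = path[-1]
        if best is None or final < best[0]:
            best = (final, params, EMTrace(path, n_iters, converged, restart))
    if best is None:
        raise FitFailedError(f"all {options.n_restarts} restarts collapsed for k={k}")
    return best[1], best[2]
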