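"""Gaussian mixture approximating family.

The approximation problem posits a parametric family ``{q_theta}`` from which
the member closest (in KL divergence) to the target density ``q* = r / rho``
is sought. This module implements the Gaussian mixture family on ``R^p``:
parameter container with validation, numerically stable log-density,
sampling, the free-parameter dimension ``d`` used by the information
criterion's complexity penalty, and JSON (de)serialization.

Densities are evaluated through per-component Cholesky factors and combined
with a log-sum-exp, so that mixtures whose component densities span many
orders of magnitude (typical when approximating rare-event targets) remain
stable.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, solve_triangular
from scipy.special import logsumexp

from .errors import InvalidArgumentError

__all__ = [
    "GaussianMixtureParams",
    "ModelSpace",
    "param_dimension",
    "gmm_log_density",
    "gmm_sample",
    "canonicalize",
    "floor_covariance",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: absolute tolerance on sum(weights) == 1
_WEIGHT_TOL = 1e-12


def param_dimension(k: int, p: int) -> int:
    """Free-parameter dimension of a k-component Gaussian mixture on R^p.

    Counts ``k - 1`` free mixing weights plus, per component, ``p`` mean
    coordinates and ``p(p+1)/2`` free covariance entries:

        d = (k - 1) + k * (p + p(p+1)/2)

    Parameters
    ----------
    k : int
        Number of mixture components, >= 1.
    p : int
        Dimension of the support, >= 1.
    """
    if int(k) != k or int(p) != p or k < 1 or p < 1:
        raise InvalidArgumentError(f"k and p must be positive integers, got k={k}, p={p}")
    k, p = int(k), int(p)
    return (k - 1) + k * (p + p * (p + 1) // 2)


@dataclasses.dataclass(frozen=True)
class GaussianMixtureParams:
    """Parameters of a k-component Gaussian mixture on R^p.

    Attributes
    ----------
    weights : (k,) ndarray
        Mixing proportions; nonnegative, summing to 1 within 1e-12.
    means : (k, p) ndarray
        Component means.
    covariances : (k, p, p) ndarray
        Symmetric positive-definite component covariances.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariances, dtype=float)
        if mu.ndim != 2:
            raise InvalidArgumentError("means must be a (k, p) array")
        k, p = mu.shape
        if w.shape != (k,):
            raise InvalidArgumentError(f"weights shape {w.shape} inconsistent with k={k}")
        if cov.shape != (k, p, p):
            raise InvalidArgumentError(
                f"covariances shape {cov.shape} inconsistent with (k, p, p)=({k}, {p}, {p})"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(cov))):
            raise InvalidArgumentError("parameters must be finite")
        if np.any(w < 0) or abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise InvalidArgumentError("weights must be nonnegative and sum to 1")
        for j in range(k):
            if not np.allclose(cov[j], cov[j].T, atol=1e-10, rtol=1e-8):
                raise InvalidArgumentError(f"covariance {j} is not symmetric")
            if np.linalg.eigvalsh(cov[j])[0] <= 0:
                raise InvalidArgumentError(f"covariance {j} is not positive definite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", cov)

    @property
    def k(self) -> int:
        return self.means.shape[0]

    @property
    def p(self) -> int:
        return self.means.shape[1]

    @property
    def dimension(self) -> int:
        """Free-parameter dimension d of this mixture."""
        return param_dimension(self.k, self.p)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixtureParams":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GaussianMixtureParams":
        return cls.from_dict(json.loads(s))

    # -- convenience ------------------------------------------------------

    @classmethod
    def single(cls, mean, cov) -> "GaussianMixtureParams":
        """A one-component (plain Gaussian) member of the family."""
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        return cls(weights=np.ones(1), means=mean[None, :], covariances=cov[None, :, :])


@dataclasses.dataclass(frozen=True)
class ModelSpace:
    """The collection of candidate mixture families searched over.

    Attributes
    ----------
    p : int
        Support dimension.
    k_grid : tuple of int
        Strictly increasing candidate component counts.
    eps_cov : float
        Relative covariance eigenvalue floor applied during fitting.
    """

    p: int
    k_grid: tuple
    eps_cov: float = 1e-6

    def __post_init__(self) -> None:
        kg = tuple(int(k) for k in self.k_grid)
        if len(kg) == 0 or any(k < 1 for k in kg):
            raise InvalidArgumentError("k_grid must be nonempty with all entries >= 1")
        if any(b <= a for a, b in zip(kg, kg[1:])):
            raise InvalidArgumentError("k_grid must be strictly increasing")
        if self.p < 1:
            raise InvalidArgumentError("p must be >= 1")
        if self.eps_cov <= 0:
            raise InvalidArgumentError("eps_cov must be positive")
        object.__setattr__(self, "k_grid", kg)

    def dimensions(self) -> dict:
        """Map each candidate k to its free-parameter dimension d."""
        return {k: param_dimension(k, self.p) for k in self.k_grid}


def _component_log_densities(params: GaussianMixtureParams, x: np.ndarray) -> np.ndarray:
    """(n, k) matrix of per-component Gaussian log-densities."""
    n, p = x.shape
    out = np.empty((n, params.k))
    for j in range(params.k):
        c, lower = cho_factor(params.covariances[j], lower=True)
        dev = (x - params.means[j]).T  # (p, n)
        sol = solve_triangular(c, dev, lower=lower)
        maha = np.einsum("ij,ij->j", sol, sol)
        log_det = 2.0 * np.sum(np.log(np.diag(c)))
        out[:, j] = -0.5 * (p * _LOG_2PI + log_det + maha)
    return out


def gmm_log_density(params: GaussianMixtureParams, points: np.ndarray) -> np.ndarray:
    """Log-density ``log q_theta(x_i)`` of the mixture at each row of `points`.

    Uses a log-sum-exp over per-component log-densities (Cholesky based), so
    the result only reaches -inf when every component density underflows.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.ndim != 2 or x.shape[1] != params.p:
        raise InvalidArgumentError(
            f"points must be (n, {params.p}), got shape {np.shape(points)}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("points must be finite")
    comp = _component_log_densities(params, x)
    with np.errstate(divide="ignore"):
        log_w = np.log(params.weights)
    return logsumexp(comp + log_w[None, :], axis=1)


def gmm_sample(
    params: GaussianMixtureParams,
    n: int,
    seed: "int | np.random.Generator",
) -> np.ndarray:
    """Draw `n` i.i.d. rows from the mixture.

    Component labels are drawn from the mixing weights, then Gaussian
    deviates are generated per component via Cholesky factors. Identical
    seeds give identical output.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rng.choice(params.k, size=n, p=params.weights)
    z = rng.standard_normal((n, params.p))
    x = np.empty((n, params.p))
    for j in range(params.k):
        idx = labels == j
        if not np.any(idx):
            continue
        chol = np.linalg.cholesky(params.covariances[j])
        x[idx] = params.means[j] + z[idx] @ chol.T
    return x


def canonicalize(params: GaussianMixtureParams) -> GaussianMixtureParams:
    """Return an equivalent mixture with components sorted by first mean
    coordinate (ties by weight). The mixture likelihood is label-symmetric;
    this ordering is for reporting and comparisons only, never for fitting."""
    order = np.lexsort((params.weights, params.means[:, 0]))
    return GaussianMixtureParams(
        weights=params.weights[order],
        means=params.means[order],
        covariances=params.covariances[order],
    )


def floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    """Clip eigenvalues of a symmetric matrix from below at `floor`.

    Weighted M-steps can produce near-singular covariances when only a few
    points carry positive weight; the floor keeps every component density
    evaluable.
    """
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] >= floor:
        return cov
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T
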