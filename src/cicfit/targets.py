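"""Synthetic unnormalized-density targets with known ground truth.

Every consumer of the package supplies an evaluator for a nonnegative
function r(x) whose normalized version q* = r / rho is the density to be
approximated; rho = \\int r dx is unknown in applications. The constructors
here build three families of such targets for which rho and q* ARE known in
closed form, so the estimators can be checked exactly:

* in-family Gaussian-mixture targets, r = rho * q_gmm — the well-specified
  case where the approximating family contains the truth;
* half-space indicator targets, r(x) = 1{a.x > b} * phi_p(x) — the optimal
  importance-sampling density for estimating a Gaussian tail probability
  rho = Phi(-b), a rare-event target whose r is zero on most of the space;
* conjugate normal-normal posteriors, r = prior * likelihood — the Bayesian
  evidence setting with a closed-form marginal likelihood.

Brute-force oracles (adaptive quadrature in 1-D, plain Monte Carlo above)
provide independent values of the cross-entropy C(theta) = -\\int r log
q_theta and of rho for validation.

Evaluations of r are counted: the driver's economy contract (every point is
evaluated exactly once) is checked against `eval_count`. Oracles use the
uncounted handle.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
from scipy import integrate, stats

from .errors import InvalidArgumentError, OracleFailureError
from .model_space import GaussianMixtureParams, gmm_log_density, gmm_sample

__all__ = [
    "UnnormalizedTarget",
    "OracleEstimate",
    "make_gmm_target",
    "make_indicator_target",
    "make_conjugate_posterior_target",
    "oracle_cross_entropy",
    "oracle_rho",
    "build_target",
]


@dataclasses.dataclass
class UnnormalizedTarget:
    """A pointwise evaluator of r(x) >= 0 on R^p with an evaluation counter.

    `rho_true` and `log_q_star` are optional ground-truth fields used only
    by tests and oracles; production targets leave them None. Calling the
    target counts one evaluation per row; `evaluate_uncounted` is reserved
    for oracles and plotting.
    """

    p: int
    fn: Callable[[np.ndarray], np.ndarray]
    name: str = "target"
    rho_true: Optional[float] = None
    log_q_star: Optional[Callable[[np.ndarray], np.ndarray]] = None
    sample_q_star: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None
    eval_count: int = 0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(points, dtype=float))
        if x.shape[1] != self.p:
            raise InvalidArgumentError(f"points must have {self.p} columns")
        self.eval_count += x.shape[0]
        return self._eval(x)

    def evaluate_uncounted(self, points: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(points, dtype=float))
        return self._eval(x)

    def _eval(self, x: np.ndarray) -> np.ndarray:
        r = np.asarray(self.fn(x), dtype=float)
        if r.shape != (x.shape[0],):
            raise InvalidArgumentError("evaluator must return one value per row")
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise InvalidArgumentError("r values must be finite and nonnegative")
        return r

    @property
    def has_truth(self) -> bool:
        return self.rho_true is not None


@dataclasses.dataclass(frozen=True)
class OracleEstimate:
    """Value with a Monte-Carlo standard error (0 for quadrature)."""

    value: float
    stderr: float


def make_gmm_target(params: GaussianMixtureParams, rho: float) -> UnnormalizedTarget:
    """In-family target r(x) = rho * q_params(x), with full ground truth."""
    if rho <= 0:
        raise InvalidArgumentError("rho must be positive")

    def fn(x):
        return rho * np.exp(gmm_log_density(params, x))

    return UnnormalizedTarget(
        p=params.p,
        fn=fn,
        name=f"gmm_k{params.k}_rho{rho:g}",
        rho_true=float(rho),
        log_q_star=lambda x: gmm_log_density(params, x),
        sample_q_star=lambda n, rng: gmm_sample(params, n, rng),
    )


def make_indicator_target(direction: np.ndarray, b: float) -> UnnormalizedTarget:
    """Half-space rare-event target r(x) = 1{a.x > b} * phi_p(x).

    This is (up to normalization) the optimal importance-sampling density
    for estimating the standard-Gaussian tail probability P(a.X > b), so
    rho = Phi(-b) in closed form and q* is the half-space-truncated
    standard Gaussian.
    """
    a = np.asarray(direction, dtype=float)
    if a.ndim != 1 or not np.isclose(np.linalg.norm(a), 1.0, atol=1e-10):
        raise InvalidArgumentError("direction must be a unit vector")
    p = a.size
    rho = float(stats.norm.sf(b))
    log_rho = float(stats.norm.logsf(b))

    def log_phi(x):
        return -0.5 * (p * np.log(2 * np.pi) + np.sum(x * x, axis=1))

    def fn(x):
        inside = x @ a > b
        out = np.zeros(x.shape[0])
        out[inside] = np.exp(log_phi(x[inside]))
        return out

    def log_q_star(x):
        inside = x @ a > b
        out = np.full(x.shape[0], -np.inf)
        out[inside] = log_phi(x[inside]) - log_rho
        return out

    def sample_q_star(n, rng):
        # along `a`: truncated normal above b; orthogonal: standard normal
        t = stats.truncnorm.rvs(b, np.inf, size=n, random_state=rng)
        z = rng.standard_normal((n, p))
        z_perp = z - np.outer(z @ a, a)
        return np.outer(t, a) + z_perp

    return UnnormalizedTarget(
        p=p,
        fn=fn,
        name=f"halfspace_b{b:g}",
        rho_true=rho,
        log_q_star=log_q_star,
        sample_q_star=sample_q_star,
    )


def make_conjugate_posterior_target(
    prior_mean: float,
    prior_var: float,
    obs: np.ndarray,
    obs_var: float,
) -> UnnormalizedTarget:
    """Normal-normal Bayesian target r(theta) = prior(theta) * likelihood.

    With prior theta ~ N(m0, v0) and observations y_i | theta ~ N(theta,
    sigma2), the posterior is N(mn, vn) with vn = 1/(1/v0 + n/sigma2) and
    mn = vn (m0/v0 + sum y_i / sigma2); the normalizing constant is the
    model evidence, the density of y under N(m0 1, sigma2 I + v0 J).
    """
    y = np.atleast_1d(np.asarray(obs, dtype=float))
    if prior_var <= 0 or obs_var <= 0:
        raise InvalidArgumentError("variances must be positive")
    if y.size == 0:
        raise InvalidArgumentError("obs must be nonempty")
    n = y.size
    vn = 1.0 / (1.0 / prior_var + n / obs_var)
    mn = vn * (prior_mean / prior_var + y.sum() / obs_var)
    # evidence by completing the square in theta:
    # log rho = const(y) + mn^2/(2 vn) + 0.5 log(2 pi vn)
    const = (
        -0.5 * np.log(2 * np.pi * prior_var)
        - 0.5 * n * np.log(2 * np.pi * obs_var)
        - prior_mean**2 / (2 * prior_var)
        - np.sum(y * y) / (2 * obs_var)
    )
    log_rho = float(const + mn * mn / (2 * vn) + 0.5 * np.log(2 * np.pi * vn))

    def fn(x):
        theta = x[:, 0]
        log_prior = stats.norm.logpdf(theta, prior_mean, np.sqrt(prior_var))
        log_lik = np.sum(
            stats.norm.logpdf(y[None, :], theta[:, None], np.sqrt(obs_var)), axis=1
        )
        return np.exp(log_prior + log_lik)

    tgt = UnnormalizedTarget(
        p=1,
        fn=fn,
        name="conjugate_posterior",
        rho_true=float(np.exp(log_rho)),
        log_q_star=lambda x: stats.norm.logpdf(x[:, 0], mn, np.sqrt(vn)),
        sample_q_star=lambda m, rng: rng.normal(mn, np.sqrt(vn), size=(m, 1)),
    )
    tgt.posterior_mean = mn  # type: ignore[attr-defined]
    tgt.posterior_var = vn  # type: ignore[attr-defined]
    return tgt


def _quad_1d(f, lo=-40.0, hi=40.0, epsabs=1e-9):
    val, err = integrate.quad(f, lo, hi, limit=400, epsabs=epsabs, epsrel=1e-9)
    if not np.isfinite(val) or err > max(1e-6, 1e-4 * abs(val)):
        raise OracleFailureError(f"quadrature did not converge (err={err})")
    return val


def oracle_cross_entropy(
    target: UnnormalizedTarget,
    params: GaussianMixtureParams,
    n_mc: int = 200_000,
    seed: int = 0,
) -> OracleEstimate:
    """Brute-force value of C(theta) = -\\int r(x) log q_theta(x) dx.

    1-D targets use adaptive quadrature (standard error reported as 0);
    higher dimensions require ground truth and use Monte Carlo from q*
    with C = rho * E_{q*}[-log q_theta], reporting a standard error.
    """
    if target.p == 1:

        def integrand(x):
            xx = np.array([[x]])
            r = target.evaluate_uncounted(xx)[0]
            if r == 0.0:
                return 0.0
            return -r * gmm_log_density(params, xx)[0]

        return OracleEstimate(value=_quad_1d(integrand), stderr=0.0)
    if target.sample_q_star is None or target.rho_true is None:
        raise OracleFailureError("need ground truth (or p == 1) for the oracle")
    rng = np.random.default_rng(seed)
    x = target.sample_q_star(n_mc, rng)
    neg_logq = -gmm_log_density(params, x)
    rho = target.rho_true
    return OracleEstimate(
        value=float(rho * np.mean(neg_logq)),
        stderr=float(rho * np.std(neg_logq, ddof=1) / np.sqrt(n_mc)),
    )


def oracle_rho(target: UnnormalizedTarget, n_mc: int = 1_000_000, seed: int = 0) -> OracleEstimate:
    """Ground-truth rho when known; otherwise quadrature (p = 1) or plain
    Monte Carlo against a wide Gaussian reference (p = 2)."""
    if target.rho_true is not None:
        return OracleEstimate(value=float(target.rho_true), stderr=0.0)
    if target.p == 1:
        val = _quad_1d(lambda x: target.evaluate_uncounted(np.array([[x]]))[0])
        return OracleEstimate(value=val, stderr=0.0)
    if target.p == 2:
        rng = np.random.default_rng(seed)
        sd = 4.0
        x = rng.normal(scale=sd, size=(n_mc, 2))
        ref = np.exp(-0.5 * np.sum((x / sd) ** 2, axis=1)) / (2 * np.pi * sd * sd)
        vals = target.evaluate_uncounted(x) / ref
        return OracleEstimate(
            value=float(np.mean(vals)),
            stderr=float(np.std(vals, ddof=1) / np.sqrt(n_mc)),
        )
    raise OracleFailureError("oracle_rho requires truth fields or p <= 2")


def build_target(spec: dict) -> UnnormalizedTarget:
    """Construct a fixture target from a config mapping.

    Recognized forms::

        {type: gmm, rho: 3.0, weights: [...], means: [[...]], covariances: [[[...]]]}
        {type: indicator, b: 1.5, p: 2}           # direction defaults to e_1
        {type: indicator, b: 1.5, direction: [...]}
        {type: posterior, prior_mean: 0, prior_var: 1, obs: [...], obs_var: 1}
    """
    spec = dict(spec)
    kind = spec.pop("type", None)
    if kind == "gmm":
        rho = float(spec.pop("rho", 1.0))
        extra = set(spec) - {"weights", "means", "covariances"}
        if extra:
            raise InvalidArgumentError(f"unknown target keys: {sorted(extra)}")
        params = GaussianMixtureParams.from_dict(spec)
        return make_gmm_target(params, rho)
    if kind == "indicator":
        b = float(spec.pop("b"))
        if "direction" in spec:
            direction = np.asarray(spec.pop("direction"), dtype=float)
        else:
            p = int(spec.pop("p", 2))
            direction = np.zeros(p)
            direction[0] = 1.0
        if spec:
            raise InvalidArgumentError(f"unknown target keys: {sorted(spec)}")
        return make_indicator_target(direction, b)
    if kind == "posterior":
        return make_conjugate_posterior_target(
            prior_mean=float(spec.pop("prior_mean", 0.0)),
            prior_var=float(spec.pop("prior_var", 1.0)),
            obs=np.asarray(spec.pop("obs"), dtype=float),
            obs_var=float(spec.pop("obs_var", 1.0)),
        )
    raise InvalidArgumentError(f"unknown target type: {kind!r}")
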