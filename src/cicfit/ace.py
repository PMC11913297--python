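"""Approximate cross-entropy (ACE), importance weights, and the CIC value.

The quantity being minimized over the mixture family is the cross-entropy

    C(theta) = - \\int r(x) log q_theta(x) dx,

which equals rho times the usual cross-entropy from q_theta to the target
q* = r / rho. Because r can only be evaluated pointwise, C is estimated by
importance sampling: with X_i drawn from a proposal q_eta and weights
w_i = r(X_i) / q_eta(X_i),

    ACE(theta) = - (1/n) sum_i w_i log q_theta(X_i)

is unbiased for C(theta). The cumulative form pools stages s = 0..t-1 with
per-observation (not per-stage) equal weighting. The same weights give the
importance-sampling estimator of the normalizing constant,
rho_hat = mean(w_i), which has zero variance exactly when the proposal is
the target itself.

The cross-entropy information criterion corrects the optimism of evaluating
the ACE at its own minimizer:

    CIC = ACE(theta_hat) + rho_hat * d / n,

where d is the free-parameter dimension of the family. With direct sampling
from the target this reduces to rho times the AIC.

Stage bookkeeping lives here too: each sampling stage stores its points,
raw r values, proposal log-densities and weights once, so that model search
over candidate mixtures never re-evaluates the (expensive) target function.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateSupportError,
    InvalidArgumentError,
    InvalidTargetError,
)
from .model_space import GaussianMixtureParams, gmm_log_density

__all__ = [
    "StageRecord",
    "SampleArchive",
    "importance_weights",
    "ace",
    "rho_hat",
    "rho_hat_stderr",
    "cic_value",
    "ess",
]


def importance_weights(r_values: np.ndarray, proposal_log_density: np.ndarray) -> np.ndarray:
    """Importance weights w_i = r(X_i) / q_eta(X_i) from stored evaluations.

    `proposal_log_density` holds log q_eta(X_i) for the proposal the points
    were actually drawn from. Raises ``InvalidTargetError`` for negative or
    non-finite r values and ``DegenerateSupportError`` when every weight is
    zero (the proposal entirely missed the support of the target).
    """
    r = np.asarray(r_values, dtype=float)
    lq = np.asarray(proposal_log_density, dtype=float)
    if r.shape != lq.shape or r.ndim != 1:
        raise InvalidArgumentError("r_values and proposal_log_density must be equal-length 1-D")
    if np.any(~np.isfinite(r)) or np.any(r < 0):
        raise InvalidTargetError("r values must be finite and nonnegative")
    if np.any(~np.isfinite(lq)):
        raise InvalidArgumentError("proposal log-densities must be finite")
    w = np.zeros_like(r)
    pos = r > 0
    with np.errstate(over="raise"):
        w[pos] = np.exp(np.log(r[pos]) - lq[pos])
    if not np.any(w > 0):
        raise DegenerateSupportError("all importance weights are zero")
    return w


@dataclasses.dataclass(frozen=True)
class StageRecord:
    """One sampling stage: points drawn from the stage proposal plus the
    stored target evaluations and weights.

    Invariant: ``weights = r_values / exp(proposal_log_density)`` (checked
    to relative 1e-12), so candidate evaluation downstream never touches r.
    """

    stage_index: int
    points: np.ndarray
    r_values: np.ndarray
    proposal_log_density: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.points, dtype=float))
        r = np.asarray(self.r_values, dtype=float)
        lq = np.asarray(self.proposal_log_density, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        n = x.shape[0]
        if self.stage_index < 0:
            raise InvalidArgumentError("stage_index must be nonnegative")
        if r.shape != (n,) or lq.shape != (n,) or w.shape != (n,):
            raise InvalidArgumentError("stage arrays must share length n")
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise InvalidTargetError("r values must be finite and nonnegative")
        if np.any(~np.isfinite(lq)) or np.any(~np.isfinite(x)):
            raise InvalidArgumentError("points and proposal log-densities must be finite")
        expected = np.where(r > 0, r * np.exp(-lq), 0.0)
        scale = np.maximum(np.abs(expected), 1e-300)
        if np.any(np.abs(w - expected) > 1e-12 * scale):
            raise InvalidArgumentError("weights inconsistent with r / proposal density")
        object.__setattr__(self, "points", x)
        object.__setattr__(self, "r_values", r)
        object.__setattr__(self, "proposal_log_density", lq)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_r(
        cls,
        stage_index: int,
        points: np.ndarray,
        r_values: np.ndarray,
        proposal_log_density: np.ndarray,
    ) -> "StageRecord":
        """Build a record, computing the weights from r and the proposal."""
        w = importance_weights(r_values, proposal_log_density)
        return cls(stage_index, points, r_values, proposal_log_density, w)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def p(self) -> int:
        return self.points.shape[1]


class SampleArchive:
    """Ordered collection of sampling stages 0..t-1 sharing one support
    dimension. Supports the cumulative ACE and the cumulative normalizing
    constant estimator, plus NPZ/CSV round-trips."""

    def __init__(self, p: int):
        if p < 1:
            raise InvalidArgumentError("p must be >= 1")
        self.p = int(p)
        self.stages: list[StageRecord] = []

    def add(self, record: StageRecord) -> None:
        if record.p != self.p:
            raise InvalidArgumentError("stage dimension mismatch")
        if record.stage_index != len(self.stages):
            raise InvalidArgumentError(
                f"expected stage index {len(self.stages)}, got {record.stage_index}"
            )
        self.stages.append(record)

    def __len__(self) -> int:
        return len(self.stages)

    def _resolve(self, stages: Optional[Sequence[int]]) -> list[StageRecord]:
        if stages is None:
            recs = self.stages
        else:
            idx = sorted(set(int(s) for s in stages))
            if not idx or idx[0] < 0 or (idx and idx[-1] >= len(self.stages)):
                raise InvalidArgumentError(f"stage subset {stages} out of range")
            recs = [self.stages[s] for s in idx]
        if not recs:
            raise InvalidArgumentError("no stages selected")
        return recs

    def concat(self, stages: Optional[Sequence[int]] = None):
        """(points, weights, n_total) concatenated over the selected stages."""
        recs = self._resolve(stages)
        x = np.concatenate([r.points for r in recs], axis=0)
        w = np.concatenate([r.weights for r in recs])
        return x, w, x.shape[0]

    def n_total(self, stages: Optional[Sequence[int]] = None) -> int:
        return sum(r.n for r in self._resolve(stages))

    # -- persistence ------------------------------------------------------

    def to_npz(self, path) -> None:
        arrays = {"p": np.asarray(self.p), "n_stages": np.asarray(len(self.stages))}
        for rec in self.stages:
            s = rec.stage_index
            arrays[f"points_{s}"] = rec.points
            arrays[f"r_values_{s}"] = rec.r_values
            arrays[f"proposal_log_density_{s}"] = rec.proposal_log_density
            arrays[f"weights_{s}"] = rec.weights
        np.savez(path, **arrays)

    @classmethod
    def from_npz(cls, path) -> "SampleArchive":
        with np.load(path) as data:
            archive = cls(int(data["p"]))
            for s in range(int(data["n_stages"])):
                archive.add(
                    StageRecord(
                        stage_index=s,
                        points=data[f"points_{s}"],
                        r_values=data[f"r_values_{s}"],
                        proposal_log_density=data[f"proposal_log_density_{s}"],
                        weights=data[f"weights_{s}"],
                    )
                )
        return archive

    def to_dataframe(self):
        """Long-format table: stage, x_1..x_p, r_value, proposal_log_density, weight."""
        import pandas as pd

        frames = []
        for rec in self.stages:
            d = {"stage": np.full(rec.n, rec.stage_index, dtype=int)}
            for j in range(self.p):
                d[f"x_{j + 1}"] = rec.points[:, j]
            d["r_value"] = rec.r_values
            d["proposal_log_density"] = rec.proposal_log_density
            d["weight"] = rec.weights
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ace(
    archive: SampleArchive,
    candidate: GaussianMixtureParams,
    stages: Optional[Sequence[int]] = None,
) -> float:
    """Approximate cross-entropy of a candidate mixture on archived stages.

    Returns ``-(sum_s sum_i w_i^(s) log q_cand(X_i^(s))) / (sum_s n_s)`` over
    the requested stages (all stages when `stages` is None). With a single
    stage this is the one-stage estimator; pooling stages gives the
    cumulative estimator with equal per-observation weighting.

    If the candidate assigns zero density (log-density underflows to -inf)
    to any positively weighted point, returns +inf — the candidate violates
    absolute continuity with respect to the target there and is ranked
    strictly worst, rather than raising.
    """
    if candidate.p != archive.p:
        raise InvalidArgumentError("candidate dimension does not match archive")
    x, w, n = archive.concat(stages)
    logq = gmm_log_density(candidate, x)
    pos = w > 0
    if np.any(np.isneginf(logq[pos])):
        return float("inf")
    return float(-(np.sum(w[pos] * logq[pos])) / n)


def rho_hat(archive: SampleArchive, include_initial: bool = True) -> float:
    """Importance-sampling estimate of the normalizing constant rho.

    The mean of the stored weights over the included stages: all stages when
    `include_initial` is True, otherwise stages s >= 1 only. Excluding the
    initial stage discards the sample drawn from the user-supplied starting
    proposal, which may be far from the target and inflate the variance.
    """
    if len(archive) == 0:
        raise InvalidArgumentError("archive is empty")
    if include_initial:
        stages = None
    else:
        if len(archive) < 2:
            raise InvalidArgumentError(
                "include_initial=False requires at least one stage with s >= 1"
            )
        stages = range(1, len(archive))
    _, w, n = archive.concat(stages)
    if not np.any(w > 0):
        raise DegenerateSupportError("all included weights are zero")
    return float(np.sum(w) / n)


def rho_hat_stderr(archive: SampleArchive, include_initial: bool = True) -> float:
    """Naive standard error of :func:`rho_hat`: sd(weights)/sqrt(N) over the
    included stages. Stages are treated as independent draws; adaptivity
    across stages makes this an approximation used for diagnostic bands."""
    stages = None if include_initial else range(1, len(archive))
    _, w, n = archive.concat(stages)
    if n < 2:
        return float("inf")
    return float(np.std(w, ddof=1) / np.sqrt(n))


def cic_value(ace_value: float, rho_estimate: float, d: int, n_total: int) -> float:
    """The cross-entropy information criterion:
    ``ace_value + rho_estimate * d / n_total``.

    `n_total` must be the number of observations underlying `ace_value`
    (the pooled count for the cumulative form). The penalty corrects the
    asymptotic downward bias -rho*d/n of evaluating the ACE at its own
    minimizer.
    """
    if rho_estimate <= 0 or not np.isfinite(rho_estimate):
        raise InvalidArgumentError("rho_estimate must be positive and finite")
    if d < 0 or n_total < 1:
        raise InvalidArgumentError("d must be >= 0 and n_total >= 1")
    return float(ace_value + rho_estimate * d / n_total)


def ess(weights: np.ndarray) -> float:
    """Effective sample size (sum w)^2 / sum w^2 — a diagnostic for
    importance-weight degeneracy, in (0, n]."""
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    s2 = np.sum(w * w)
    if s2 <= 0:
        raise DegenerateSupportError("all weights are zero")
    return float(s * s / s2)
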