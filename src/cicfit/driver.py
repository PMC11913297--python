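"""Iterative CIC-based approximation of an unnormalized density.

The procedure alternates sampling and refitting. Starting from a
user-supplied proposal, each stage t:

1. draws n_{t-1} points from the current proposal and evaluates r once per
   point (the only place r is ever called), storing the stage;
2. for every candidate component count k, fits the minimum cross-entropy
   mixture on the pooled archive (or the newest stage only, in the
   non-cumulative variant) and scores it by the CIC;
3. adopts the CIC-minimizing mixture as the next stage's proposal.

After the last stage a final sample from the selected mixture feeds the
normalizing-constant estimate, which pools all post-initial stages; the
initial stage is excluded because the starting proposal may be far from the
target and would inflate the variance.

Two estimator conventions, matching the two forms of the criterion:

* cumulative (default): the ACE pools all archived stages with equal
  per-observation weight, and rho_hat uses the initial stage only while it
  is the sole stage, then switches to stages s >= 1;
* non-cumulative: fits and rho_hat use only the newest stage, with a fixed
  single-entry component grid — the fixed-family iterative scheme.

Candidate dimensions whose free-parameter count d reaches half the effective
sample size of the fitting weights are skipped as unsupportable; if every
candidate fails the stage errors out.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .ace import (
    SampleArchive,
    StageRecord,
    ace,
    cic_value,
    ess,
    rho_hat,
    rho_hat_stderr,
)
from .em import EMOptions, EMTrace, fit_mce
from .errors import (
    DegenerateSupportError,
    FitFailedError,
    InsufficientSupportError,
    InvalidArgumentError,
)
from .model_space import GaussianMixtureParams, gmm_log_density, gmm_sample, param_dimension
from .targets import UnnormalizedTarget

__all__ = [
    "RunConfig",
    "KRecord",
    "FitReport",
    "ApproximationResult",
    "run_stage",
    "select_dimension",
    "approximate",
]

logger = logging.getLogger("cicfit")

# candidate k is skipped when d >= this fraction of the effective sample size
_DIM_ESS_FRACTION = 0.5
# warn when the newly selected model leaves its own stage this weight-degenerate
_ESS_WARN = 5.0


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one approximation run.

    n_stage may be a single size for all post-initial stages or a sequence
    of length tau; n_initial sizes the pilot sample from `initial_params`.
    """

    tau: int
    n_initial: int
    n_stage: "int | Sequence[int]"
    initial_params: GaussianMixtureParams
    k_grid: Sequence[int]
    cumulative: bool = True
    seed: int = 0
    em_options: EMOptions = dataclasses.field(default_factory=EMOptions)
    warm_start: bool = False

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise InvalidArgumentError("tau must be >= 1")
        if self.n_initial < 1:
            raise InvalidArgumentError("n_initial must be >= 1")
        kg = tuple(int(k) for k in self.k_grid)
        if not kg or any(k < 1 for k in kg):
            raise InvalidArgumentError("k_grid must be nonempty with entries >= 1")
        if not self.cumulative and len(kg) != 1:
            raise InvalidArgumentError(
                "non-cumulative runs fix the family: k_grid must have exactly one entry"
            )
        ns = self.n_stage
        if isinstance(ns, (int, np.integer)):
            if ns < 1:
                raise InvalidArgumentError("n_stage must be >= 1")
        else:
            ns = tuple(int(v) for v in ns)
            if len(ns) != self.tau or any(v < 1 for v in ns):
                raise InvalidArgumentError("per-stage sizes must have length tau, all >= 1")
        object.__setattr__(self, "k_grid", kg)
        object.__setattr__(self, "n_stage", ns)

    def stage_size(self, t: int) -> int:
        """Sample size n_t: t = 0 is the pilot stage, t = 1..tau the rest."""
        if t == 0:
            return int(self.n_initial)
        if isinstance(self.n_stage, tuple):
            return int(self.n_stage[t - 1])
        return int(self.n_stage)


@dataclasses.dataclass
class KRecord:
    """Score of one candidate component count at one stage."""

    k: int
    d: int
    ace: float
    cic: float
    n_iters: int = 0
    converged: bool = False
    skipped: Optional[str] = None


@dataclasses.dataclass
class FitReport:
    """Everything recorded at one stage: per-k scores, the selection, the
    stage's rho estimate, and weight diagnostics."""

    t: int
    records: list
    selected_k: int
    selected_params: GaussianMixtureParams
    rho_estimate: float
    ess_per_stage: list
    n_used: int

    @property
    def cic_by_k(self) -> dict:
        return {r.k: r.cic for r in self.records if r.skipped is None}


@dataclasses.dataclass
class ApproximationResult:
    """Output of :func:`approximate`."""

    selected_params: GaussianMixtureParams
    rho_trajectory: np.ndarray  # per-stage rho_hat, final entry is rho_final
    reports: list
    rho_final: float
    rho_final_stderr: float
    archive: SampleArchive
    r_evaluations: int
    seed: int


def select_dimension(cic_by_k: dict) -> int:
    """The component count with minimal CIC; ties go to the smallest k."""
    finite = {k: v for k, v in cic_by_k.items() if np.isfinite(v)}
    if not finite:
        raise FitFailedError("no candidate dimension has a finite CIC")
    best = min(finite.values())
    return min(k for k, v in finite.items() if v == best)


def _sample_stage(
    target: UnnormalizedTarget,
    proposal: GaussianMixtureParams,
    n: int,
    stage_index: int,
    seed: int,
) -> StageRecord:
    # stream namespace 1 = stage sampling (fits use namespace (t, k, restart))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, stage_index)))
    x = gmm_sample(proposal, n, rng)
    r = target(x)
    lq = gmm_log_density(proposal, x)
    return StageRecord.from_r(stage_index, x, r, lq)


def _stage_rho(archive: SampleArchive, cumulative: bool) -> float:
    """rho_hat convention for the CIC at the current stage: with a single
    archived stage use it; afterwards exclude the initial stage. The
    non-cumulative variant always uses the newest stage alone."""
    if not cumulative:
        rec = archive.stages[-1]
        w = rec.weights
        if not np.any(w > 0):
            raise DegenerateSupportError("all weights zero in newest stage")
        return float(np.mean(w))
    return rho_hat(archive, include_initial=(len(archive) == 1))


def run_stage(
    target: UnnormalizedTarget,
    archive: SampleArchive,
    current: GaussianMixtureParams,
    config: RunConfig,
    t: int,
) -> tuple:
    """Run stage t >= 1: sample from `current`, archive, fit all candidate
    k, select by CIC. Returns ``(archive, FitReport)`` with the archive
    extended in place by one stage of ``config.stage_size(t - 1)`` points."""
    if t < 1:
        raise InvalidArgumentError("t must be >= 1")
    n_new = config.stage_size(t - 1)
    record = _sample_stage(target, current, n_new, len(archive), config.seed)
    archive.add(record)

    fit_stages = None if config.cumulative else [len(archive) - 1]
    x_fit, w_fit, n_used = archive.concat(fit_stages)
    ess_fit = ess(w_fit)
    rho_stage = _stage_rho(archive, config.cumulative)

    records: list[KRecord] = []
    fitted: dict[int, GaussianMixtureParams] = {}
    for k in config.k_grid:
        d = param_dimension(k, archive.p)
        if d >= _DIM_ESS_FRACTION * ess_fit:
            records.append(KRecord(k, d, np.inf, np.inf, skipped="dimension-vs-ess"))
            continue
        try:
            params, trace = fit_mce(
                archive,
                k,
                dataclasses.replace(config.em_options, seed=config.seed),
                stages=fit_stages,
                stream_key=(2, t),
            )
        except (InsufficientSupportError, FitFailedError) as exc:
            records.append(KRecord(k, d, np.inf, np.inf, skipped=type(exc).__name__))
            continue
        a = float(trace.objective_path[-1])
        c = cic_value(a, rho_stage, d, n_used)
        records.append(KRecord(k, d, a, c, trace.n_iters, trace.converged))
        fitted[k] = params
        logger.info(
            "stage %d k=%d d=%d ace=%.6g cic=%.6g iters=%d ess=%.1f",
            t, k, d, a, c, trace.n_iters, ess_fit,
        )

    cic_by_k = {r.k: r.cic for r in records if r.skipped is None}
    if not cic_by_k:
        raise FitFailedError(f"stage {t}: every candidate k failed or was skipped")
    k_star = select_dimension(cic_by_k)
    selected = fitted[k_star]

    try:
        new_w = record.r_values * np.exp(-gmm_log_density(selected, record.points))
        if np.any(new_w > 0) and ess(new_w) < _ESS_WARN:
            logger.warning(
                "stage %d: selected k=%d leaves ESS %.2f < %.0f on its own stage",
                t, k_star, ess(new_w), _ESS_WARN,
            )
    except Exception:  # diagnostics only, never fatal
        pass

    report = FitReport(
        t=t,
        records=records,
        selected_k=k_star,
        selected_params=selected,
        rho_estimate=rho_stage,
        ess_per_stage=[float(ess(s.weights)) for s in archive.stages],
        n_used=n_used,
    )
    return archive, report


def approximate(target: UnnormalizedTarget, config: RunConfig) -> ApproximationResult:
    """Run the full loop: stages t = 1..tau, then a final sample from the
    selected mixture for the normalizing-constant estimate.

    The returned rho trajectory holds the per-stage estimates used in the
    CIC (t = 1..tau) followed by the final pooled estimate over all
    post-initial stages including the last sample. Total r evaluations are
    exactly n_0 + n_1 + ... + n_tau.
    """
    archive = SampleArchive(config.initial_params.p)
    if target.p != archive.p:
        raise InvalidArgumentError("target and initial proposal dimension mismatch")
    current = config.initial_params
    reports: list[FitReport] = []
    traj: list[float] = []
    for t in range(1, config.tau + 1):
        archive, report = run_stage(target, archive, current, config, t)
        reports.append(report)
        traj.append(report.rho_estimate)
        current = report.selected_params

    # final sample from the output model, used only for rho estimation
    final_record = _sample_stage(
        target, current, config.stage_size(config.tau), len(archive), config.seed
    )
    archive.add(final_record)
    rho_final = rho_hat(archive, include_initial=False)
    rho_se = rho_hat_stderr(archive, include_initial=False)
    traj.append(rho_final)

    return ApproximationResult(
        selected_params=current,
        rho_trajectory=np.asarray(traj),
        reports=reports,
        rho_final=rho_final,
        rho_final_stderr=rho_se,
        archive=archive,
        r_evaluations=target.eval_count,
        seed=config.seed,
    )
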