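# Methods

This note documents the statistical model behind `cicfit`, the numerical
choices made where the mathematics leaves freedom, what the synthetic
targets do and do not emulate, and the known limitations.

## Problem and estimators

The package approximates a density `q* = r/rho` on `R^p` given only a
pointwise evaluator of the nonnegative function `r`; `rho = ∫ r dμ` is
unknown and is itself a quantity of interest (evidence, partition
function, rare-event probability). Approximation is parametric: the family
is the set of `k`-component Gaussian mixtures `q_θ` with unconstrained
means and covariances, free-parameter dimension
`d = (k-1) + k(p + p(p+1)/2)`.

Minimizing `KL(Q* ‖ Q_θ)` is equivalent to minimizing the (scaled)
cross-entropy `C(θ) = -∫ r log q_θ dμ`. With points `X_i` drawn from a
proposal `q_η` whose support covers that of `q*`, and weights
`w_i = r(X_i)/q_η(X_i)`, the approximate cross-entropy (ACE)
`-(1/n) Σ w_i log q_θ(X_i)` is unbiased for `C(θ)`; its minimizer is the
minimum cross-entropy estimator (MCE). The same weights give
`rho_hat = mean(w_i)`, exact with zero variance when `q_η = q*`.

The ACE evaluated at its own minimizer underestimates `C` by `rho·d/n`
asymptotically; the cross-entropy information criterion adds the estimated
penalty back:

    CIC(d) = ACE(θ̂_d) + rho_hat · d/n.

Minimizing CIC over the candidate grid of `k` performs model selection.
When samples come from `q*` itself the weights are constantly `rho` and
the CIC equals `rho × AIC` exactly — an identity the test suite checks at
machine precision.

### Cumulative forms and the stage loop

The driver runs stages `t = 1..τ`. Stage `t` samples `n_{t-1}` points from
the current proposal, evaluates `r` once per point, and refits every
candidate `k` on the pooled archive (all stages, equal weight per
observation — no stage-level reweighting; schemes that overweight newer
stages are deliberately not implemented). The CIC's `rho_hat` at stage `t`
uses the initial (pilot) stage while it is the only stage and switches to
stages `s ≥ 1` as soon as a post-pilot stage exists; the final estimate
after the loop pools stages `1..τ` including one last sample drawn from the
output mixture. The pilot stage is excluded from `rho` estimation because
the user-supplied starting proposal may be far from the target and would
inflate the estimator's variance. The per-stage `rho_hat` cannot depend on
`k`, so it is computed once per stage before the `k` loop.

A non-cumulative variant (fixed single `k`, fits and `rho_hat` from the
newest stage only) exists for studying the estimators' per-stage
behaviour, and is the configuration under which the asymptotic-bias
property is tested: for the 1-D Gaussian family (`d = 2`) with
`r = 3·N(0,1)`, `n = 400` per stage and two stages, the replicate mean of
`n·[ACE(θ̂) - C(θ̂)]/rho` over 1000 runs falls in `-2 ± 0.8`.

CIC-based selection is performed already at `t = 1`, although the bias
result formally concerns later stages; at `t = 1` the criterion is still a
reasonable (if not bias-exact) ranking and selecting a sane `k` early
prevents the proposal from collapsing or overspreading.

## Weighted EM

The MCE for a mixture is found by EM on the weighted objective:
responsibilities `γ_ij ∝ π_j N(x_i; μ_j, Σ_j)`, combined masses
`m_ij = w_i γ_ij`, and the standard closed-form M-step on the masses. Each
iteration weakly decreases the ACE; every accepted trace is checked
non-increasing to 1e-9. With `k = 1` one step lands exactly on the
weighted mean and covariance; with constant weights the procedure is the
classical EM for the MLE (validated against scikit-learn's
`GaussianMixture` to 1e-6 in the objective).

Numerical choices:

* **Initialization** — weighted k-means++-style seeding: means drawn from
  the positively weighted points, first by weight, then by weight ×
  squared distance to the nearest chosen mean; covariances start at the
  global weighted covariance; mixing weights uniform. `k = 1` is
  special-cased to its closed form.
* **Covariance floor** — eigenvalues of every fitted covariance are
  clipped below at `eps_cov` (default 1e-6) times the mean weighted data
  variance per coordinate. Rare-event weights concentrate on few points
  and would otherwise produce singular covariances.
* **Collapse handling** — a component whose mass falls below 1e-12 of the
  total weight, or whose covariance sits at the floor for 3 consecutive
  iterations, is re-seeded at the highest-weight point currently best
  explained by another component; after 2 re-seeds the restart is
  abandoned. If all restarts fail for some `k`, that `k` is excluded from
  selection at this stage.
* **Stopping** — relative ACE change below 1e-6 or 500 iterations;
  4 restarts by default, ties across restarts broken by the lowest restart
  index. The reported trace covers the winning restart's final monotone
  descent (a re-seed resets it).
* **Dimension guard** — a candidate `k` is skipped when
  `d ≥ 0.5 × ESS` of the fitting weights (`ESS = (Σw)²/Σw²`): with
  importance weights, the nominal sample size overstates the information
  available, and fitting more free parameters than half the effective
  sample supports is not meaningful.
* **Density evaluation** — per-component Cholesky factors plus
  log-sum-exp; a candidate assigning numerically zero density to a
  positively weighted point receives ACE `= +∞` (absolute continuity
  violated there) and thus ranks last rather than raising.
* **Selection ties** — equal CIC values resolve to the smallest `k`.
* **Randomness** — one root seed; sampling and each `(stage, k, restart)`
  fit draw from separate `SeedSequence` spawn keys, so enlarging the `k`
  grid does not perturb any other fit's stream and runs are bit-for-bit
  reproducible.
* **Refitting** — every `k` is re-fit from fresh initializations on the
  full archive at every stage rather than warm-started from the previous
  stage, matching the cumulative MCE's definition and avoiding path
  dependence.

Defaults: `τ = 7`, `n_0 = n_t = 1000`, `k` grid `1..10` (config layer);
the acceptance-facing runs in the tests use the smaller schedules stated
there.

## Synthetic targets

All tests run against generated targets with known `rho` and `q*`:

* **In-family mixture targets** (`make_gmm_target`) — `r = rho·q_GMM`; the
  well-specified case. The standard two-component fixture (means ±3, unit
  variances, `rho = 3`) is well-separated so the true `k` is identifiable
  at `n = 1000` per stage.
* **Half-space indicator** (`make_indicator_target`) — `r(x) = 1{a·x > b}·φ_p(x)`
  with `rho = Φ(-b)` exactly. This reproduces the rare-event structure —
  `r` is zero on most of the space, only points past the threshold carry
  weight — while keeping truth closed-form. It is a deliberately
  simplified stand-in for curved limit-state geometries in structural
  reliability: a Gaussian mixture can match a half-space-truncated
  Gaussian closely, so passing here does not demonstrate performance on
  strongly curved failure boundaries.
* **Conjugate normal-normal posterior** (`make_conjugate_posterior_target`)
  — `r = prior × likelihood` with closed-form posterior and evidence (by
  completing the square; no `n × n` matrix is formed).

Oracles: 1-D quantities use adaptive quadrature (absolute tolerance 1e-9
over a generous fixed window); higher dimensions use Monte Carlo from the
known `q*` with reported standard errors, and tests use 4·SE bands.

What the fixtures do **not** emulate: heavy-tailed or multimodal-with-
unknown-count targets, stochastic evaluators of `r` (where `r(x)` is a
random draw rather than a function), support dimensions beyond `p = 2`,
and model misspecification beyond the truncated-Gaussian case. Passing
tests therefore certify the estimators and the selection machinery under
the stated conditions, not field performance on arbitrary targets.

## Problem sizes used in the checks

The statistical checks use: 500 replicates × 500 points for unbiasedness;
1000 replicates × 2 × 400 points for the bias constant; 20 seeds of a
4-stage, 1000-points-per-stage run for selection recovery; 50 seeds of a
3-stage, 500-points-per-stage run for the variance trend; and single
5-stage, 1000-points-per-stage runs for the end-to-end `rho` checks.
These sizes were chosen as the smallest at which the quantities under test
have standard errors well inside the asserted bands.

## Known limitations

* The variance estimate attached to the final `rho_hat` treats all pooled
  weights as i.i.d.; adaptivity across stages makes it approximate
  (typically slightly optimistic). It is a diagnostic, not a confidence
  procedure.
* Importance weighting degrades in high dimensions; with `d` capped at
  half the ESS, the usable `k` grid can shrink to `{1}` for very rare
  events at small pilot sizes. Increase `n_0` or start the proposal closer
  to the region where `r` is large.
* Only Gaussian components are implemented. The EM and criterion extend to
  other exponential-family mixtures, and the module boundaries keep that
  extension local to the model-space layer, but no other family ships.
* The non-cumulative variant intentionally disables per-stage model
  selection (the grid must be a single `k`); selection with fresh per-stage
  data only is not supported.
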