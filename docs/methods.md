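# Methods

## The dose-finding problem

A Phase I combination trial escalates two drugs over an `r x c` grid of dose
combinations, looking for the maximum tolerated dose (MTD): the combination
whose dose-limiting-toxicity (DLT) probability is closest to a pre-specified
target toxicity rate `theta`.  Toxicity is monotone within each drug's margin
but not across diagonal moves, so instead of one dose-toxicity ordering there
is a *partial* ordering, represented here as M candidate total orders
("simple orderings") with prior weights `p(m)`.

Doses are indexed 1..K column-within-row from the bottom-left of the grid
(`k = c*(i-1) + j` for drug-A level `i`, drug-B level `j`).

## Working model and inference

Under ordering `m` the DLT probability at dose `k` is modelled with the
one-parameter power model applied to the skeleton `alpha_1 < ... < alpha_K`
permuted by the ordering (`alpha_{m,k} = alpha_{I_m(k)}`):

    psi_m(d_k, a) = alpha_{m,k} ^ exp(a),     a ~ Normal(mean 0, variance 1.34)

The `exp(a)` form keeps every real `a` valid and the Normal(0, 1.34) prior is
the standard weakly-informative choice for this parametrization.  A plain
`alpha^a` form (exponent itself the parameter, prior truncated to `a > 0`)
is provided as an option because the closed-form 2x2 coherency conditions are
derived under it; the two parametrizations are never mixed inside one
analysis (the condition checkers work directly on plug-in exponents and never
touch the `exp(a)` machinery).

With per-dose counts `(n_k, y_k)` the likelihood is a product of binomials.
Per ordering we compute the marginal likelihood, the posterior ordering
probability (Bayes' rule over prior weights), the posterior mean `a_hat_m`,
and the per-ordering posterior-mean toxicity `E_m[psi_m(d_k, a)]`.

Two estimation rules are built on these quantities:

* **Model selection (POCRM)** — select `m* = argmax p(m | data)` and plug
  `a_hat_{m*}` into the working model.
* **Model averaging (BMA-POCRM)** — transform each ordering's parameter
  posterior into a posterior density of the risk itself (change of variables
  through `psi_m`), mix the densities with weights `p(m | data)`, and use the
  mixture mean.  Because integration and summation commute, the mixture mean
  equals the `p(m | data)`-weighted average of per-ordering posterior means;
  the implementation uses the latter and the test suite verifies the identity
  against direct integration of the mixture density in the risk variable.

Both rules allocate the next cohort to the dose minimizing
`|estimate - theta|` (ties to the lower dose).  Two further averaging
variants are provided for comparison: averaging per-ordering *point
estimates* (identical to the mixture mean, kept as an independent code path)
and averaging per-ordering *recommended doses* (each ordering votes with its
posterior probability; no averaged estimates exist under this rule).

The mixture density also yields equal-tailed credible intervals and overdose
probabilities `P(R(d_k) > theta | data)` directly.

## Estimation coherency

For each dose `i`, `nu_i` (`xi_i`) is the set of doses ranked less (more)
toxic than `i` under *every* candidate ordering.  An update is two-sided
estimation incoherent when, after a non-DLT at `d_i`, the estimate at some
dose in `nu_i U xi_i` rises — or after a DLT, falls.  The one-sided variant
restricts to `nu_i` (non-DLT) or `xi_i` (DLT).  Changes smaller than a
detection threshold (default 0.001) are ignored as numerical noise; the
threshold is configurable.  The magnitude of an incoherent update is the
largest wrong-direction change across violating doses (the aggregation
across doses is a package choice; the per-dose magnitudes are retained in
the event records).

Model selection is vulnerable to incoherency exactly when the selected
ordering changes between updates — an empirical invariant checked over
thousands of randomized 2x2 trials in the test suite.  Model averaging
dampens those jumps; when both designs are incoherent on the same update the
averaged magnitude is bounded by `M_S / (1 - log alpha_K)`.

For 2x2 grids with both monotone orderings at equal prior weight and the
plain power model, closed-form sufficient conditions for coherency are
implemented as mechanical checkers on the plug-in exponent sets
`A_1 = {log R_k / log alpha_k}` and `A_2` (middle skeleton values swapped):

* The model-selection condition compares `alpha_3^{min A_2}` with
  `alpha_2^{max A_1}` (and the mirrored pair).  Because `A_1` and `A_2`
  share their first and fourth elements, `max A_1 >= min A_2` always, which
  together with `alpha_2 < alpha_3` makes this condition unsatisfiable for
  any strictly increasing skeleton: the checker is faithful to the stated
  inequality and reports all intermediate quantities, but in practice it
  always returns False and the empirical auditors are the operative tool.
* The model-averaging condition (built from the same extremes and the
  auxiliary quantities `U_1..U_4`) is satisfiable — roughly a fifth of
  random 2x2 configurations meet it — and whenever it holds, exhaustive
  enumeration of every DLT path of length 6 finds zero incoherent averaged
  updates.  The exponent entering `U_4` is ambiguous in its source
  derivation; the checker defaults to the choice symmetric with `U_2`
  (`max A_1`) and exposes the alternative as a switch.

## Simulation engine

Trials run one cohort at a time (default: 60 cohorts of 1 patient), refitting
the design after every cohort.  Outcomes are pre-drawn as per-dose Bernoulli
streams so that the j-th patient ever assigned to a dose has the same outcome
under every design sharing the streams (common random numbers) — design
comparisons are then paired and outcome noise cancels.

Operating characteristics per scenario: PCS (recommended dose's true
toxicity equals `theta` exactly, tolerance 1e-9 — scenario generators place
an exact-`theta` dose where the family allows one), PAS (true toxicity in
the deliberately asymmetric interval `[theta - 0.1, theta]`), POTS (true
toxicity above `1.1 * theta`), NPTOT (mean patients treated at such doses),
incoherency statistics (fraction of trials with at least one event, mean
number of affected cohorts, maximum magnitude, threshold 0.001), and RMSE of
final estimates.

### Synthetic scenarios

The scenario generator emulates the structure of combination-trial truths
rather than any particular trial: true toxicities are strictly increasing
along one candidate ordering with independent uniform gaps of 0.04-0.11
(typical adjacent-dose spacing in this literature), clipped to [0.01, 0.95],
with the MTD placed uniformly away from the grid extremes.  Families control
how many candidate orderings rank-sort the truth: `one_correct` uses an
ordering appearing once in the candidate list, `two_correct` a duplicated
one, and `zero_correct` ties an incomparable adjacent pair so no total order
sorts the truth strictly.  `all_toxic` (minimum above `1.1 * theta`) and
`all_safe` (maximum below `theta`) probe the boundary settings.  What the
generator does **not** emulate: correlated drug interactions, non-monotone
margins, patient heterogeneity, or late-onset toxicities — passing tests
demonstrate correctness of the algorithms under the stated Bernoulli model,
not clinical performance on real trials.

### Trial replay from summary data

A completed trial reported as per-dose `(n_j, y_j)` is replayed by building
fixed response streams: the first `n_j` entries of dose j's stream are a
seeded permutation of the observed outcomes; the rest are imputed from
`Beta(1 + y_j, 1 + n_j - y_j)` (uniform prior updated by the counts; fresh
probability per synthetic patient by default, one per dose as an option),
with `Beta(3, 3)` for doses never assigned.  Fixed run-in cohorts are
entered before the first model update.  Streams guarantee identical
responses across designs wherever allocation paths overlap.

## Numerical choices

* **Quadrature.**  All parameter-space integrals use a fixed 401-node
  Gauss-Legendre rule spanning 12 prior standard deviations (positive
  half-line only for the plain parametrization), vectorized over
  orderings x nodes x doses.  The rule is deterministic (bit-identical
  reruns) and agrees with adaptive quadrature to ~1e-10 on these smooth
  unimodal integrands; a 10,001-point trapezoid is the independent test
  oracle.  Marginal likelihoods are accumulated in log space with a max
  shift.  Probabilities are clipped to `[1e-12, 1 - 1e-12]` inside logs.
* **Skeleton.**  The indifference-interval recursion is solved per step by
  1-D root bracketing (xtol 1e-12); the closed-form geometric solution is
  the test oracle.  Skeleton output is validated strictly increasing in
  (0, 1); parameter combinations that leave the unit interval raise rather
  than silently clip.
* **Ties.**  Ordering argmax ties are detected with relative tolerance 1e-9
  (exact mathematical ties can differ in the last floating-point bits when
  two orderings induce identical likelihoods) and broken toward the highest
  tied index by convention — the worked example's twelfth update hits such a
  tie, and the convention matches the trajectory shipped with the fixture;
  the lowest-index rule is available as an option.  Allocation ties go to
  the lower dose (the conservative choice); dose-voting ties likewise.
* **Degenerate inputs.**  Empty trials return the prior (uniform ordering
  posteriors, prior-mean parameter); mixture densities reject boundary
  risks r in {0, 1}; audit updates whose cohort mixes DLT and non-DLT
  outcomes are skipped (no single audit direction exists).

## Defaults and open choices

| Parameter | Default | Why |
|---|---|---|
| prior variance | 1.34 | standard weakly-informative value for `alpha^exp(a)` |
| detection threshold | 0.001 | numerical-noise guard on estimate changes |
| cohort size / length | 1 / 60 | the study conditions for the operating-characteristic comparisons |
| start dose | `d_1` | conservative; configurable (replays may start at interior doses) |
| dose skipping | allowed | the pure allocation criterion; a one-untried-level-per-margin clamp is provided as an option reflecting common practice |
| stopping | fixed horizon | no early-stopping rules; safety hooks can be layered on top |
| tie break (orderings) | highest index | matches the shipped worked-example trajectory; deterministic |

The package ships no real patient data; the worked-example fixture is a
configuration plus count vectors, and replays of real trials require the
user to supply their own summary table.

## Problem sizes used in the shipped checks

The acceptance script recomputes only the deterministic worked example
(12 patients).  The test suite's empirical theory checks use 1,000
randomized 2x2 trials of 12 patients and exhaustive enumeration of all 64
six-patient DLT paths; the design-comparison property uses 3 synthetic 3x2
scenarios at 500 replicates of 60 single-patient cohorts.  These sizes give
stable verdicts for the directional and invariant claims they check; they
are not calibrated to reproduce magnitude-level operating characteristics,
which depend on scenario sets not shipped here.

## Known limitations

* Two-agent grids only; no dose-schedule or three-agent partial orders.
* One-parameter working models only (no two-parameter logistic).
* The 2x2 condition checkers do not extend to larger grids; for those the
  empirical auditor is the only coherency instrument.
* Ordering posteriors are exact up to quadrature on a single scalar
  parameter; no MCMC is needed or provided.
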