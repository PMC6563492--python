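# Methods

## Model

Each subject contributes q repeated measurements

y_i = X_i β + Z_i b_i + ε_i,  b_i ~ N(0, D),  ε_i ~ N(0, σ²Ψ),

with b_i and ε_i independent across and within subjects. Two mean
structures are implemented. Under the group model (`Mg`, p = c + 1 fixed
effects) all arms share an intercept and each arm has its own time
slope, selected by an indicator structure, so arms are exchangeable at
baseline. Under the dose model (`Md`, p = 3) the mean is
β0 + β1·t + β2·δ and the dose level δ of each arm is itself a design
variable. Random-effect classes: none (`FE`), random intercept (`RI`,
Z = 1), independent or correlated random intercept and slope
(`RIRS`/`RIRSc`, Z = (1, t)). Serial correlation Ψ is the identity,
compound symmetry (ρ off the diagonal) or AR(1) with
ψ(t_j, t_j′) = ρ^|t_j − t_j′|.

Time units are whatever the caller uses — standardized [−1, 1] regions
or days — and ρ is interpreted per unit of that scale; nothing is
rescaled internally. A consequence worth knowing: with schedules spaced
tens of days apart and ρ ≈ 0.33/day, AR(1) correlation is numerically
negligible except between near-coincident occasions. AR(1) at ρ = 0 is
defined as the identity (continuity convention; 0⁰ = 1 on the
diagonal).

## Dropout and expected information

Dropout is monotone and noninformative: the probability that a subject
of a group is still observed at time t is a non-increasing
response-probability function p(t, δ) — linear, quadratic, logistic, or
constant 1. The count of subjects with exactly j observed occasions is
multinomial. The logistic family cannot reach p = 1 at baseline, so its
successive differences would not sum to one; we therefore treat the
baseline measurement as always observed (`baseline_certain`, the
default), giving event probabilities

π_1 = 1 − p(t_2),  π_j = p(t_j) − p(t_{j+1}),  π_q = p(t_q),

which coincide with the literal differences whenever p(t_1) = 1. The
literal form is available (`baseline_certain=False`) and validates
p(t_1) = 1 to 1e−9. Monotonicity is checked numerically on a
1000-point grid, not symbolically.

A subject observed at the first j occasions contributes the information
of the truncated design against the leading j×j block of V
(marginalization of a multivariate normal), and the dropout-expected
information is M(ξ) = Σ_k Σ_j m_kj X_k[j]ᵀ V_k[j]⁻¹ X_k[j] with
m_kj = N w_k π_kj. Its inverse is used as the covariance approximation
throughout; no higher-order correction is applied.

One convention deserves emphasis. When the first two occasions are
fixed by the experimenter and the design region truncated (the standard
device for logistic dropout), the design-search criterion *discounts
subjects whose only measurement is the baseline* (the j = 1 pattern,
which carries intercept information only and whose mass 1 − p(t_2)
does not depend on any free variable). This is the
`include_baseline_only=False` setting used by the bundled trial
problems; it is what reproduces the published optimal schedules of this
problem family to four decimals. With the pattern included, the
criterion surface is so flat that the optimum moves by only ~2 days
(criterion difference ~2e−5). The expected-count tables always include
the pattern, so the reported counts sum to the group allocations.

## Design search

The decision variables are the free occasion times (one shared schedule
under the *restricted* condition, one per arm under *flexible*), c − 1
allocation weights, and any free dose levels. The objective is
−log det M(ξ), computed via slogdet with an eigenvalue guard; infeasible
or singular points return a large penalty. Constraints: box bounds on
every variable, strict ordering enforced as t_{j+1} − t_j ≥ ε with
ε = 1e−6 × region width, weights in [1e−4, 1 − 1e−4] with a simplex
inequality for c > 2. SLSQP is run from one deterministic equispaced
start plus seeded random feasible starts (n_starts = 20 by default),
the incumbent is polished with a tighter tolerance, and the reported
criterion is recomputed from scratch on the assembled design. The
ρ-profile solver warm-starts each grid point from the previous
solution.

Local optima are real: with white errors (ρ = 0) and no random slope,
the criterion rewards ε-separated replicate occasions at the region
ends, which can beat the symmetric interior solution; the multistart
reports whichever is best. Endpoint conventions follow standard
practice: first occasion at the region's lower bound (highest response
probability), last at the pre-selected end of study; under logistic
dropout the second occasion is fixed too. Published four-decimal time
points are reproduced only up to optimizer tolerance — the surfaces are
flat to ~1e−5 over a day or more, so reproductions within ~1 day are
the realistic expectation. Doses land on a bound of the dose region
whenever the criterion is monotone in δ; no special casing is applied.

## Cost model

A subject measured at q occasions costs recruit_cost + (q − 1) ×
visit_cost, with recruitment covering the baseline measurement. The
affordable sample size floor(budget / per-subject-cost) charges every
*planned* visit whether or not the subject drops out — the conservative
convention when budgets are committed up front — and `cost_scan`
re-solves the design problem at each candidate q with the matching N.

## Simulation and estimation

`simulate_trial` draws, per subject: random effects, then errors from
the Cholesky factor of σ²Ψ, then the dropout pattern — in that fixed
order, so a seed determines the data bit-for-bit. Estimation is
available-case generalized least squares with the variance components
held at the simulation truth (the ML estimator for known covariance);
per-replicate re-estimation of variance components is deliberately out
of scope, a limitation that affects absolute variance levels slightly
but not efficiency ratios between designs.

`evaluate_designs` exploits a collapse: the GLS estimate depends on the
data only through per-(group, pattern) sums of response vectors, and a
sum of g i.i.d. N(μ_j, V_j) vectors is N(g μ_j, g V_j). Each replicate
therefore draws multinomial pattern counts and one Gaussian sum per
cell — distributionally identical to subject-level simulation (the test
suite cross-checks the two paths) and orders of magnitude faster.
Group sizes come from largest-remainder rounding of N w_k so they sum
to N exactly. Relative D-efficiencies between designs are computed from
the empirical covariance matrices, with a standard error estimated by
splitting the replicates into 20 batches.

## Synthetic data: what it does and does not emulate

The simulator generates exactly the assumed model: Gaussian responses,
linear mean in time (and dose), monotone multinomial dropout
independent of outcomes. It does not emulate informative dropout,
intermittent missingness, floor/ceiling effects of bounded cognitive
scores, measurement-occasion jitter, or model misspecification. Passing
tests therefore certify the framework's internal consistency and its
optimality claims *under the assumed model*, not robustness to
violations of it — the sensitivity machinery (alternative D structures,
ρ-profiles) is the intended tool for exploring that.

## Numerical choices and defaults

- Positive-definiteness threshold for response covariances: smallest
  eigenvalue 1e−10; failures raise rather than regularize.
- Criterion comparisons use log determinants throughout to avoid
  overflow at N ≈ 150 scales.
- Ordering gap ε = 1e−6 × region width; near-coincident occasions are
  legitimate solutions, ties are not.
- Expected-count tables round half away from zero; cells whose exact
  value is within ~0.06 of a half-integer can differ by one unit from
  other implementations' tables.
- The bundled one-year-trial constants use the squared reading of the
  pilot variance estimates (σ² = 2.613², d11 = 2.661²); for the
  random-intercept model only the ratio d11/σ² and ρ affect the optimal
  times, so the alternative literal reading moves the optimum
  negligibly.
- Default problem sizes: 100 000 simulation replicates per design in
  the acceptance script (batching SE on efficiency ratios ≈ 0.004),
  50 000 in the heavier tests, multistart counts 10–20.

## Known limitations

- Only D-optimality; no A-/E-/c- or compound criteria.
- No global-optimality certificate (no equivalence-theorem check);
  multistart SLSQP is a heuristic, mitigated by grid-search oracles in
  the tests for low-dimensional problems.
- Variance components are nuisance parameters fixed at assumed values
  (locally optimal designs); no Bayesian or maximin robustification.
- At most two random effects (intercept, slope); no GLMMs; no
  informative or intermittent missingness.
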