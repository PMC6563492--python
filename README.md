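# lmmdesign

D-optimal experimental designs for multiarm trials with repeated
measurements and design-dependent dropout.

Longitudinal trials lose subjects as they run: the longer the follow-up
and the less effective the treatment, the fewer subjects remain under
observation. Ignoring this at the planning stage wastes measurements on
occasions that few subjects will reach. `lmmdesign` is for trial
statisticians who want to choose measurement schedules, group allocation
weights and dose levels that maximize the information actually expected
from an incomplete data set — and to trade follow-up occasions against
sample size under a fixed budget.

## Model and criterion

Responses of subject *i* follow a linear mixed model

```
y_i = X_i β + Z_i b_i + ε_i,    b_i ~ N(0, D),    ε_i ~ N(0, σ²Ψ),
```

with serial correlation Ψ (AR(1): ψ(t_j, t_j′) = ρ^|t_j − t_j′|, or
compound symmetry) and random-effect structure D (fixed effects only,
random intercept, random intercept + slope, optionally correlated). Two
mean structures are built in: a common intercept with one time slope per
group (`Mg`), and an intercept + time slope + dose slope model (`Md`)
for dose-finding.

Dropout is noninformative and monotone: a group's probability of still
being observed at time *t* is a non-increasing response-probability
function p_obs(t, δ) (linear, quadratic or logistic families). The
number of subjects in group *k* with exactly *j* observed occasions is
multinomial with expectation m_kj, and the expected Fisher information
of the fixed effects under available-case analysis is

```
M(ξ) = Σ_k Σ_j m_kj · X_k[j]ᵀ V_k[j]⁻¹ X_k[j],
```

where the `[j]` blocks are the leading *j* rows/block of the group's
design matrix and response covariance. A design
ξ = {t_k, w_k, δ_k; N} is locally D-optimal when it maximizes
log det M(ξ) over the design region, subject to strictly increasing
schedules and weights on the simplex. Designs are compared by relative
D-efficiency, RED(ξ, ξ*) = (det cov* / det cov)^(1/p).

## Worked example

Redesign of a one-year, two-arm Alzheimer's trial (placebo vs active
treatment, doses 0 and 100, N = 144, five occasions with days 0, 42 and
364 fixed), using the pilot-fitted random-intercept AR(1) model and
logistic retention:

```python
from lmmdesign import optimize_design
from lmmdesign.alzheimer import five_point_problem

sol = optimize_design(five_point_problem(), seed=1, n_starts=20)
g = sol.design.groups[0]
print("schedule:", [float(round(t, 4)) for t in g.t])
print("placebo weight:", round(g.w, 4), " placebo dose:", round(g.dose, 4))
```

prints

```
schedule: [0.0, 42.0, 285.2353, 355.6951, 364.0]
placebo weight: 0.4221  placebo dose: 0.0
```

i.e. the D-optimal schedule measures everyone at days 0, 42, ~285, ~356
and 364, assigns 42% of subjects to placebo (the arm with heavier
dropout is made smaller) and puts the active arm at the top of the dose
region. The expected-count report for this design
(`lmmdesign report examples/design_comparison.yaml --design xi_D_star`)
shows how many subjects are expected to reach each occasion.

Simulating both the original schedule (days 0/42/126/210/364, equal
arms) and the optimum under the fitted generative model
(`lmmdesign evaluate examples/design_comparison.yaml`) shows the
original design is ~8% less efficient per fixed-effect parameter, and a
four-occasion design funded at N = 172 from the same budget (recruiting
costs twice a follow-up visit) beats the five-occasion optimum by ~9%.

The command-line interface mirrors the library: `optimize`,
`profile-rho`, `evaluate`, `simulate`, `cost-scan` and `report`, each
taking a YAML configuration (see `examples/`).

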