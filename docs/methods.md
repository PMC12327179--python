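# Methods

## Model and assumptions

`psfcoex` couples two competing plant populations to an arbitrary number of
microbial taxa. Plants grow logistically with direct per-capita interaction
coefficients `c_ij` (competition encoded as negative values; the type
admits any sign, and downstream analyses check signs explicitly) and an
additive per-capita effect `σ_iX S_X` from each microbial taxon. Each
microbe grows logistically towards a carrying capacity set entirely by the
plants that cultivate it, `k_X = φ_XA N_A + φ_XB N_B` — microbes track
plant abundance rather than having an independent niche. The framework is
phenomenological: interaction coefficients stand in for whatever resource
or chemical mechanism produces them, which keeps the model parameterizable
from competition experiments but means resource-mediated feedbacks with
their own dynamics are out of scope, as are more than two plant species
(the coexistence machinery used here is strictly pairwise) and any
fluctuation-dependent coexistence mechanism (the environment is a fixed
scalar per analysis, not a process in time).

Environmental context enters through scaling rules: any `c`, `σ` or `φ`
parameter may be declared a linear function `θ̂₀ + v·θ̂₁` of a scalar
environmental variable `v`. A rule *replaces* the static value in the
configuration (the scaling function defines the whole parameter, not a
perturbation; a shadowed static value triggers a warning). Cultivation
rates cannot be negative, so `φ` rules are clamped at zero, making them
piecewise-linear: they follow the line where it is non-negative and stay
at zero otherwise. Nonlinear monotone scaling can be supplied through the
`function` hook on a rule; the linear form is the only built-in.

## Reduction and coexistence metrics

With microbes at quasi-equilibrium (`S_X = k_X`), substituting `k_X` into
the plant equations yields plain two-species Lotka–Volterra dynamics with
effective coefficients `α_ij = c_ij + Σ_X σ_iX φ_Xj`. The additivity over
taxa is exact, which is also why metrics are invariant to splitting a
taxon's cultivation mass across clones (tested).

Niche overlap `ρ = sqrt((α_AB α_BA)/(α_AA α_BB))` and the fitness ratio
`f_B/f_A = sqrt((α_AA α_AB)/(α_BB α_BA))` are defined only when all four
`α_ij` are negative; any facilitative entry makes the square roots
meaningless and the metrics are reported as NaN with `defined=False`. The
outcome classifier does not use the band form `ρ < f < 1/ρ`: it evaluates
the mutual-invasibility inequalities directly (`i` invades `j`'s resident
monoculture iff `α_ij > α_jj`), which is algebraically equivalent where
both are defined (the identities `f·ρ = |α_AB|/|α_BB|` and
`f/ρ = |α_AA|/|α_BA|` give the equivalence, and a property test checks it
on 1000 random matrices) but remains valid under facilitative off-diagonal
entries. Missing self-limitation (`α_ii ≥ 0`) raises an error in direct
calls and is labelled `undefined` in gradient tables so scans can cross
such regions.

Boundary flagging uses a relative tolerance of 1e-9 on the invasion
margins and on `ρ − 1`: analytic fixtures sit exactly on metric boundaries
(one built-in scenario has `ρ = 1` with both invasion inequalities strict)
and must be labelled deterministically while still being marked as
borderline.

## Numerical choices

* **Integration.** `scipy.integrate.solve_ivp` with the implicit Radau
  method, rtol 1e-8, atol 1e-10. Extinction trajectories drive a microbe's
  carrying capacity to zero, which makes the logistic term arbitrarily
  stiff; auto-switching methods were observed to step over the decay and
  produce non-finite states, while Radau resolves it. Any `solve_ivp`
  method name can be passed instead. Non-finite or failed integrations
  raise with the last good state attached. Negative overshoots smaller
  than the absolute tolerance are clipped to zero.
* **Degenerate carrying capacity.** The microbe equation divides by `k_X`;
  below `k_X = 1e-12` (abundance units) it switches to pure decay
  `−g_X S_X`, the correct limit of the logistic as capacity vanishes (and
  the reachable state once a clamped cultivation rate hits zero).
* **Defaults `r_i = g_X = 1`.** Equilibria, metrics and outcome labels are
  independent of these rates (tested for `g` across two orders of
  magnitude); they only set transient timescales, so neutral defaults are
  used and are overridable everywhere.
* **Convergence** is reported (not asserted) as `max|dy/dt| < 1e-8` at the
  final time.
* **Equilibria.** The interior point solves `1 + αN = 0` by a dense 2×2
  linear solve; determinants below 1e-12 relative to `max|α|²` are treated
  as singular and reported infeasible with a reason, as are non-positive
  solutions.
* **Transition location.** Gradient scans use a 256-point coarse scan to
  bracket label changes, then bisection to a default bracket width of
  1e-6. Multiple regime changes inside one coarse cell would be collapsed
  to a single reported transition; the shipped scenarios are nowhere near
  that resolution limit.

## Sensitivity analyses

One-at-a-time sweeps hold everything at baseline and move one parameter
across its box (default 201 grid points — fine enough to resolve the
boundary curvature as `α` entries approach zero). The standard boxes are
`c ∈ [−0.1, 0]`, `σ ∈ [−0.01, 0.01]`, `φ ∈ [0, 20]` and, for composite
feedback terms `m_ij = σ_iX φ_Xj` treated as directly manipulable
quantities, `m ∈ [−0.2, 0.2]` (the product range implied by the σ and φ
boxes). Rows where any `α ≥ 0` are retained with `defined=False` rather
than dropped, so downstream consumers can see where curves truncate.

Local sensitivities are closed-form: log-differentiating the two metrics
gives each partial as a weighted sum of `(∂α_ij/∂p)/α_ij`, with
`∂α/∂c_kl` an indicator, `∂α_i·/∂σ_iX = φ_X·` and `∂α_·j/∂φ_Xj = σ_·X`.
Every closed-form partial is verified at call time against a central
finite difference (step 1e-6 of the box width, relative tolerance 1e-4);
baselines on a definedness boundary raise and point the caller to sweeps.

The global screen draws a Latin hypercube jointly over all boxes and
estimates each parameter's first-order index as the variance of 20-bin
conditional means over the variance of the metric, excluding undefined
samples and reporting their fraction. This estimator is an implementer
choice and is labelled as such in the output metadata. The fitness ratio
is heavy-tailed near the definedness boundary (it diverges as an
interspecific `α` approaches zero), so index estimates stabilise only in
the several-thousand-sample regime; the default is 8192 samples, at which
the σ-over-φ importance ordering is reproducible across seeds.

A note on sweep directions at the shared-pathogen baseline
(`σ_A = −0.002, σ_B = −0.00225, φ_A = 10.5, φ_B = 10`): the niche
difference is monotone in every primitive parameter, growing with
intraspecific interaction strength and with σ (pathogen → mutualist
direction), shrinking with interspecific strength — but its direction in
the cultivation rates is *not* universal. Cross-multiplying the linear
numerator and denominator of `ρ²` shows the sign is decided by which
plant's σ has the larger magnitude: at this baseline the competitor's σ
outweighs the host's for both φ targets, so the niche difference declines
as either cultivation rate rises. The tests assert the analytically
verified directions rather than a blanket rule.

## Built-in scenarios and the synthetic invasion configurations

The theory scenarios (`ThSi-*`, `SeAn`) carry their published
parameterizations verbatim, tagged `literature` per parameter and asserted
to the printed decimal in tests. The invasion case-study configurations
(`InSi-I/II/III`) model a garlic-mustard-style invader: published numeric
values for these are not available, so the shipped numbers are synthetic —
constraint-chosen, tagged `constraint-chosen`, and selected once to
satisfy every stated qualitative property: the invader dominant in sterile
soil (`|c_AA| < |c_BA|`, `|c_BB| > |c_AB|`); an invader-specific pathogen
(`σ_AX = −0.002`) whose cultivation `φ_XA = max(v − 2, 0)` rises with soil
moisture and yields coexistence at the gradient midpoint; a
native-specific mutualist (`σ_BY = +0.0025`) with cultivation
`φ_YB = max(8 − v, 0)` declining in moisture; and a generalist decomposer
(`σ_AZ = +0.0024, σ_BZ = +0.0005`) cultivated by both plants at rates
rising with moisture. Under these choices the three gradients produce, by
construction, the regime sequences exclusion→coexistence (boundary at
moisture 7), priority→exclusion→coexistence (boundaries 2 and 7), and
priority→exclusion with no coexistence anywhere on `[0, 20]` (the
native's invasion margin stays negative because the decomposer's benefit
to the invader offsets the pathogen's stabilisation). Only these
qualitative sequences are claims; the specific numbers are illustrative.

## What the tests do and do not show

The random-model generators sample direct competition in `[−0.1, −0.02]`,
microbial effects in `[−0.003, 0.003]` and cultivation in `[0, 10]` —
the same order of magnitude as the built-in scenarios, representing
abundant microbes with small per-capita effects. Agreement between the
classifier, the band rule and rare-invader ODE growth is checked away from
invasion-margin boundaries (relative margin ≥ 0.1 for the ODE oracle,
since a sign read off a finite-time trajectory is meaningless at a
boundary). Passing these tests shows the algebra, the classifier and the
dynamics are mutually consistent under the model's own assumptions; it
says nothing about how well a linear scaling or a logistic microbe tracks
any real soil community, and nothing about fluctuation-driven coexistence,
spatial structure, or demographic noise, none of which are modelled.
Problem sizes (1000 random matrices, 100 ODE cross-checks, 20 random
coexistence models × 3 microbial growth rates, 8192 screen samples) were
chosen so each analysis is reproducible in seconds on one core.
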