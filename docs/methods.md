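# Methods

## The model

`fimdesign` simulates and calibrates a six-gene regulatory network in
which each gene *j* is described by two state variables, its mRNA and
protein concentration:

    d[mRNA_j]/dt = cod_j − mRNA_deg_rate · [mRNA_j]
    d[p_j]/dt    = rbs_j_strength · [mRNA_j] − p_deg_rate · [p_j]

`cod_j` is the gene's promoter strength `pro_j_strength` multiplied by a
Hill term for every incoming regulatory edge: `u/(1+u)` for activation
and `1/(1+u)` for inhibition, with `u = ([p_reg]/K)^h`.  The network has
eight edges: gene 1 is constitutive and activates genes 2, 3 and 4;
gene 2 inhibits 3; gene 6 inhibits 2; gene 5 inhibits 4; and gene 4
inhibits both 5 and 6 (a negative feedback loop through genes 4/5).

Conventions: every mRNA degrades at the fixed rate 1 (this sets the
time unit), all proteins share one unknown degradation rate, initial
mRNA concentrations are 0 and initial proteins 1.  Each edge carries one
half-saturation constant `K` and one Hill exponent `h` (the exponent is
shared between the numerator and denominator of the activation term).
That leaves 29 free parameters: 6 promoter strengths, 6 translation
(`rbs`) strengths, 8 K's, 8 h's and `p_deg_rate`.

Perturbations are evaluation-time overrides so the free-parameter list
never changes: deletion forces a gene's `pro` and `rbs` strengths to 0,
overexpression doubles its `rbs` strength, knockdown multiplies its
(and only its) mRNA degradation rate by 5.

## Synthetic data

The generator emulates the measurement menu of a network-inference
challenge.  Time series span t = 0..20 (by which the system has reached
steady state), with 21 points for mRNA and 41 for proteins.  A
"microarray" returns all six mRNA series; a "protein pair" returns two
protein series; a "gel-shift assay" returns direct noisy estimates of
one edge's log K and log h (Gaussian, sigma = 0.1 in natural-log space —
the assay's noise level is our modelling choice, as only the assay's
existence is specified by the challenge setting).  Observation noise is
two-channel Gaussian, `y = max(0, v + C1 ξ1 + C2 ξ2 v)` with C1 = 0.1
(absolute) and C2 = 0.2 (relative); reported uncertainties are
`sigma = sqrt(C1² + (C2 y)²)` computed from the *observed* value.  The
candidate catalog crosses 19 perturbations with 16 time-series
measurements and adds 8 assays: 312 experiments.  No multi-gene
perturbations, no altered initial conditions, and experiments carry no
prices.

Ground-truth parameters are drawn log-uniformly: [0.5, 2] for
`p_deg_rate` and the Hill exponents, [0.25, 4] for strengths and K's.
These ranges keep truths well inside the penalty-defined plausible
region (so recovery is possible in principle) while producing diverse
dynamics.  What the generator does *not* emulate: model mismatch (the
fitted equations are exactly the generating equations), non-Gaussian or
correlated noise, and measurement dropout.  Passing tests therefore
demonstrate the selection machinery, not robustness to misspecification.

## Fitting

The cost is half the squared norm of the stacked residual vector: data
residuals `(y_obs − y_pred)/sigma` plus, for every parameter, two
penalty residuals `w·θ` and `w/θ` whose joint minimum sits at θ = 1.
Weights are 0.1 for `p_deg_rate` and Hill exponents (these parameters
are only identifiable within about an order of magnitude of 1) and
1e-4 for the rest (free to move over ~8 orders).  The penalties exist to
keep search away from regions where the ODEs become unintegrable; they
are weak enough not to move final estimates appreciably.

Optimization is Levenberg–Marquardt over x = log θ (which enforces
positivity and makes the 29 axes commensurate).  Implementation choices
that mattered:

- **Identity damping.**  Marquardt's diag(JᵀJ) scaling is disastrous
  here: sloppy directions have near-zero curvature, so scaled damping
  permits enormous steps along them and the iteration thrashes.  With
  λI damping in log parameters the same problems converge in ~100
  iterations.
- **Failure handling.**  ODE-solver failures (and log-parameter
  overflow) during a trial step are treated as infinite-cost points so
  the iteration retreats; a failure at the current iterate aborts the
  fit with status `solver_failed`.
- **Convergence.**  The monitor is the angle α between the residual
  vector and the tangent plane spanned by the Jacobian columns (the
  model-manifold convergence criterion); cos α < 1e-4, or a step below
  1e-10, declares convergence.  α and the tolerance are stored in the
  fit record because the distinct-minima diagnostic derives its
  resolution limit |r|·cos α from them (cos α floored at the configured
  tolerance).
- λ decreases ×10 on acceptance and grows ×7 on rejection.

Multistart draws starts log-uniformly over the penalty ranges
([w, 1/w] per parameter).  All statuses are recorded so success rates
are measurable; typical success is tens of percent, with failures at
extreme starts due to integration breakdown — mirroring behaviour at
the full 10,000-start scale.

Sensitivities `∂y/∂log θ` come by default from the analytic
forward-sensitivity system (the 12 state equations augmented with their
360 variational equations), integrated with the same stiff-capable
solver; a central finite-difference fall-back (`method="fd"`, step 1e-6
in log parameters) implements the identical contract and cross-checks
the analytic path in tests.  The forward system is ~30× faster per
Jacobian and is what makes the design loop affordable.  Solver
tolerances default to rtol 1e-8 / atol 1e-10 (far below the noise
floor); the design-loop tests and examples use rtol 1e-6 / atol 1e-8,
which changes costs by amounts negligible against C1 = 0.1.

## Information and criteria

The Fisher information is I = JᵀJ with J the Jacobian of the σ-scaled
*data* residuals in log parameters — penalty rows are excluded so I
measures experiment information only.  All spectral quantities use the
SVD of J rather than eigen-decomposition of I; singular values below
1e-8 of the largest are treated as exact null directions.

- `D_param = (1/N) Σ 1/s_μ²` estimates the mean squared log-parameter
  error; it is infinite while any direction is unconstrained.
  Calibration: uniform 10% uncertainty ⇔ D = 0.01, 30% ⇔ ≈ 0.1 (this
  calibration is why natural logs are used throughout).
- `D_pred = (1/M) trace(I_pred I⁻¹)` propagates parameter uncertainty
  into a set of M target predictions, with I_pred the information the
  predicted observables would carry (σ from the noise model applied to
  predicted values).  The inverse is the SVD pseudo-inverse; if the
  prediction loads on a null direction of I, D_pred is infinite.

The default prediction target asks for proteins 2, 4 and 6 on the
41-point grid under a strong perturbation of gene 4 (translation ×10,
promoter ×2, feedback constant K8 ×5) — a stand-in, chosen once, for a
challenge-style "perturbed time course" target whose exact factors are
not public.

## Greedy selection

Each iteration refits the model (warm start from the previous best fit
plus optional random restarts), simulates every catalog candidate
*noiselessly* at the best fit, appends the candidate's σ-scaled
sensitivity rows to the current data Jacobian, and scores the stacked
matrix with D_param or D_pred.  The minimum-D candidate is purchased;
its data are then generated from the *true* parameters with noise.  Ties
break by catalog order; candidates whose simulation fails score
infinite.  The loop stops at D ≤ stop_D (default 0.01, i.e. ~10%
parameter uncertainty) or an iteration cap.  Assay candidates
contribute two rows with 1/assay_sigma in their log K / log h columns.
The history records both the score at selection time and the criterion
recomputed after refitting, since the two differ whenever refitting
moves the evaluation point.

Inside the loop the optimizer runs with a capped iteration budget and a
slightly relaxed angle tolerance (1e-3): selection needs a good fit,
not a polished one, and the relaxation cuts loop time several-fold.  A
random-selection baseline draws purchases uniformly from the catalog
under an otherwise identical loop.

## Diagnostics

Fit ensembles on sparse data show the sloppy-landscape phenomenology:
fits classify as *good* when their data cost is both within a factor
(default 3) of the ensemble minimum and within 5 standard deviations of
the chi-square expectation n/2 — the second clause is what separates
"statistically acceptable" from merely "best found".  Distinctness of
two fits is judged in residual space: they are the same minimum if
their residual vectors are closer than the optimizer's resolution
|r|·cos α; the distinct-minima count is the number of connected
components of the indistinctness graph (the relation is not
transitive).  Straight-line cost profiles in log-parameter space
measure the barriers between minima.  PCA of the good fits (in log
parameters, the space where fitting happens) yields the ensemble's
dominant-variance subspace, which is compared to the span of the
smallest right singular vectors of J via principal angles; the null
reference draws uniformly random subspace pairs (orthonormalized
Gaussian frames) in the 29-dimensional parameter space.

## Problem sizes used in tests

The package's tests run the full pipeline at reduced scale, chosen once
as the smallest sizes at which each qualitative claim is still a
meaningful statistical statement: multistart landscape surveys use
~30 starts (not 10,000); the greedy loop runs with 8 initial starts and
warm-only refits; greedy-vs-random uses 5 replicate truths with the
random arm capped at twice-plus-one the greedy count; the reduced-noise
recovery check regenerates the designed sequence's data at 0.1× noise
and refits from 8 fresh starts.  The acceptance script
(`scripts/acceptance.py`) recomputes the desk-scale quantities — the
D-criterion calibration and the 4000-replicate random-subspace null —
from scratch at every run.

## Known limitations

- Standard Levenberg–Marquardt is used; the geodesic-acceleration
  variant converges faster on sloppy manifolds and would raise the
  multistart success rate.
- The distinct-minima count is tolerance-dependent by construction;
  only its order of magnitude is meaningful.
- D_pred's trace formula assumes the data information is invertible on
  the directions the prediction probes; the implementation returns
  infinity otherwise rather than regularizing.
- Greedy selection is one-step-ahead; no batch or budget-constrained
  design is attempted.
- Gel-shift assay noise (log-normal, σ = 0.1) is an interpretation; the
  ranking position of assays in a designed sequence shifts with this
  choice.
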