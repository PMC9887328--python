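# Methods

This note documents the statistical machinery in `landmed`, the assumptions
behind it, the numerical choices made where the design was open, and what the
synthetic-data generator does and does not emulate.

## Sparse FPCA by conditional expectation (`landmed.fpca`)

Tumor-burden measurements are modelled as noisy evaluations of a smooth
subject-level process, Y_ij = η₀(t_ij) + D_i(t_ij) + ε_ij with
ε ~ N(0, σ²), and D_i expanded in the eigenbasis of its covariance,
D_i(t) = Σ_k γ_ik ρ_k(t), Var(γ_ik) = λ_k.

**Estimation.** The mean η₀ is a local-linear smooth (Gaussian kernel) of all
pooled (t, Y) points.  The covariance surface is a two-dimensional
local-linear smooth of raw residual cross-products for visit pairs j ≠ l;
same-visit products are excluded because their expectation carries the extra
σ², and σ̂² is recovered as the average gap between a one-dimensional smooth
of squared residuals and the surface diagonal over the central 80% of the
domain (boundary regions are data-sparse and bias-prone), floored at 1e-8.
Both smoothers operate on data binned to the evaluation grid — exact when
visits lie on the grid, as simulated schedules do, and O(grid) instead of
O(pairs) — with bin counts as weights.

**Bandwidths** are selected by generalized cross-validation over a geometric
candidate grid (8 candidates spanning ~1.5 grid spacings to 40% of the
domain for the mean; 6 candidates for the covariance), separately for mean
and covariance, with a fallback of 10% of the domain if GCV degenerates.
Nothing in the pipeline is sensitive to the exact candidate set; the GCV
leverage term uses the own-bin kernel weight.

**Eigendecomposition** is performed on the quadrature-weighted surface
(trapezoid weights W: eigh of W^{1/2} G W^{1/2}).  Eigenvalues are clipped at
zero; eigenfunctions are renormalized to unit L² norm and signed so each has
a non-negative integral (falling back to a non-negative left-most non-zero
value), which makes scores reproducible across runs.  The default grid is 51
equispaced points on [0, 1]; quadrature error is negligible at that density.

**Scores** are best linear predictions
γ̂_ik = λ_k φ_k(t_i)' Σ_i⁻¹ (y_i − μ_i) with
Σ_i = Φ_i Λ Φ_i' + σ̂² I built from all retained components at the subject's
own visit times (a 1e-8 ridge is added if Σ_i is numerically singular).  For
dense, low-noise data this reduces to the plain inner product ∫(Y − η₀)ρ_k;
for a subject with a single noisy visit it shrinks the raw projection toward
zero — the behavior that makes the summaries usable at early landmarks.

**Component count** K is the smallest number of components whose cumulative
fraction of variance explained reaches a threshold, default 0.90 (a fixed K
or a stricter threshold can be supplied for sensitivity analyses).

**Landmark protocol.** The eigensystem (mean, eigenfunctions, eigenvalues,
σ²) is fitted once on the full observation window and then held fixed;
at each landmark only the scores are recomputed from measurements strictly
before the landmark.  This moving-window scheme avoids refitting FPCA per
landmark and guarantees that summaries never use post-landmark data (the
suite verifies this by perturbing post-landmark values).  When the landmark
exceeds a subject's last visit, landmark scores equal full-data scores
exactly.

## Mediator variants (`landmed.response`)

* `binary` — objective response: 1 if any pre-landmark post-baseline value is
  ≤ 70% of baseline (a 30% decrease, ties inclusive per RECIST practice) or
  equals 0.  No confirmation scan is required and progression/stable-disease
  distinctions are ignored; the indicator is "ever PR-or-CR before the
  landmark", so it is monotone non-decreasing in the landmark.  Baseline is
  the earliest visit (t = 0 in simulated data).
* `fpc` — the first K conditional-expectation scores in the pre-landmark
  window.
* `integrated` — ÎD_i = ∫₀^min(τᵢ, L_p) D̂_i(s) ds by trapezoid quadrature of
  the K-truncated reconstruction; a cumulative-exposure summary on the scale
  the simulator's hazard actually uses.
* `none` — reference model without tumor-burden information.

## Landmark proportional-hazards models (`landmed.cox`)

Risk sets use the strict rule T̃_i > L_p with residual time T̃_i − L_p.
Partial-likelihood maximization (Efron tie handling, Newton iterations,
score tolerance 1e-9, 50 iterations) is delegated to statsmodels' PH
machinery; monotone-likelihood divergence (|coef| > 25) is flagged rather
than silently returned.  The baseline cumulative hazard is the Breslow
estimator with Efron correction for tied event times, evaluated at the
sample mean of the predictors; the centering vector is stored on the fit so
dynamic predictions Ŝ(L_p + t | L_p) = exp(−Ĥ₀(t))^exp(θ'(x − x̄)) are
center-consistent.  Horizons beyond the last baseline jump extrapolate flat
with a warning.  Landmarks whose risk set carries fewer than 5 events
(configurable) are skipped with a warning rather than fitted unstably.

Survival time and longitudinal time may live on different scales (days vs a
[0, 1]-rescaled axis): the dataset records the rescaling divisor and landmark
sweeps map survival-scale landmarks onto the longitudinal axis by dividing by
it.  No administrative truncation of residual time is applied within a
landmark model.

Default landmark grids: deciles (10th–90th) of observed event times for real
data; 0.2 to 2.0 in steps of 0.2 on the simulation time scale.  Both are
overridable.

## Prediction metrics (`landmed.metrics`)

The landmark AUC at horizon u is the fraction of concordant (case, control)
pairs — cases fail in (L_p, L_p + u], controls survive past L_p + u — with
ties counted ½.  Subjects censored inside the window are excluded from both
sets; this naive estimator is mildly optimistic under heavy within-window
censoring, and no inverse-probability weighting is applied (the weighted
Brier variant in particular is known to be numerically unstable, and is
deliberately not implemented).  The "C-index at the median" anchors the
horizon at the median observed event time; landmarks at or past the median
return NaN and are skipped.  The true-probability Brier score,
mean{(I(T > L_p + u) − Ŝ)²} over subjects truly at risk, requires uncensored
truth and is therefore a simulation-only tool; it is a proper score, so the
generating model attains the lowest expected value.

## R² mediation effect sizes (`landmed.mediation`)

The direct (A), mediated (R) and full (A, R) PH models are fitted by the same
routine as the landmark models (one code path).  Survival-model covariates Z
are excluded from all three models by default — the canonical decomposition —
and an `include_Z` flag adds them to all three symmetrically.
Multidimensional mediators enter as K columns and the R² formulas operate on
the whole coefficient vector.

R²_b (explained relative risk) uses mean-centered predictors and the entropy
constant of the standard extreme-value distribution, stored at full precision
as 1 + Euler–Mascheroni = 1.57721…; R²_w = θ'Σ̂θ/(1 + θ'Σ̂θ) uses the
sample covariance (denominator N − 1).  Both are exactly 0 at θ̂ = 0.
R²_med and SOS are reported unclipped with flags for negative R²_med,
out-of-range SOS, and undefined SOS (zero total effect): with small total
effects and moderate N these estimators genuinely leave [0, 1], and hiding
that would misrepresent the uncertainty.  Predictors are centered but not
standardized before R²_b, matching the formula as defined.

## The trial simulator (`landmed.simulate`)

Each subject draws A ~ Bernoulli(0.5), X, Z ~ N(0, 1).  Time-varying
coefficients are spline expansions η_j(t) = Σ_l ξ_jl B_l(t) in the four
cubic B-spline basis functions on [0, 1] (clamped ends, no interior knots —
equivalently the cubic Bernstein basis).  The event hazard is

    h(t | A, Z, D) = h₀(t) exp{β₁A + β₂Z + α R(min(t, 1))},
    R(s) = ∫₀^s D(u) du,  D(u) = η₁(u)A + η₂(u)X,

with Weibull baseline h₀(t) = (k/b)(t/b)^(k−1), shape k = 1.682, scale
b = 1.024.  Event times are drawn by inverse transform: the cumulative hazard
is accumulated by trapezoid quadrature on a grid of step 0.001 over [0, 1];
draws landing inside the grid are inverted there, and draws beyond it use the
closed-form tail T = b·[H₀(1) + (−log U − H̃(1))·e^{−β₁A−β₂Z−αR(1)}]^{1/k},
obtained by solving H(T) = −log U with the exposure frozen at R(1).  With
α = β₁ = β₂ = 0 this reproduces the closed-form Weibull law exactly (verified
by a Kolmogorov–Smirnov test on 20,000 draws), which validates the quadrature.

Censoring is C ~ Unif(0, 10); observed time min(T, C), indicator I(T ≤ C).
Visit schedules place a baseline visit at t = 0 plus m ~ Poisson(5) visits
drawn uniformly without replacement from grid points strictly inside
(0, min(1, T̃)); measurements add N(0, σ² = 0.01) noise to η₀(t) + D(t).
Subjects with fewer than 3 post-baseline visits are dropped, as in the
analysis-set convention for real trials.  The hidden truth (true event time,
true cumulative exposure) is retained for oracle metrics.

Five registered coefficient settings span the qualitatively distinct
treatment–trajectory–survival structures: direct effect only with and
without a treatment effect on the trajectory (a1, a2), indirect effect only
(b: β₁ = 0, α = 10), both (c), and a global null (d).  The population mean
η₀(t) defaults to 3·exp(−0.8t) — a smooth, monotone-decreasing curve on the
scale of a typical LDSUM trajectory; η₀ cancels from the hazard, so the
survival-side truth is unaffected by this choice, and it is configurable.

Seeding: a master seed spawns per-subject substreams (numpy `SeedSequence`),
so identical seeds give bit-identical datasets and per-replicate seeds in
study runs are independent.

**What the generator does not emulate.** Visit schedules are independent of
tumor burden given survival (no informative dropout); censoring is purely
administrative/uniform; there is a single X and a single Z; trajectories may
go negative since D is Gaussian (real LDSUM is non-negative); and the
longitudinal follow-up window is [0, 1] while survival may extend far beyond
it.  Passing tests therefore demonstrate correctness of the estimation
machinery under sparse, irregular, survival-truncated sampling — not
robustness to informative observation processes, which real trial data may
exhibit.

**Study sizes.** End-to-end checks use N = 1000 subjects per replicate and 20
replicates where a mean is reported, which keeps the Monte Carlo error of
mean coefficients near 0.015 and of mean SOS near 0.05; unit tests use a few
hundred subjects.  Per-setting censoring proportions are reported as means
over 5 replicates so their Monte Carlo error stays below one percentage
point.

## Known limitations

* The AUC estimator ignores within-window censoring (documented bias); no
  IPCW variants are provided.
* R² mediation measures require large samples; with weak total effects the
  SOS estimate is noisy and frequently outside [0, 1] (flagged).
* No causal identification is claimed: the decomposition is predictive
  explained-variation, not a counterfactual mediation effect, and no
  unmeasured-confounding assumptions are imposed.
* The varying-coefficient regression reports pointwise OLS standard errors
  on PACE reconstructions over the full grid (observed plus predicted
  domain; an observed-domain restriction is available) without accounting
  for the estimation error in the reconstructions themselves.
* Under the default settings the indirect-effect hazards are heavy-tailed
  (exposure terms of order e^{±5X}), so per-setting censoring proportions
  carry meaningful replicate-to-replicate variability; setting c averages
  slightly above 40%.
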