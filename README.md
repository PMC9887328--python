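# landmed

Landmark mediation survival analysis with longitudinal tumor-burden surrogates.

In solid-tumor trials, tumor burden (the RECIST sum of longest diameters,
LDSUM) is measured repeatedly over follow-up but is usually collapsed into a
single binary "objective response" before it ever enters a survival model.
`landmed` keeps the whole trajectory in play.  It answers two questions for
biostatisticians analyzing two-arm oncology trials:

1. **How well do tumor-burden summaries predict survival, and how does that
   change over follow-up?**  Landmark Cox models are refitted at a grid of
   times L_p using only patients still at risk and only data observed before
   L_p, yielding time-varying coefficients and dynamic survival predictions.
2. **How much of the treatment's survival benefit is carried by the
   trajectory?**  R²-based mediation effect sizes decompose the explained
   variation in survival into direct and trajectory-mediated parts.

## The model

Longitudinal tumor burden follows a varying-coefficient model

    Y_i(t) = η₀(t) + η₁(t)·A_i + η₂(t)·X_i + ε_i(t) = η₀(t) + D_i(t) + ε_i(t),

with treatment A, baseline covariates X, and the subject-level deviation
D_i(t) expanded in a Karhunen–Loève basis D_i(t) = Σ_k γ_ik ρ_k(t).  Because
visits are sparse, noisy and irregular, the scores γ_ik are estimated by
conditional expectation (the PACE approach): mean and covariance are obtained
by local-linear smoothing of pooled observations, and each subject's scores
are best linear predictions given their own visits.

Survival follows a proportional-hazards model with a tumor-burden summary R:

    h(t | A, Z, R) = h₀(t) · exp{β₁A + β₂Z + αR},

where R is one of: the binary objective response (ever ≥30% shrinkage or
disappearance before the landmark), the first K FPC scores, or the integrated
smoothed trajectory ÎD_i = ∫₀^min(τᵢ,L_p) D̂_i(s) ds.  At each landmark the model
is refitted on the risk set {T̃_i > L_p} with residual time T̃_i − L_p and a
Breslow/Efron baseline, giving dynamic predictions
Ŝ(L_p + t | L_p) = Ŝ₀(t)^exp(linear predictor).

Mediation is quantified by fitting the direct (A), mediated (R) and full
(A, R) models and combining their explained-variation measures:

    R²_med = R²_{T,D} + R²_{T,M} − R²_{T,F},    SOS = R²_med / R²_{T,D},

with either Heller's explained relative risk R²_b (using the Gumbel entropy
constant 1.5772 ≈ 1 + γ) or the Weibull approximation
R²_w = θ'Σθ / (1 + θ'Σθ).  SOS near 1 means the trajectory carries
essentially all of the treatment effect; estimates can fall outside [0, 1]
in finite samples and are flagged, never clipped.

A joint longitudinal–survival simulator generates trials under five
registered coefficient settings (direct-only, indirect-only, both, null)
with the hazard driven by the cumulative trajectory exposure
α∫₀^min(t,1) D(s) ds, and retains the hidden truth for oracle metrics
(true-probability Brier scores).

## Worked example

```python
import landmed as lm

# simulate a two-arm trial where the treatment effect on survival is fully
# mediated by the tumor-burden trajectory (setting "b")
sim = lm.simulate_trial("b", lm.SimConfig(n_subjects=1000), seed=7)
ds = sim.dataset
print(f"subjects retained: {len(ds)}  censoring: {1 - ds.events().mean():.1%}")

es = lm.fit_pace(ds)                      # sparse FPCA on all trajectories
K = lm.select_K(es, fve_threshold=0.90)
print(f"K = {K} components explain {es.fve[K-1]:.1%} of trajectory variance")

summaries, _ = lm.build_summaries(ds, es, variant="integrated", K=K)
res = lm.mediation_decomposition(
    ds.observed_times(), ds.events(), ds.treatments(), summaries, measure="Rw"
)
print(f"R2_direct = {res.r2_direct:.4f}  R2_mediator = {res.r2_mediated_model:.4f}  "
      f"R2_full = {res.r2_full:.4f}")
print(f"R2_med = {res.r2_med:.4f}  SOS = {res.sos:.3f}")
```

Output:

```
subjects retained: 874  censoring: 38.1%
K = 2 components explain 94.1% of trajectory variance
R2_direct = 0.0222  R2_mediator = 0.5161  R2_full = 0.5159
R2_med = 0.0224  SOS = 1.010
```

Read: the treatment-only model explains about 2% of survival variation; the
full model gains essentially nothing over the mediator-only model, so
R²_med ≈ R²_direct and SOS ≈ 1 — the integrated trajectory carries the whole
treatment effect, which is exactly how this scenario was generated.

A command-line interface wraps the same pipeline:

```bash
landmed simulate --setting b --n 1000 --seed 7 --out-dir trial/
landmed analyze  --longitudinal trial/longitudinal.csv --survival trial/survival.csv \
                 --z-cols z --variants none,binary,fpc,integrated --landmarks 0.2:2:0.2 \
                 --out-dir results/
landmed simstudy --settings a1,a2,b,c,d --reps 20 --out-dir study/
```

`analyze` writes coefficient trajectories, landmark C-index tables and the
mediation decomposition as CSV, plus a provenance JSON that reproduces the
run exactly.

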