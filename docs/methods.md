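# Methods

## Model

The unit of analysis is the well median: the median body length (µm) of all
retained animals in one well, roughly 48 h of recovery after a cold exposure
applied at the L1 stage. Well medians are modelled as

    y = Xβ + Z_s a + Z_g g + e,
    a ~ N(0, σ²_s I),   g ~ N(0, σ²_g I),   e ~ N(0, σ²_e I),

where the fixed part X carries an intercept, the treatment contrast
(cold vs control) and the plate-design contrasts (reference-level indicator
coding; "control" and the first design in sorted order are the references),
`a` indexes strains and `g` indexes strain × treatment combinations. σ²_s is
genetic variance in length expressed in both environments; σ²_g is genetic
variance in the *response* to cold (G×E, i.e. plasticity); σ²_e absorbs
well-to-well noise. Broad-sense heritabilities are the two variance shares
over the common denominator σ²_s + σ²_g + σ²_e.

Assumptions worth stating: random effects and residuals are Gaussian and
homoscedastic on the well-median scale; treatments and designs shift means
only (the Brown–Forsythe test checks the first of these for treatment);
wells are exchangeable within a strain × treatment × design cell. The model
is fit separately per cold-exposure duration; duration is not a factor.

## REML fitting

The residual variance is profiled out, leaving the variance *ratios*
γ_k = σ²_k/σ²_e as free parameters on [0, ∞). All likelihood evaluations are
reduced to q×q and p×p linear algebra on the precomputed cross-products
Z'Z, Z'[X y], [X y]'[X y] (q = total random-effect levels, p = fixed
coefficients), so a fit costs O(n) once plus O(q³) per objective
evaluation. The criterion

    −2ℓ_R(γ) = (n−p)(log 2πσ̂² + 1) + log|I + ΛZ'ZΛ| + log|X'W⁻¹X|,
    σ̂² = y'P_W y/(n−p),   W = I + ZΓZ',

is minimised by bound-constrained L-BFGS-B with analytic gradients
(envelope theorem over the profiled σ̂²), from the fixed start grid
γ ∈ {0.2, 1, 5} per free ratio. Every subset of ratios pinned at zero is
profiled separately and the best restricted likelihood wins, which handles
the nonnegativity boundary exactly and keeps the fit deterministic — no
random restarts. Convergence uses L-BFGS-B ftol 1e-13 / gtol 1e-8; on
balanced one-way designs the fit reproduces the closed-form ANOVA
estimators to ~1e-8 relative. The response is mean-centred internally for
conditioning (REML is shift invariant; the offset is restored on the
intercept). The restricted log-likelihood matches lme4's REML `logLik`
definition, verified against lmerTest on a frozen fixture.

Degenerate inputs: an all-constant response drives all components to the
boundary (variances 0); a rank-deficient fixed design raises immediately;
non-finite responses are rejected.

## Random-term tests

Each random term is tested by refitting the model with exactly that term
removed (full REML, not a score approximation) and forming
χ² = 2(ℓ_full − ℓ_reduced), clamped at zero. Because the null σ² = 0 lies
on the boundary, the LRT null distribution is the 50:50 mixture
½χ²₀ + ½χ²₁; the reported p-value is half the χ²₁ upper tail. Under a true
null this halved p rejects at close to nominal level (checked by
simulation: 1000 null replicates at the 7-strain assay size give a
rejection rate within [0.02, 0.08] at α = 0.05).

## Fixed-term tests

Type-III F statistics use the reference-coded coefficient block of each
factor: F = (Lβ̂)'(LĈL')⁻¹(Lβ̂)/rank(L) with Ĉ = σ̂²(X'W⁻¹X)⁻¹. Denominator
df follow Satterthwaite: for a 1-df contrast ℓ,
ν = 2(ℓ'Ĉℓ)²/Var(ℓ'Ĉℓ), where the variance is the delta-method quadratic
form of ∂(ℓ'C(θ)ℓ)/∂θ against the asymptotic covariance of the variance
components θ = (σ²_s, σ²_g, σ²_e). Both the gradient and the observed
information use central finite differences on the variance scale with step
max(1e-6, 1e-4·θ_i); the information is pseudo-inverted so boundary fits
degrade gracefully. Multi-df factors are eigen-decomposed into independent
1-df contrasts whose ν_i are pooled (2E/(E−q) with E = Σ ν_i/(ν_i−2)).
Sanity anchors: with no random terms the recipe collapses to the exact
residual df (n−p); with an interior two-random-term fit the treatment test
lands on its interaction error stratum, ddf ≈ (n_strains−1); both are
enforced in tests, alongside agreement with lmerTest's DenDF to ≲1% on the
frozen fixture.

## Quality control

Order is fixed and tested: object filters (MDHD class, length < 165 µm —
the boundary value is kept) → per-well medians and count filter (retain
5 ≤ n ≤ 60 inclusive, reading "fewer than five or more than 60" literally)
→ outlier wells. Outlier fences are Q1 − 1.5·IQR and Q3 + 1.5·IQR with
linear-interpolation quartiles (the default of mainstream statistical
environments; configurable since other conventions move the fences), open
at the fence (a median exactly on a fence is retained, reading "fell
outside" strictly). Groups are strain × treatment × plate design; groups
with fewer than 4 eligible wells skip outlier detection because quartiles
of so few points are unstable — with the assay's 12 wells per group this
never triggers in practice. Count-failed wells are excluded before fences
are computed. Removals are tallied at every stage per strain × treatment,
so retained-count tables can be reproduced under either tallying
convention. The "replicate plate" grouping key is identified with plate
design: one plate per design per treatment, 12 wells × 3 designs = 36 wells
per strain and treatment.

## Cold-tolerance delta and reaction norms

delta = mean(control well medians of the same strain and design) − (cold
well median), one value per surviving cold well; cold wells whose strain ×
design lost all control wells are dropped with a warning. Strain-level
mean differences pool all surviving cold wells by default; averaging within
designs first is available and identical under balance. Reaction-norm
means are arithmetic means of well medians per strain × treatment; the
slope (cold − control) is the strain's plasticity. The delta is
descriptive: the mixed model's response is the well median itself, as the
model formula states.

## Variance-equality and normality screens

The pipeline-level test pools *all* surviving well medians into two groups
(control vs cold) across strains and designs — hence df = (1, N_wells − 2)
— and applies the Brown–Forsythe statistic: one-way ANOVA on
z = |x − group median|, computed from sums of squares in-package and
cross-checked in tests against `scipy.stats.levene(center="median")` to
1e-12. Equal mean deviations across groups give F = 0 exactly; only
all-constant groups are undefined. Median centring is used because control
lengths are typically left-skewed (a minority of slow developers), which
the Shapiro–Wilk screen (delegated to scipy) makes visible; the screen is
applied to well medians, the same values the variance test consumes.

## Synthetic assay generator

`simulate_well_medians` draws directly from the model above;
`simulate_object_table` layers per-animal lengths Normal(well mean,
sd_object²), truncated positive by resampling, and injects artifacts:
debris objects uniform on [40, 164] µm, MDHD objects on [30, 120] µm (both
Poisson-thinned per well at rate × mean count), and count anomalies that
force a well's animal count below 5 or above 60 with equal probability.
Ordinary counts are Poisson around the target, resampled into the usable
5–60 range so the anomaly rate is the *only* source of count-failure
wells. One SeedSequence per dataset is spawned into a well-layer stream
and an object-layer stream, in that order, so the well table is identical
whether or not objects are generated.

Defaults (chosen once): 7 strains, 12 wells/strain/plate, 3 designs, 50
animals/well; grand mean 750 µm and treatment effect −130 µm, matching the
scale of a 48-h recovery assay in which cold-treated animals lag by roughly
one larval stage; design effects (−12, 2, 10) µm, a small edge-effect-sized
wobble; variance shares 0.20 : 0.45 : 0.35 of a total well-median variance
of 3600 µm² (sd ≈ 26.8, 40.2, 35.5 µm), an illustrative strong-G×E regime;
sd_object 50 µm for within-well developmental spread; artifact rates
(debris 0.02, MDHD 0.01, count anomalies 0.03) small enough to leave the
design effectively balanced. What the generator does *not* emulate:
strain-dependent hatching success (real assays show per-strain animal
counts varying several-fold), skewed or heavy-tailed well noise,
spatial/edge structure within plates beyond the design main effect, and
any length–count dependence. Passing tests therefore demonstrate
correctness of the statistical machinery under the model's own
assumptions, not robustness to those real-data features.

## Problem sizes used in validation

Oracle equivalence: 50 random balanced one-way designs (3–10 groups × 2–10
replicates). Heritability recovery: 200 replicates of 50 strains × 10
wells × 2 treatments × 3 designs with true H² = 0.25 for both ratios; the
mean estimates recover the truth within ±0.03 (the individual estimates
scatter with SD ≈ 0.06–0.07, dominated by the finite strain sample). LRT
calibration: 1000 null replicates at the 7-strain assay size.
Brown–Forsythe calibration: 2000 replicates of two equal-variance normal
groups of 30.

## Known limitations

- Satterthwaite df rely on finite-difference information; at boundary fits
  (a variance estimated exactly 0) the reported df switch to the stratum of
  the surviving terms, as lmerTest's do, which can look abrupt across
  near-boundary datasets.
- Heritability point estimates are ratio statistics and inherit small-sample
  bias from the strain sample size; no standard errors or intervals are
  reported.
- The LRT refits remove exactly the named term; correlated random slopes,
  kinship matrices and narrow-sense heritability are out of scope.
- The QC stage consumes object class labels as given; it does not
  re-classify objects.
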