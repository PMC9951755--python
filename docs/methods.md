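# Methods

This note documents the statistical machinery in `munmeta`: the models, the
estimation choices, the synthetic-data generator, and the places where the
design was genuinely open.

## Unit of analysis and data model

The unit of analysis is the *treatment mean*: one experimental group's mean
UN (g/d) with its standard error (SEm), alongside MUN (mg/dL), BW (kg), DMI
(kg/d), CP and NDF (% of DM), and a diet stratum (TMR or fresh
forage/pasture). Studies are identified by DOI strings and belong to exactly
one stratum. Conversion constants are stored exactly as conventionally
printed — milk urea mmol/L ÷ **0.357** → MUN mg/dL, milk urea mg/dL ×
**0.467** → MUN mg/dL, CP = N × **6.25** — and the near-identity
1/(6.006 × 0.467) ≈ 0.357 (urea molar mass 60.06 g/mol, 46.7% N) is treated
as documentation, not a substitute: the printed divisor is authoritative
because downstream coefficients were produced with it.

Missing optional covariates are `None`/NaN, never 0; any operation that needs
them raises. The canonical sort is (diet, study id, original row order), so
every fit is invariant to input permutation. The train/test split removes
whole studies per stratum (never individual records), is driven by a single
integer seed through `numpy.random.default_rng`, and sorts study ids before
sampling so the partition does not depend on row order.

## Weighted random-intercept REML

All regressions share one model:

    y = Xβ + Z u + ε,  u ~ N(0, σ²_s I),  Var(ε_i) = σ² / w_i,

with one random intercept per study and weights
`w_i = (1/SEm_i²) / mean(1/SEm²)`. Normalizing to mean 1 keeps σ²_s and σ²
on the squared response scale (g²/d²). Equal weights are the fallback when
*no* record has an SEm; a mixture of present and absent SEm is an error
(silent partial weighting would distort the fit).

Estimation is REML profiled over the variance ratio λ = σ²_s/σ². For fixed
λ the marginal covariance V₀ = diag(1/w) + λZZ' is block diagonal per study,
and each block is a diagonal plus a rank-one matrix, so V₀⁻¹x and log|V₀|
have closed Sherman–Morrison forms and one objective evaluation costs O(n).
The scalar objective

    log|V₀| + log|X'V₀⁻¹X| + (n − p)·log(r'V₀⁻¹r)

is minimized by bounded search on λ ∈ [0, 10⁶] (absolute tolerance 1e-10),
with the λ = 0 boundary checked explicitly; GLS then gives β and
σ̂² = r'V₀⁻¹r/(n − p). The engine is deterministic, fails loudly on rank
deficiency (naming the aliased columns — nothing is dropped silently), and
with one record per study reports σ²_s = 0 with a warning since the
intercept variance is then confounded with the residual. The implementation
is cross-checked in the test suite against closed-form weighted least
squares at λ = 0, against statsmodels `MixedLM` (unweighted REML), and
against R `lme4::lmer` with `weights=` on identical data — the latter two
are independent oracles, not dependencies of the fit.

**Degrees of freedom.** Wald t tests use a between-within convention,
df = n_obs − rank(X) − n_studies + 1 (n_obs − rank(X) when the random
intercept is unidentifiable). The literature this workflow serves rarely
states its df method; a Satterthwaite approximation would differ in small
samples, so downstream consumers should read p-values near a threshold as
*significance classes* rather than exact probabilities. A simulation in the
test suite confirms the type-I error rate for a null covariate is close to
nominal (≈5%) at realistic sizes.

## Bias decomposition

For an equation under audit, residuals are observed − predicted (negative
mean residual = over-prediction; report prose translates). Predictions are
centered at their grand mean over the *pooled* evaluation set — not per
diet — and residuals are regressed on diet + centered prediction + their
interaction with study intercepts and SEm weights. Pooled centering is a
deliberate choice: the interaction p-values (does the bias differ between
diet systems?) depend on where the predictions are centered, and per-diet
centering would absorb exactly the diet contrast being tested. After
centering, the intercept estimates the mean bias and the slope the linear
bias. Two parameterizations of the same model are fitted: reference coding
for interaction tests, cell means for the per-diet estimates and their SEs.

RMSEP = √(mean squared residual) and RPE = 100·RMSEP/mean(observed) are
computed per diet on the raw residuals, outside the weighted regression —
they describe raw predictive error, not the weighted fit. The identity
RMSEP² = (mean residual)² + Var(residual) (population form) is enforced in
tests. No multiple-testing correction is applied across the
residual-vs-covariate grid; the rows are diagnostics, not a decision
procedure.

## Model development

Candidate families: M4 (UN/BW ~ MUN), M5 (UN ~ MUN + CP + DMI), M6
(UN ~ MUN + CP + DMI + BW), M7 (UN/BW ~ MUN + CP + DMI), each starting with
the diet factor and all covariate×diet interactions. Backward elimination
removes, per refit, the removable term with the largest Wald p above the
threshold (default α = 0.05, configurable; ties broken lexicographically so
the path is fully deterministic). Hierarchy is enforced: a main effect is
not removable while its interaction survives, nor the diet factor while any
diet interaction survives; the intercept is an ordinary removable term (the
per-BW MUN-only family genuinely favors a zero intercept). A `block` mode
that removes all non-significant removable terms per sweep is provided
because sequential-vs-joint removal of interactions is a genuinely open
choice; sequential is the default. Final models with surviving diet terms
are refitted in cell-means form so each diet's coefficient carries its own
SE, and per-BW responses are multiplied through by BW when the equation is
finalized, so every emitted equation predicts UN in g/d.

## Agreement statistics

Lin's concordance is computed as CCC = r·C_b with u = (m_p − m_o)/√(s_p s_o),
v = s_p/s_o, C_b = 2/(v + 1/v + u²), using population (n-denominator)
moments, which makes the covariance form
2·cov/(var_o + var_p + (m_o − m_p)²) algebraically identical — the test
suite holds the two to 1e-10. Descriptive summaries (mean, SD, CV%, range)
use the sample SD (n−1), the convention of published summary tables; both
conventions are exposed via `ddof` because neither is universal. At least
3 pairs and non-constant vectors are required. RMSEP on the test set is
unweighted: evaluation measures raw prediction error.

## Synthetic-data generator

The generator emulates a two-stratum literature data frame. Defaults are the
training-split study conditions: 38 TMR + 7 pasture studies, 2–5 treatment
means each (~153 means), stratum covariate profiles
(TMR: MUN 13.2 ± 3.17 mg/dL, BW 647.5 ± 64.74 kg, DMI 22.1 ± 2.65 kg/d,
CP 16.7 ± 1.85%; pasture: MUN 18.5 ± 2.46, BW 508.6 ± 63.60,
DMI 17.0 ± 3.25, CP 19.5 ± 3.40), and a default truth equation
UN/BW = −0.253 + 0.00932·MUN + 0.0260·CP with var_study = 24² and
var_resid = 11² g²/d² — variance components consistent with the reported
per-BW residual SD (~0.019 × ~600 kg) and an ~83/17 study/residual split.

Covariates are drawn two-level: a study mean (70% of the variance) plus
within-study deviations (30%), sharing a correlation structure of
BW↔DMI +0.6 and MUN↔CP +0.5 (all others 0). The 70:30 split and the
correlations are fixture conventions — plausible for treatment means that
share animals and base diets — not literature estimates. Draws are clipped
to physiological bounds (MUN > 2 mg/dL, CP ∈ (8, 30)%, BW ∈ (300, 900) kg,
DMI ∈ (5, 35) kg/d); at the default profiles clipping is a far-tail event.
SEm is gamma(16, 0.625) g/d (mean 10, CV 25%), which gives the normalized
weights a CV near 50% so the weighting is exercised nontrivially. The
response adds the study intercept and a heteroscedastic residual
ε_i ~ N(0, var_resid/w_i) tied to the drawn SEm — exactly the error law the
weighted fit assumes, so parameter-recovery tests are a clean closed loop.
A floor of 1 g/d guards the positivity invariant; it never binds at
defaults.

What the generator does **not** emulate: real selection effects in which
studies get published, non-Gaussian covariate shapes, correlation between a
study's SEm and its covariates, breed or days-in-milk structure, and any
nonlinearity beyond the generating equation. Passing recovery tests
therefore demonstrate that the estimation machinery is correct under the
stated model, not that the model is true of any particular literature.

## Numerical and scale choices

Simulation-backed tests run at the study's own conditions (45 studies,
~150 means) with 100–500 replicates depending on the statistic; the
moment-convergence check uses ~5000 records per stratum, where the
between-study clustering leaves the SD estimator an effective n of the
study count — hence a 4% band on SDs against 3% on means. All stochastic
tests and the acceptance script derive every stream from explicit integer
seeds.

## Known limitations

- Single random intercept only: no crossed/nested effects, random slopes,
  or ML mode — the workflow's model space does not need them.
- Wald/between-within inference, as discussed above.
- Coefficient SEs of published equations are stored for reporting; no
  uncertainty propagation into predictions.
- Affine equations can extrapolate below zero for extreme covariates;
  predictions are returned unclipped with a warning, since truncation is a
  caller's policy decision.
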