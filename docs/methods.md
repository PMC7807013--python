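# Methods

## The analysis problem

In a partially migratory population, residents and long-distance migrants
share colonies in the breeding season but winter ~3000 km apart. If
migration is costly, the cost should surface after return — in body
condition, laying date, clutch size or fledging success — and possibly
differ between breeding areas of different productivity. The package
implements that analysis as a pipeline with a synthetic-data harness so
every stage can be validated against known truth.

## Strategy classification

Each bird-year is classified from up to three streams, reconciled
conservatively:

* **Winter resightings.** The winter window for breeding year Y is
  01 Nov (Y−1) – 15 Jan (Y), *inclusive on both ends* (the source rules
  say "between" without specifying; inclusivity matches the two-week
  buffer intent of the window). In-area records give resident evidence;
  records at any other location (e.g. a Sahelian roost) give migrant
  evidence.
* **Geolocator fixes.** Resident iff no window fix is south of 36° N —
  but only when the window has at least one fix; absence of data is
  `unknown("no winter coverage")`, never residency. Migrant iff ≥ 2
  window fixes are south of 23° N; any two window fixes qualify (whether
  they must come from distinct days is unspecified upstream). Fixes only
  at 23–36° N give `unknown`.
* **Feather δ¹³C.** Migrant iff strictly above the −20 ‰ cutoff. The
  stream never emits resident: a low (Iberian) value can be a migrant
  that moulted P9/P10 before departure. A feather collected in breeding
  year Y is assigned to the winter preceding season Y.

**Reconciliation.** Agreement among determinate verdicts gives that
strategy; no determinate verdict gives `unknown`; resident-vs-migrant
contradiction gives `unknown` with a conflict flag and all evidence
retained. A majority vote would silently resolve disagreements that the
analysis should surface, so conflicts are data, not errors. First-year
birds are classified but excluded from fitness analyses.

The sensitivity analysis repeats *everything* (classification through
final models) at cutoffs −20.5, −20.0 and −19.5 ‰ and reports whether
the selected models agree.

## Phenology

First-egg date provenance, in order: directly observed; back-calculated
as exactly 32 calendar days before an observed first hatch (fixed
incubation span — its variation is out of scope); estimated from a
chick's wing chord. The wing-growth model is a linear mixed model (wing ~
age, nest random intercept, REML) fitted on known-age chicks aged 14–30
days only — growth is non-linear beyond day 30, and out-of-window rows
are excluded with a logged count. Marginal R² is var(fixed predictions) /
(var(fixed) + nest variance + residual variance). Age inversion uses
fixed effects only (a new chick's nest effect is unknown) and rounds to
whole days before date arithmetic, since dates are day-resolution;
predicted ages outside 14–30 days are flagged extrapolated. The
wing-growth calibration may use years that the fitness analyses exclude —
the exclusion filter applies to inference, not calibration.

Nest success requires at least one chick older than 20 days (strict);
those chicks are the fledgling count. Brood condition is the sibling mean
of chick mass/P8.

## Condition index

Raw condition mass/P8 separates dynamic reserves from structural size.
The index is built by z-scoring raw condition and fitting

z-condition = f(day-of-year) + sex offset + bird intercept + ε

with f a **cyclic** penalized regression spline (no artificial Jan-01
discontinuity; the cyclic domain is anchored at day 0.5–365.5 so the
wrap-around period is one full year — anchoring at the observed data
range would shorten the period by a day or two and visibly distort the
January fit). Whether sex should enter as an offset or as separate
smooths is genuinely open; the default is one shared smooth plus a sex
offset, switchable (`sex_smooths=True`).

The smoother is the mixed-model representation of a penalized spline:
the penalty matrix is eigen-decomposed, its null space (constants) is
absorbed by the intercept, and the scaled positive eigenspace becomes an
i.i.d. random-effect block, so REML estimates the smoothing parameter
jointly with the bird-intercept and residual variances. This is
implemented directly (profiled REML over the variance ratios, Woodbury
identities, Nelder–Mead over 2–3 log-ratios) because no installed Python
package offers a GAMM with both penalized smooths and crossed random
intercepts; the construction is the standard one used by mixed-model GAMM
software. Fixed-effect SEs come from the GLS information matrix; variance
-component SEs from the numerical REML Hessian by the delta method.
Effective df is the trace of the smoother matrix for the fixed+smooth
part (random intercepts excluded).

The **relative-condition index** is the residual from the
population-level prediction (smooth + sex), centred; "fitted" is defined
as observed − residual so the two always reconstruct the data. The index
deliberately retains the bird intercept — downstream GLMMs model it again
as a random effect. Because the response is z-scored, adding a constant
to all condition values leaves the index exactly unchanged. (A constant
added to *mass* changes condition by c/P8 per row, which no smoother can
absorb exactly; the invariance holds on the condition scale.)

The **pre-incubation subset** keeps captures strictly before 02 May of
their year — the peak of mean female condition, after which condition
reflects breeding effort more than the preceding winter. The cutoff is a
fixed configured date, not re-estimated per dataset, so the subset
definition is reproducible. (The source material prints both "May 01" as
a figure annotation and "02 May" in the analysis text; strictly-before-02
-May, i.e. through 01 May, satisfies both readings.)

The same machinery fits seasonal NDVI per study area (per-area smooths,
area offsets, pixel random intercepts) and exposes per-area peak dates.
The between-area shape test is an ML likelihood-ratio statistic against a
shared-smooth null, referred to χ² with the difference in effective df —
an approximation (penalized fits have no exact LRT reference); simulation
checks show it is roughly calibrated at the problem sizes used, and
p-values should be read as indicative.

## Conway–Maxwell–Poisson regression

Clutch sizes are underdispersed; the CMP family handles this with
dispersion ν (ν=1 Poisson, ν>1 underdispersed). log Z(λ,ν) is a
truncated series accumulated in log space; the truncation extends until a
term contributes < 10⁻¹² relative to the running sum, with a cap that
adapts to the series mode ≈ λ^(1/ν) (a fixed cap of ~1000 terms would
break normalization for overdispersed corners like ν=0.3, λ=20, whose
mode sits near 21 500). The regression links log λ = Xβ with one shared
ν, maximized by BFGS with analytic gradients (score in β is X'(y−E[Y]);
in log ν it involves E[log Y!], both computed in the same series pass);
SEs come from the numerical Hessian. ν̂ is reported with a delta-method
SE; fits reduce to Poisson GLM estimates when ν is fixed at 1 (verified
to 10⁻¹² in tests). Near-degenerate counts push ν̂ to the
underdispersion limit; it is bounded at 50 with a warning.

## Model selection

Parameter counting is uniform across a candidate set: one per
fixed-effect coefficient, plus one per variance component (residual,
random intercept), plus one for ν (CMP), plus one for ĉ (QAICc).
Mixed models are fitted by **ML**, not REML, so criteria are comparable
across fixed structures. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); QAICc
replaces −2ℓ by −2ℓ/ĉ and adds one parameter for ĉ, which is estimated
from the global (most complex) binomial model as Pearson χ²/df, floored
at 1, and applied to all candidates.

All sub-models of the global model are fitted subject to marginality
(interactions keep their main effects). The Δ2 subset is everything
within 2 criterion units of the best; the final model is its
fewest-parameter member, ties broken by the better criterion value. Model
averaging is deliberately not performed (interaction terms make averaged
coefficients incoherent). Non-convergent candidates are dropped with a
log entry.

Post-hoc contrasts on a final model containing the strategy×area
interaction are migrant−resident within each area plus the area contrast,
with single-step adjustment: each contrast's adjusted p is the
tail probability of the maximum absolute standardized contrast under the
joint normal distribution implied by the contrast covariance (max-|z|,
computed from the multivariate normal box probability; the quadrature is
seeded for reproducibility). This is a documented stand-in for the
common single-step implementations; exact published p-values are not
treated as reproducible targets.

## Synthetic cohort generator

Defaults define the study conditions: 100 individuals × 5 years
(2014–2018) = 500 bird-years in two areas ("A-rich", later phenology,
higher condition; "B-poor") at 50:50; P(migrant)=0.45 with a 0.10 annual
switch probability (comparable to the observed switch frequency among
multi-year individuals); isotope means −23.5 ‰ (Iberian) and −16.5 ‰
(Sahelian) with SD 1.2 ‰, chosen to bracket the −20 ‰ cutoff, and a
0.15 pre-moult probability so the migrant-only asymmetry of the isotope
stream matters; winter resighting probability 0.5 (residents),
geolocator 0.08, feather sampling 0.6, capture 0.10 per bird-month
(yielding ≈ 570 captures ≈ the study's 566); first-egg day-of-year
means 118 (A) and 107 (B), SD 10 d; clutches CMP with baseline λ=35,
ν=2.5 and log-λ slope −0.30 per phenology SD (mean clutch ≈ 4,
underdispersed); condition baseline 1.30 g/mm, seasonal amplitude 0.06
peaking 02 May, sex offset 0.05, individual SD 0.04, residual SD 0.06,
area offset 0.05, and a migrant deficit of 0.06 (one residual SD) applied
in the poor area only, strictly before 02 May. The nest fraction (0.55)
and capture effort are free parameters with no stated counterpart.
Migrant winter fixes sit near the Senegal roost (14.5° N ± 1°) with
linear transit; resident winter fixes are clipped north of 36° N.

The generator emulates detection *probabilities* only — no light curves,
rasters, or observation-process detail — and its effects are additive
and Gaussian where real data may not be. Passing recovery tests
demonstrates that the pipeline's estimators are consistent and calibrated
under the assumed structure, not that the field data satisfy it.

## Problem sizes and numerical choices

Recovery and calibration tests run at the study scales: 500 bird-years
for classifier recovery, 566 captures for smoother recovery, n=141
bird-years for the interaction power and null-calibration simulations
(50 replicates each), 100 replicates of n=500 for ν recovery. Module
-level checks with heavier nominal replication (post-hoc null behaviour,
NDVI null calibration) run at reduced replicate counts chosen to keep the
default suite fast while still binding. Random draws are seeded
everywhere; the pipeline is deterministic given config + seed.

Known limitations: the smooth-difference test's χ² reference is
approximate; the post-hoc adjustment uses the normal rather than t
distribution (adequate at the residual df involved); CMP ν̂ carries the
usual O(1/n) ML bias (~2% at n=500); conflict handling never attempts
resolution, so datasets with noisy streams will yield more `unknown`
calls than a voting scheme would.
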