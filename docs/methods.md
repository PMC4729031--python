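# Methods

`tickcomm` analyses longitudinal cattle-tick surveys: repeated monthly
collections of adult ticks from sentinel steers in several herds (sites)
nested in climatic areas. The reference design has 4 areas, 12 sites, 12
sentinel steers per site and 12 monthly collections; seven taxa are
analysed (*Hyalomma spp*, *A. variegatum*, *Rhipicephalus spp* excluding the
*Boophilus* subgenus, and the *Boophilus* species *R. annulatus*,
*R. decoloratus*, *R. microplus*, *R. geigyi*). This note documents the
statistical procedures, their assumptions, the tunable parameters, and what
the synthetic-data generator does and does not emulate.

## Data model

One observation = one (site, month, steer, taxon, attachment-site) cell
with a non-negative adult count. `month_index` is survey-relative (areas
start in different calendar months); `calendar_month` is kept for climate
joins. Attachment site (head, legs, flank, perineum, tail) may be missing;
rows lacking it are excluded only from the attachment analysis. Composition
percentages for named taxa use the identified total (collection total minus
unidentified specimens) as denominator; the unidentified share uses the
grand total. `UNIDENTIFIED` and `BOOPHILUS_UNASSIGNED` never enter
community or GLM analyses.

## Beta-diversity partition

The units × taxa count matrix `Y` (unit = site, or site-month sampling
event) is Hellinger-transformed row-wise, `y'_ij = sqrt(y_ij / y_i.)`, then
column-centred to `s_ij`. With `SS_total = Σ s_ij²`:

    BD     = SS_total / (n − 1)                (total beta diversity, in [0, 1])
    LCBD_i = Σ_j s_ij² / SS_total              (unit contributions, Σ = 1)
    SCBD_j = Σ_i s_ij² / SS_total              (taxon contributions, Σ = 1)

An all-zero unit has no defined composition and is rejected by name;
`aggregate_abundance` flags such units so callers can drop them. When every
unit hosts the same assemblage (`SS_total = 0`), BD is 0 and the
contributions are reported missing, never zero.

**Permutation inference.** LCBD significance permutes each taxon's *raw*
abundances independently across units, then re-transforms and
re-partitions; this breaks unit–taxon association while preserving each
taxon's marginal abundance distribution. Permuting raw counts before the
transform is deliberate (the transform depends on row sums, which the
permutation alters). Whole-column swapping was considered and rejected: it
leaves the LCBD of a two-column matrix nearly invariant and tests nothing.
P-values use the add-one convention `p = (1 + #{LCBD* ≥ LCBD}) / (1 +
nperm)` (default `nperm = 999`), so they are never zero; permuted matrices
that become degenerate (a unit losing all its ticks, or `SS* = 0`) count as
non-exceedances. The test is deterministic given a seed.

**Richness correlation.** Pearson r between per-unit species richness
(taxa with raw count > 0) and LCBD, two-sided p from the t distribution
with n − 2 df. A negative correlation indicates that high-LCBD units are
species-poor sampling events.

**Climate vs geography.** Event-level (site-month) LCBD is regressed by
OLS on (i) rainfall + temperature, (ii) site indicators, (iii) both, and
the three adjusted R² are reported (`R²_adj = 1 − (1 − R²)(n − 1)/(n − m −
1)`, m non-intercept parameters). Because the adjustment penalises
parameters, the joint R²_adj can sit slightly below the larger component —
the nesting inequality holds only up to that penalty. Rank-deficient
designs are rejected with the aliased columns named.

## Seasonal abundance factor (s_x)

Per taxon and site, steer-month counts are modelled as negative binomial
(NB2: variance `μ + μ²/θ`, log link). Months with zero total form the
`absent` level. A taxon present in fewer than 3 distinct months is
**sporadic** and excluded from seasonal modelling — fewer than three
support points cannot identify a seasonal factor.

Month merging proceeds in three calibrated steps at level `alpha` (0.05):

1. **Global pre-test.** Likelihood-ratio test of the full month factor
   (each fit re-estimating θ, chi² on #months − 1 df). Non-significant →
   one level. Without this guard, pairwise agglomeration over-splits
   homogeneous series drastically (the pair that survives merging is
   data-selected, so its "significance" is biased); with it, a homogeneous
   series resolves to one level at rate ≈ 1 − alpha by construction. LR is
   used rather than Wald because the NB Wald test with estimated θ is
   measurably liberal at these sample sizes (empirical size ~0.075 vs
   ~0.045 for LR at nominal 0.05).
2. **Agglomeration.** Fit `count ~ level`, compute all pairwise Wald tests
   between level coefficients, merge the pair with the largest p above a
   Šidák-adjusted threshold over the month-pair family
   (`1 − (1 − alpha)^(1/C(m,2))`), ties broken by the smaller fitted-mean
   difference; refit; repeat. The family adjustment compensates for the
   selection inherent in testing data-driven groupings.
3. **Cleanup.** Each pair of surviving levels is re-tested with an honest
   month-granularity LR homogeneity test on the pooled months (no
   data-driven grouping inside the test); pairs that pass are merged,
   repeatedly.

Measured operating characteristics (NB θ = 1.5, 12 steers × 12 months):
homogeneous series → one level in ~93 % of replicates; means 1 vs 30 → two
levels in ~93 %; means 1/8/40 → three levels in 10/10. Non-convergence at
any step falls back to merging the nearest-mean pair and flags the factor.
Surviving levels are ranked by fitted mean and named `low < medium < high`
(up to three) or `L1..Lk`. Level estimates are reported as mean ± SE of
ticks/steer/month, where the SE reflects month-to-month variation within
the level (SD of the monthly means / √#months), not steer-to-steer
variation; single-month levels have no SE.

## Co-infestation design (Π_all-but-x)

`H, A, R, Rm, Ra, Rd, Rg` are 0/1 steer-month presence indicators
(marginal over attachment sites). For focal taxon x, the design contains
the indicators of every co-occurring taxon except x plus their products up
to `max_order` (default 2). The full 2⁶ − 1 = 63-column design is
available but unidentifiable at 12 steers/site, hence the default.
Constant, duplicated or too-sparse columns (fewer than `min_cells`
observations in either state) are dropped with a log note.

## Abundance models

Maximal model: `count ~ s_x * Π_all-but-x` (NB, log link), rows of the
`absent` season excluded. Fitting mirrors R's `glm.nb`: θ by full maximum
likelihood (NB2), then a GLM with fixed θ supplies coefficient inference,
deviance and per-term Wald chi² tests; AIC counts θ as a parameter. A fit
on all-zero counts is refused (no finite NB fit). When the maximal
interaction model is ill-conditioned the pipeline retries without
season × partner interactions, then season-only, and flags the model —
convergence failure on over-rich designs is an expected outcome at this
sample size, not an error.

**Backward elimination.** Candidates are terms with Wald p > alpha that
respect marginality (a term is never dropped while a retained higher-order
term contains all its factors). Among the (up to 3) least-significant
candidates, each removal is refit and the drop with the lowest AIC is
adopted; elimination stops when every eliminable term is significant. The
cap of 3 AIC evaluations per step is a runtime choice that preserves the
AIC preference among the plausible drops. θ is re-estimated at every
refit, keeping AICs comparable. If elimination empties the model the
intercept-only fit is returned flagged.

## Incidence models

Per area and taxon, steer-month presence is modelled as binomial (logit):
maximal model `SITE * s_x + Π_all-but-x` (the site factor is dropped when a
single site is modelled; the seasonal factor is built from area-pooled
counts), then the same backward elimination. Overdispersion is checked a
posteriori as residual deviance / residual df; above 1.5 the model is
refit as quasibinomial (SEs inflated by √(Pearson χ²/df), no AIC,
elimination then proceeds largest-p-first). The 1.5 threshold sits above
the ungrouped-Bernoulli deviance baseline, which is ≈ 1.3–1.4 for
mid-range rates rather than 1 (the deviance of 0/1 data reflects entropy,
not fit), so a correctly specified model does not trigger the refit.
Minimal models explaining less than 10 % of the null deviance are flagged
`not_considered`. Complete separation falls back to a small-ridge
penalized fit with flagged, SE-less coefficients.

## Dynamics correlations

Monthly site-level totals of pairs of taxa (and taxon vs rainfall or
temperature) are correlated (Pearson, two-sided, ≥ 3 paired months,
zero-variance series → missing). Per-site p-values for a pair are combined
across sites with Stouffer's method, signed by the correlation direction.

## Attachment-site analysis

Counting unit: the individual attached tick of the focal taxon (rows with
recorded attachment site). Rows of the 2 × C table split focal ticks by
whether their host steer-month also carried the partner taxon; columns are
the five body parts (`body5`) or preferred/not-preferred (`preferred2`,
with *Rhipicephalus spp* preferring head + legs, all other taxa flank +
perineum, and the tail counted as not-preferred). Tables with an empty row
or fewer than two non-zero columns are flagged untestable.

**Fisher's exact test.** Two-sided p by the "probability ≤ observed" rule:
the sum of multivariate-hypergeometric probabilities of all tables with the
observed margins no more probable than the observed table (for 2 × 2 this
is the usual hypergeometric two-sided sum). Enumeration is exact while the
margin-compatible table bound stays below 10⁷; beyond that, 10⁵
margin-preserving Monte-Carlo draws (Patefield algorithm, seeded) give
`p = (1 + hits) / (1 + n_mc)`.

**Stouffer combination.** `Z = Σ z_i / √k`. For `preferred2` tables the
default is signed: each two-sided Fisher p enters at p/2 with the sign of
the observed preferred-site enrichment (an unsigned combination of
two-sided p-values cannot represent direction); for `body5` tables, where
no direction exists, the unsigned conversion `z = Φ⁻¹(1 − p)` is used.
Exact 0/1 inputs are clamped into the open interval and flagged.

## Synthetic-survey generator

The generator draws, per steer-month-taxon, a count `NB(mean, θ)` whose
mean follows a seasonal schedule (high/medium/low levels patterned on
observed magnitudes — e.g. the invasive *R. microplus* high level defaults
to 30 ticks/steer/month; Boophilus-subgenus taxa peak in the late rainy
season, the two/three-host taxa at its beginning, with the rainy-season
calendar differing by area). Area taxon pools reproduce the regional
absences (no *Rhipicephalus spp*, *R. annulatus* or *R. microplus* in the
Sahelian area; no *R. decoloratus* in the South-West area); the native
Boophilus species outside North Benin receive a trickle mean (0.01) that
leaves them sporadic. θ defaults to 1.5 — moderate overdispersion typical
of aggregated macroparasite burdens.

Co-infestation uses a two-pass draw: pass 1 draws baseline counts for all
taxa, whose positivity defines baseline presences; pass 2 redraws a
taxon's count only where the multipliers changed its mean
(`mean × Π_j m[j→i]^presence_j`). Taxa without incoming interactions keep
their pass-1 counts, so their *observed* presence is exactly the presence
the multipliers acted through — this makes `m[j→i]` recoverable as a
log-linear coefficient (`log m`) when regressing on observed partner
presence, and avoids the circular joint definition a simultaneous scheme
would need. Counts are spread over body parts multinomially by per-taxon
preference vectors; climate series are seasonal curves with mild
multiplicative noise, scaled to the stated annual totals (1400/1300/1200
mm, and 900 mm for the most arid area). Identical (config, seed) yields
byte-identical CSV output.

**What the generator does not emulate** — and hence what passing tests do
not establish about field data: steer-level susceptibility differences
(frailty) and within-steer temporal autocorrelation (repeated measures);
tick life-cycle dynamics linking months; identification error;
between-site spatial correlation; climate-driven year-to-year variation.
Its purpose is the observation model the estimators assume, so recovery
tests validate the estimators, not the field realism of the design.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level throughout |
| `nperm` | 999 | LCBD permutations |
| `nb_size` (θ) | 1.5 | NB size (inverse dispersion) of the generator |
| sporadic rule | < 3 months | months of presence needed for a seasonal factor |
| `max_order` | 2 | interaction order of Π_all-but-x |
| overdispersion refit | ratio > 1.5 | deviance/df threshold for quasibinomial |
| not-considered | < 10 % | minimal-model explained deviance floor |
| Fisher enumeration bound | 10⁷ | above it, Monte-Carlo with 10⁵ draws |

## Problem sizes used by the test and acceptance suites

Calibration and power experiments run at sizes chosen to make their Monte
Carlo error small relative to the asserted margins: permutation type-I
calibration uses 200 exchangeable 10 × 4 matrices at `nperm = 199`;
co-infestation detection uses 100 simulated single-site surveys (12 steers
× 12 months, multiplier 2); season-level recovery uses 30 replicates of
the 1-vs-30 design; the brute-force partition oracle runs on 1,000 random
5 × 4 matrices; the end-to-end determinism check runs the full pipeline
twice on a one-site-per-area reduction of the reference design with
`nperm = 49`.

## Known limitations

* Plain GLMs treat steer-months as independent, as the reported analyses
  do; repeated measures on the same steers are not modelled (no GEE/mixed
  effects), so standard errors are optimistic when within-steer correlation
  is present.
* The backward-eliminated minimal model inherits the usual post-selection
  caveats; reported p-values are not selection-adjusted.
* No multiple-testing correction is applied across taxon-by-site models
  (matching the reported analysis style); a Benjamini–Hochberg pass can be
  applied downstream on the emitted coefficient tables.
* The attachment analysis tests independence only; it does not model
  attachment-site choice.
* Event-level (site-month) LCBD is used for the climate/geography
  partition; monthly-mean LCBD is not implemented.
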