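# tickcomm

Community structure, seasonality and co-infestation analysis for
longitudinal cattle-tick surveys.

`tickcomm` is built for the kind of field study where adult ticks are
collected monthly from sentinel steers in several herds (sites) nested in
climatic areas, each tick recorded with its taxon and attachment site on
the host body. Its motivating setting is the West African cattle-tick
community — seven analysed taxa (*Hyalomma spp*, *A. variegatum*,
*Rhipicephalus spp*, and the *Boophilus*-subgenus species *R. annulatus*,
*R. decoloratus*, the invasive *R. microplus*, and *R. geigyi*) surveyed
over 12 months at 12 sites in Benin and Burkina Faso — but the pipeline
applies to any survey with that long-format structure. It answers three
questions:

1. **How does the tick assemblage vary in space and time?** Beta diversity
   of the Hellinger-transformed site × taxon matrix, partitioned into local
   (LCBD) and species (SCBD) contributions with permutation inference, a
   richness–LCBD correlation, and an adjusted-R² partition of LCBD onto
   climate (rainfall, temperature) versus sampling geography.
2. **What drives each taxon's burden and incidence?** Negative-binomial
   GLMs of steer-month counts with a data-built seasonal factor s_x
   (months merged into abundance levels) crossed with the co-infestation
   design Π_all-but-x (presence indicators of the other taxa and their
   interactions), simplified by marginality-respecting backward
   elimination under AIC preference; binomial (or quasibinomial, under
   overdispersion) GLMs of incidence rates.
3. **Does co-infestation redistribute ticks on the host body?** 2 × C
   contingency tables (partner present/absent × attachment sites) tested
   with Fisher's exact test per site and combined across sites with
   Stouffer's method.

The core quantities, in the field's notation: with `y'_ij = sqrt(y_ij /
y_i.)` the Hellinger transform and `s_ij` its column-centred residual,

    BD = Σ s_ij² / (n − 1),   LCBD_i = Σ_j s_ij² / Σ s_ij²,   SCBD_j = Σ_i s_ij² / Σ s_ij²

and the abundance model for taxon x is `count ~ s_x * Π_all-but-x` with
`count ~ NB(μ, θ)`, log link.

Because such surveys rarely come with deposited raw data, the package
includes a first-class synthetic-survey generator
(`tickcomm.synthetic_survey`) that emulates the reference design — 4
areas, 12 sites, 12 steers, 12 months, seasonal NB counts, co-infestation
multipliers, multinomial attachment-site placement, per-area climate
curves — with a truth ledger for parameter-recovery testing. See
`docs/methods.md` for the statistical details and the generator's scope.

## Worked example

```python
from tickcomm import (default_config, simulate_survey, summarize_composition,
                      aggregate_abundance, beta_diversity_partition,
                      lcbd_permutation_test)

survey, climate, truth = simulate_survey(default_config(), seed=1)
print(summarize_composition(survey).to_text())

mat = aggregate_abundance(survey, unit="site").drop_all_zero()
res = beta_diversity_partition(mat.frame)
pvals = lcbd_permutation_test(mat.frame, nperm=999, seed=2)
print(f"BD = {res.bd_total:.3f}")
```

prints (abridged):

```
Total adult ticks collected: 20232
           R_MICROPLUS:   12829 ( 63.41 % of identified,  63.41 % of total)
          A_VARIEGATUM:    2828 ( 13.98 % of identified,  13.98 % of total)
          HYALOMMA_SPP:    2131 ( 10.53 % of identified,  10.53 % of total)
     RHIPICEPHALUS_SPP:    1709 (  8.45 % of identified,   8.45 % of total)
    Boophilus subgenus:   13564 ( 67.04 % of total)
BD = 0.289
```

The simulated collection is dominated by the invasive *R. microplus* (63 %
of adults), as in the field setting the generator imitates; BD = 0.289
says that about 29 % of the total community variance lies between sites.
The largest SCBD in this draw is *R. microplus* (0.58) — the most
heterogeneously distributed taxon — and the three Sahelian-area sites carry
the largest LCBD values (≈ 0.16 each), flagging their depauperate
assemblages (no *Rhipicephalus spp*, *R. annulatus* or *R. microplus*).

## Command line

```sh
tickcomm simulate  --seed 1 --out run/           # survey.csv + climate.csv
tickcomm community --survey run/survey.csv --nperm 999 --seed 1 --out run/
tickcomm abundance --survey run/survey.csv --alpha 0.05 --max-order 2 --out run/
tickcomm incidence --survey run/survey.csv --out run/
tickcomm attachment --survey run/survey.csv --out run/
tickcomm all       --seed 1 --out run/           # everything, end to end
```

Outputs are CSV + plain text: a composition summary, a BD/SCBD/LCBD table
with significance stars, an event-level LCBD table, seasonal mean ± SE
estimates per abundance level, minimal-model coefficient tables for the
abundance and incidence GLMs, attachment p-value grids, and a
`manifest.json` recording versions, seeds and the config hash so every
number is traceable to its run. Exit codes: 0 ok, 1 invalid input,
2 runtime/partial failure.

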