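# Methods

## Model

`genoprev` estimates the birth and population prevalence of an autosomal
recessive disease from three inputs: a deduplicated case database (two
allele slots per case), ancestry-stratified population allele frequencies
for the catalogued pathogenic variants, and country demographics (ancestry
mixture, consanguinity rate, population).

1. **Allele tally.** Both slots of every case are counted, so a database of
   *N* cases contributes exactly 2*N* alleles; slots without an identified
   variant are kept under an `UNKNOWN` sentinel and never attributed to a
   variant. For reporting, variants observed fewer than 5 times (strict
   `<`, configurable) are pooled into an `OTHER` bucket; pooling preserves
   the grand total for every threshold.
2. **Group carrier frequency.** Within each ancestry group the pathogenic
   allele frequencies are summed: f_g = Σ_v k_v/n_v. EAS and SAS are pooled
   into a single ASIAN group *by summed counts* (k and n added, frequency
   recomputed), never by averaging frequencies, because census ancestry
   categories rarely separate Asian subgroups and counts are the substrate
   of the exact interval. Finnish data are excluded on input (no pathogenic
   alleles observed; small non-representative sample).
3. **Exact intervals.** The 95% CI on f_g is Clopper–Pearson from beta
   quantiles, computed on pooled counts: numerator Σk, denominator the
   minimum allele number across the summed variants. The source does not
   state a pooling rule for its intervals; the minimum-denominator rule is
   conservative (it never understates the uncertainty) and is validated by
   coverage simulation rather than against unpublished denominators.
4. **Optional coverage adjustment.** When only a fraction of case alleles
   (here 133/228 = 58.3%) have frequency data, dividing f_g by that
   fraction extrapolates to the full spectrum. The switch is **off by
   default**: the packaged group totals are treated as final because the
   per-ancestry headline prevalences equal the *unadjusted* totals squared.
5. **Country mixing and Hardy–Weinberg.** f_country = Σ_g w_g f_g (a convex
   combination), baseline birth prevalence p = f², consanguinity-adjusted
   p_adj = (1−c)p + c(√p/16 + 15p/16), population prevalence
   p_adj·L_disease/L_background, expected cases = prevalence × population
   rounded half-away-from-zero. Interval endpoints are pushed through the
   same maps, which are all monotone increasing on [0,1].
6. **Global aggregation.** Total cases are summed; overall population
   prevalence is total cases over total population; the global birth
   prevalence is the population-weighted mean of p_adj. "1 in N" figures
   are reciprocals rounded to the nearest thousand.

## The consanguinity equation

The adjustment is the standard inbreeding result. For offspring of first
cousins the kinship coefficient is F = 1/16, giving an affected probability
of F·q + (1−F)·q² with q the carrier (allele) frequency; substituting
q = √p and mixing over the consanguineous fraction c yields
(1−c)p + c(√p/16 + 15p/16). A widely circulated printed form of this
equation reuses one symbol for both the mixing fraction and the quantity
under the radical; evaluated literally it is not an inbreeding model. The
literal form is available behind `equation_mode="as_printed"` for
comparison and is documented as not recommended; the default
(`"repaired"`) reproduces the published country-level adjusted values given
plausible first-cousin rates.

## Pedigree Monte-Carlo oracle

`simulate_consanguineous_cohort` validates the closed form by explicit
allele dropping: the two shared grandparents carry four i.i.d. Bernoulli(q)
alleles; each linking parent is a full sibling receiving one random allele
from *each* grandparent; each cousin receives one random allele of the
linking parent plus an independent population allele; the child receives
one random allele from each cousin. The kinship coefficient is emergent —
`first_cousin_autozygosity` measures identity-by-descent directly and
converges to 1/16 independent of q — so the simulation shares no algebra
with the formula it checks. The test grid uses q ∈ {0.005, 0.02, 0.05},
c ∈ {0, 0.1, 0.3, 1} at 2×10⁶ births per cell, comparing at 3 Monte-Carlo
standard errors.

## Synthetic-data generator

`generate_frequency_table` draws k ~ Binomial(n_g, q_vg) per (variant,
group) — the sampling model a sequencing aggregate database implies.
`generate_case_database` draws each case's two alleles independently from
the normalised pathogenic-frequency vector (affected-conditional sampling),
so compound heterozygotes arise naturally, and masks a configurable
fraction of slots to UNKNOWN. What the generator does *not* emulate:
sequencing/QC artefacts, relatedness within the reference panels,
population substructure beyond fixed group frequencies, ascertainment bias
in case reporting, and mutation–selection dynamics. Passing recovery tests
therefore demonstrate the estimator's correctness under its own sampling
assumptions, not robustness to those real-data complications.

Parameter-recovery tests use per-variant frequencies of a few 10⁻⁵ summing
to ~1.2×10⁻⁴ with 10⁴–2×10⁴ chromosomes per group — the rare-variant
regime the method targets, where expected counts are small and the exact
interval's conservatism (verifiable by direct binomial summation) is
pronounced — and check ≥95% coverage over 200 seeded replicates.

## Packaged fixtures and their provenance

- `cases_synthetic.csv` / `variant_catalog_synthetic.csv`: only the
  *marginal* per-variant allele counts of the worked instance are
  published, so the pairing of 228 alleles into 114 cases is a synthetic
  construction (fixed-seed shuffle); 7 named rsIDs (89 alleles) plus 21
  synthetic-id annotated rare variants (44 alleles) and 34 unannotated
  `local:` variants (95 alleles) reproduce the published totals: 62 unique
  variants, 28 annotated, 133/228 alleles covered. (The source reports 62
  unique variants in the main text and 68 in its supplement; the catalog
  records 62 and flags, not reconciles, the discrepancy.)
- `allele_frequencies_synthetic_denominators.tsv`: published frequencies at
  6 decimals with synthetic denominators (n = 10⁶ per cell) so ac/an equals
  the printed value exactly; the true allele numbers are unpublished, which
  is also why the published country-level intervals are not reproducible
  and the CI machinery is validated by simulation instead.
- `country_demographics_synthetic.csv`: ancestry weights are back-derived
  (two-group mixtures solving w·f = √(published baseline)), not census
  data; consanguinity rates invert the published baseline→adjusted pairs
  through the adjustment formula and all land in [0, 0.23], highest in the
  Gulf states. Four Latin American countries publish carrier frequencies
  (0.0016–0.0017) *above* the largest group frequency (0.001404); no convex
  ancestry mixture can reproduce them, so their weights are clamped to the
  AMR group and flagged in the `note` column. This is an internal
  inconsistency of the published table, left visible rather than patched —
  likewise the published AFR prevalence headline (1.30 per million), which
  is inconsistent with the AFR group total (0.000186² ≈ 0.035 per million).
- `country_reference_estimates.csv`: the published per-country columns at
  printed precision, used for cross-checks and for the global aggregation
  (the clamped rows make the fully recomputed global figure 2.7 rather than
  2.8 per million births).

## Numerical choices and defaults

| Parameter | Default | Rationale |
|---|---|---|
| rare-variant threshold | 5 (strict `<`) | reporting convention of the source tally |
| alpha | 0.05 | conventional 95% exact intervals |
| coverage adjustment | off | published headline prevalences equal unadjusted totals squared |
| equation mode | repaired | literal printed form is not an inbreeding model |
| L_disease | 40 y | stated median disease life expectancy |
| L_background | 80 y | back-derived: every published population prevalence is exactly half its adjusted birth prevalence |
| case rounding | half away from zero | matches all reproducible published counts |
| global weighting | population-weighted mean of p_adj | births-weighted data unavailable; reproduces the published aggregate |

Degenerate inputs: an empty case set tallies to zero and makes coverage
undefined (error); a group absent from the frequency table yields a
zero-frequency result flagged `missing` rather than silence; zero coverage,
inverted CI bounds, weight vectors not summing to 1 (±10⁻⁶) and rates
outside [0,1] are rejected with the offending country/row named.

## Limitations

Point estimates only for ancestry weights and consanguinity rates;
no age structure in the population-prevalence conversion (a single
stationary turnover time); ancestry groups are treated as panmictic within
themselves; the consanguinity model covers first cousins or closer with a
single F = 1/16 (more distant inbreeding ignored, so adjustments are
conservative); variant pathogenicity is taken as given by the catalog.
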