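# Methods

## Model and procedure

The package predicts perturbed bioprocesses by comparing each
chemical-genetic interaction profile (per-strain sensitivity/resistance
z-scores under one condition) to a reference panel of genetic interaction
profiles. The core assumption is that a compound inhibiting a gene product
phenocopies that gene's genetic interaction profile over the shared strain
panel. The computation, in order:

1. **Alignment.** Both matrices are restricted to their shared strains, in
   the chemical-genetic file order. All later inner products are over this
   common axis.
2. **Normalization.** Query genetic interaction profiles are L2
   column-normalized; chemical-genetic profiles are not. Gene-target scores
   therefore scale with the chemical profile's overall strength — a weak,
   noisy profile cannot produce strong process scores no matter how well its
   direction matches.
3. **Resampled null.** Each entry of a resampled profile is drawn uniformly
   with replacement from that strain's scores across *treatment* conditions.
   This preserves per-strain marginal distributions (including variance that
   appears only under bioactive treatment and is invisible to solvent
   controls) while destroying cross-strain structure.
4. **Scoring.** Similarities `S = Cᵀ G'`, process scores `X = S B`, computed
   for treatments, solvent controls and resampled profiles alike.
5. **Significance.** Three (z, empirical p) pairs per (condition, term):
   against the control-cohort and resampled-cohort distributions of that
   term's scores (cohort mean, sample sd with n−1; p = fraction of cohort
   scores ≥ observed, so a tie with the most extreme null value still costs
   1/n), and against a within-profile null that permutes the gene labels of
   the condition's similarity row and recomputes term scores. Empirical
   p-values are kept as exact integer counts over a known denominator.
6. **Combination.** Per (condition, term) the *largest* p wins; p ties are
   broken by the smallest z, and exact (p, z) ties by the fixed source order
   control → resampled → within. The combined value is deliberately the most
   conservative of the three readings.
7. **FDR.** For each control cohort (solvent, resampled), the ratio of the
   cohort's discovery fraction to the treatments' discovery fraction is
   evaluated at every observed p-value (per-profile discovery = best
   combined p ≤ threshold), capped at 1, and made monotone nondecreasing in
   p by a reverse cumulative minimum. Division conventions: 0/0 → 0, x/0
   with x > 0 → cap. Both maps are reported; high-confidence discovery
   defaults to the (empirically more conservative) resampled map.

The enrichment baselines replace steps 5–6 with a hypergeometric upper-tail
test on a top-n selection (most-negative chemical-genetic scores over a
strain-universe annotation, or largest gene similarity scores over the
query universe) and feed the same FDR machinery. Tied scores at the n-th
position are all selected and the test is evaluated at the nominal n, as
the defining equations state; a strict-n variant with seeded random
tie-breaking is available behind a flag.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `n_resampled` | 50 000 (pipeline), 5 000 (synthetic studies) | resampled-null cohort size; sets the p-value resolution (1/n) of the resampled source |
| `n_permutations` | 10 000 (pipeline), 2 000 (synthetic studies) | within-profile permutations; unstated in the method's source, chosen for ~1e-4 p resolution at screen scale |
| term size bounds | 4–200 | terms smaller than 4 genes are statistically fragile; larger than 200 are too generic to be a useful mode-of-action call |
| FDR cap | 1.0 | discovery-rate ratios can exceed 1 when controls outpace treatments |
| importance inner-product threshold | 2 | a query profile must reach this similarity with the compound before it joins the term's mean profile |
| contribution cutoffs | \|z\| ≥ 2.5, importance ≥ 0.1 (strong: 5 / 0.5) | interaction calls and one-sided contribution calls for the summary fractions |
| overrepresentation region | z < −5, \|importance\| ≤ 0.1 | strong-but-uninformative interactions; BH-adjusted hypergeometric at 0.05 |

Empirical p-values of exactly 0 are preserved internally (reports should
render them as "< 1/denominator"); the FDR machinery consumes the raw
values together with their integer counts.

## Synthetic study conditions

The generator emulates the structure the method relies on, not any real
screen. Queries in a functional module share a latent per-strain signature
(query = √corr·signature + √(1−corr)·independent deviation), giving exact
within-module profile correlation `corr` and zero between modules. Both the
signature and the deviation follow a sparse-interactor mixture: 5% of
strains sit at a strong negative level, the rest at the small positive level
that balances the mean at 0 and the variance at 1 — mirroring real
interaction profiles, whose strong entries are overwhelmingly negative.
Active compounds are query columns scaled by 5 (yielding z-score-scale
interactions) plus Gaussian noise at 0.5× the signal sd; inactive compounds
and solvent controls are unit-variance Gaussian noise, the natural null for
a z-score matrix.

Default study conditions, chosen to make rank and FDR statistics meaningful
on a single CPU: 100 strains, 60 queries in 10 modules at correlation 0.7;
50 active, 50 inactive, 50 control conditions; 5 000 resampled profiles and
2 000 permutations. Null-calibration studies use an all-null screen (100
inactive treatments, 50 controls) with 2 000 resampled profiles and 1 000
permutations over 5 seeds. The simulated-profile generator (query profile +
Gaussian noise with per-strain variance 2× the strain's variance across the
network, 3 replicates per query) is additionally exercised at the reference
scale of 300 strains × 1505 queries, where it yields 4 515 profiles.

What the fixture does *not* model: plate/batch effects, replicate
conditions sharing a compound identity, dose structure, correlated noise
across strains, and annotation error. Passing tests therefore demonstrate
the statistical machinery's correctness and calibration under the model's
own assumptions, not performance on any real screen.

## Numerical choices and degenerate inputs

- Zero-variance nulls: z = 0 when the numerator is also 0, otherwise a
  ±1e30 sentinel with a flag; the empirical p remains well defined and is
  what downstream code consumes.
- Zero-norm query columns cannot be normalized and are dropped with a
  warning; annotations are restricted to the surviving queries and term
  sizes re-filtered before scoring.
- Prediction lists use one total order everywhere: p ascending, z (or
  enrichment factor) descending, term id ascending. The id key is a
  deterministic tie-break so ranks are reproducible.
- Within-profile permutations are drawn with replacement from the
  permutation group, independently per condition row; each consumer of
  randomness takes its own seeded PCG64 generator in a fixed order, so a
  run is reproducible from its seed.
- The rank-significance shuffle permutes actual (p, z) labels (chunked, no
  analytic shortcut); with all labels tied the rank is fixed by the id
  tie-break and the empirical p is exactly 1.
- AUPR uses average precision (step-function integral), normalized by the
  positives/total random baseline, which makes the convention choice
  immaterial for comparisons.
- NaN cells are rejected at load (the model assumes dense matrices); an
  explicit impute-to-zero escape hatch logs a warning.

## Design choices where the design was open

- Empirical p counting uses ≤ (a score tying a null score counts against
  it), making a control profile scored against its own cohort pay at least
  1/n — the conservative reading.
- The FDR ratio follows the defining recurrence (control fraction over
  treatment fraction); the accompanying prose in the method's description
  inverts the roles, but only the recurrence yields a false discovery rate.
- The per-term p-value universe for the FDR grid is the union of *all*
  combined p-values over all three profile types, not only per-profile
  minima.
- Whether the same permutation must be shared across condition rows in the
  within-profile null is unspecified; rows are permuted independently,
  which is statistically equivalent for per-condition counts.
- Term-size filtering is applied after restriction to the relevant gene
  universe (query genes, or strains for the direct baseline), in both
  cases.
- Rank-significance counts shuffles achieving the observed rank *or
  better* (≤).

## Known limitations

- The combined p-value is a maximum of three correlated rank p-values and
  is therefore *super-uniform* under the null (conservative by design): on
  all-null screens its pooled distribution sits visibly above the uniform
  CDF (KS distance ≈ 0.19 under the default study conditions) even though
  each single-source p is uniform and the FDR maps correctly report ≈ 1.
  Consumers should treat it as a ranking/threshold statistic, not as a
  calibrated tail probability.
- Empirical p resolution is bounded by cohort sizes; with few solvent
  controls the control-source p cannot go below 1/n_controls, which is why
  the resampled cohort is large by default.
- FDR estimates are per-profile (a profile's best prediction), not
  per-(compound, term); the per-term FDR is deliberately out of scope.
- The importance-score layer explains predictions made by this scoring
  scheme; it is not a general feature-attribution method.
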