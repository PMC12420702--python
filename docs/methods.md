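# Methods

## The problem

Genebank collections accumulate phenotype records as a by-product of seed
regeneration: each accession is grown in a single unreplicated plot in a
handful of non-consecutive years scattered over decades. The resulting data
are severely unbalanced (year sets differ per accession), heteroscedastic
(recording standards and conditions drift across years), and contaminated
with gross errors (unit slips, transcription mistakes, mislabeled plots).
Used naively, a small fraction of such errors inflates the residual variance
enough to mask real genetic differences. This package implements a curation
and analysis workflow that (a) removes implausible records, deviant years and
residual outliers with a complete audit trail, (b) estimates variance
components, entry-mean heritability and accession BLUEs from the curated
data, and (c) summarises convariety differentiation, trait interdependence
and winter frost exposure.

## The mixed model

All stages fit variants of the additive model

    y_ijkl = mu + g_i + a_j + t_k + v_l + (g:t)_ik + e_ijkl

with accession `g`, year `a`, experiment `t` (field vs greenhouse),
convariety `v` and the accession x experiment interaction. Role assignments
(fixed / random / excluded) vary by stage:

| stage              | accession | year   | convariety | g:t    |
|--------------------|-----------|--------|------------|--------|
| deviant-year scan  | random    | fixed  | excluded   | —      |
| residual scan      | fixed     | random | excluded   | —      |
| heritability       | random    | random (year x experiment combined) | excluded | random |
| BLUEs              | fixed     | random | excluded   | optional random |
| model reduction    | any term tested by Wald (fixed) or boundary-corrected REML LRT (random) |

The experiment term defaults to fixed (it has very few levels) and enters
only when at least two levels are present. Convariety is excluded from the
curation and BLUE fits so that accession differences are retained; it can be
tested for the variance-component path through `reduce_model`.

### REML implementation

Variance components are estimated by maximising the restricted
log-likelihood, profiled over both the fixed effects and the residual
variance, on log variance ratios `theta_k = log(sigma2_k / sigma2_e)`. With
`M = [X Z]`, `A = M'M`, `b = M'y` and `C(theta) = A + blockdiag(0,
Gamma^-1)`, the criterion is

    (n - p) log(y'Py) + sum_k q_k theta_k + log|C|,    y'Py = y'y - b'C^{-1}b,

evaluated with one Cholesky factorisation of `C` per step — exact for
arbitrary crossed unbalanced designs and fast because `C` is only
(p + q) x (p + q). One component is optimised by bounded scalar search,
several by Nelder–Mead on the clipped box [-30, 30]; ratios that collapse to
the lower bound (below 1e-7) are snapped to exactly zero and the term is
dropped from the final solve, which is the boundary REML solution.
Convergence is declared on the optimiser's own criterion (default relative
tolerance 1e-8); failure sets `converged_ = False` rather than raising.
Fixed-effect estimates, BLUPs, the fixed-effect covariance (used for Wald
tests, BLUE standard errors and year-mean contrasts) and conditional
residuals all come from the same mixed-model equations at the optimum.
Degenerate data that ordinary least squares already fits exactly short-cut
to all-zero components. Fixed designs use drop-first dummy coding; residual
aliasing is resolved by an in-order pivotless Cholesky on the Gram matrix
that drops trailing dependent columns (logged in `dropped_levels_`).

Per-year residual variances, needed by the deviant-year scan, come from a
second pass: per-year means of squared conditional residuals are rescaled by
a common factor so that their pooled value equals the REML residual
variance. This implicitly corrects for fixed-effect rank and BLUP shrinkage
without a full heterogeneous-variance REML, which would be disproportionate
for a screening statistic.

### BLUEs

Accession BLUEs are population-averaged: `BLUE_i = mu + g_i` plus the
record-share-weighted experiment effects, with standard errors from the
corresponding contrast of the fixed-effect covariance. A lone accession
degenerates to its arithmetic mean. On balanced designs without year
variance the BLUE equals the raw accession mean; under year effects and
unbalance it is strictly better correlated with the true genotypic value
(verified by simulation, `blue_superiority_check`).

## Outlier control

1. **Plausibility** (per trait, single pass): remove records outside
   mean ± 3 SD, both computed over all years jointly. The screen is
   deliberately unstratified — per-year screens belong to the later stages —
   and is never iterated.
2. **Phenology consistency** (EmDays, FTS, FTE, Ripe): values flagged within
   their trait x year distribution (same 3-SD rule) are removed only when
   the season is abnormal (≥ 50% of that year's phenology values flagged) or
   when the accession's other phenology traits in that year do not deviate
   in the same direction. A coherently shifted accession-year is biology and
   is kept. A flagged value with no companion phenology observations is
   removed (no corroboration available).
3. **Deviant years**: accessions random, years fixed;
   `CV_j = 100 * sd_e,j / (mu + a_j)`; years whose CV deviates more than
   3 sample SDs from the mean CV (two-sided by default; one-sided via
   config) lose all records. Years with non-positive estimated means have
   undefined CVs: they are excluded from the CV distribution and flagged for
   manual review. A 3-SD rule is structurally blind below ~11 years — the
   deviation of one point from the mean of n points is at most
   (n-1)/sqrt(n) sample SDs — so the stage requires ≥ 12 years with data and
   is otherwise skipped with a report note.
4. **Record residuals**: accessions fixed, years random; conditional
   residuals standardised to unit SD; records outside the Tukey fences
   [Q1 − 1.5 IQR, Q3 + 1.5 IQR] (linear-interpolation quartiles; both
   configurable) are removed. A degenerate IQR falls back to |z| > 3. A
   non-converged fit halts the trait with a report entry instead of passing
   records through silently.

The report's `n_data` counts records entering stage 3 (post-plausibility),
`n_outlier` the records removed by stages 3–4, matching the convention of
before/after summaries for this kind of audit; "initial" heritability is
computed on post-plausibility data, "final" on fully curated data. Every
removed record appears exactly once in the log with stage and reason.

## Heritability

Entry-mean ("ad-hoc") broad-sense heritability for unbalanced data:

    h2 = sigma2_g / (sigma2_g + sigma2_gb / q + sigma2_e / p)

with all terms from the all-random fit in which year and experiment are
combined into one environment factor. `q` is the harmonic mean over
genotypes of the number of distinct environments, `p` the harmonic mean of
records per genotype — the standard plug-in for unbalanced designs; a
literal-sum reading of the counts is available behind
`effective_counts(..., mode="literal-sum")` for sensitivity analysis only.
With a single experiment the interaction is not estimable from unreplicated
records and the reduced form (interaction term omitted) applies. `h2` is 0
whenever `sigma2_g` is 0, and is clipped to [0, 1].

## Contrasts and correlations

Convariety effects on BLUEs use the one-way model `y = mu + v + e`:
pooled-variance t statistics on all pairwise mean differences (Welch
optional), Holm step-down adjustment across the family, and a compact letter
display built by insert-and-absorb so that two groups share a letter exactly
when they are not significantly different. Groups with a single accession
are excluded from testing and reported. BLUEs enter unweighted, mirroring
the two-stage convention; a weighted mode is out of scope.

Trait correlations are pairwise-complete Pearson correlations between BLUE
vectors (Spearman optional), p values from the t transform of r,
Holm-adjusted over all trait pairs; pairs with fewer than 3 shared
accessions are reported untested.

## Weather and frost exposure

QC on the 5 cm daily minimum removes values deviating by more than 20 °C
from **both** adjacent days (a genuine cold front deviates from one side
only; an either-neighbour mode is configurable, and a missing neighbour
counts as agreeing) or by more than 15 °C from the simultaneous 2 m minimum.
Gaps are filled by the smoothed state of a local-level state-space model
whose two variances are estimated by maximum likelihood per season; series
with fewer than 10 observations fall back to linear interpolation. Observed,
unflagged values are never altered. Missing snow depths are reconstructed by
the recursion

    snow_t = max(0, snow_{t-1} + ratio * precip_t * [tmin5_t < 0]
                   - melt_rate * max(0, tmin5_t))

with defaults ratio = 1.0 cm/mm and melt_rate = 0.5 cm/(°C·day).

Frost exposure per season (Nov 1 – Apr 30): days with snow < 5 cm count as
mild frost stress below −6 °C and severe below −14 °C; the seasonal minimum
of the 5 cm temperature over thin-snow days is reported alongside, and days
still missing after imputation are tallied separately. The 1–9 survival
score maps linearly to percent: pct = (score − 1)/8 × 100.

## Synthetic data

The generator mirrors the fitted model: independent normal accession, year,
experiment and interaction effects, fixed convariety offsets, and i.i.d.
residuals whose SD can be inflated per year. Design unbalance follows the
regeneration practice: years per accession are 1 + Binomial(span − 1, p)
with p calibrated so the mean matches the collection's 4.36 cultivation
years (4.8 for the winter set), year subsets drawn uniformly, one plot per
accession-year. Convarieties default to the spring-collection imbalance
(1043 sativum, 590 speciosum, 163 axiphium, 900 medullare,
30 medullosaccharatum, remainder unknown). Gross errors are symmetric
two-sided shifts of ±8 residual SDs at a configurable rate, truth-flagged.
Weather is a seasonal sinusoid plus AR(1) noise (lag-1 correlation 0.7) for
the 2 m minimum, a stochastically offset 5 cm minimum below it, intermittent
exponential precipitation, snow from the same accumulation–melt recursion,
plus truth-flagged gaps and isolated +40 °C spikes.

What the generator does **not** emulate: genetic relatedness or marker data,
spatial field trends, trait-specific measurement scales (ordinal scores are
simulated as continuous), correlated traits, non-normal error tails beyond
the injected shifts, and calendar drift in recording standards. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every pathology of real historical data.

## Validation harness and problem sizes

`histpheno.validation` regenerates data and measures, from scratch: REML vs
closed-form ANOVA on 20 random balanced one-way designs; heritability
recovery bias at true h2 ≈ 0.1/0.5/0.9 (500 accessions, 20 replicates per
level); curation recall and heritability improvement under 5% injected gross
errors plus one 12x-inflated year (300 accessions, 30-year span, 10
replicates — a desk-scale stand-in for the collection's ~3000 accessions
that keeps every structural feature of the design); clean-data safety;
the letter-display property on 200 random significance patterns; weather
spike detection and imputation RMSE against mean fill (10 seasons); and BLUE
vs raw-mean correlation with truth (20 replicates). `scripts/acceptance.py`
writes these numbers as JSON.

## Known limitations

- Per-year residual variances are screening statistics from a second pass,
  not joint REML estimates; they are not returned as formal components.
- The Wald/LRT model-reduction tests use asymptotic references; with very
  few levels of the tested factor they are approximate.
- BLUE standard errors ignore uncertainty in the variance components.
- The snow recursion is a deliberately minimal two-parameter model; it
  reconstructs cover presence/absence around the 5 cm threshold well but is
  not a physical snowpack model.
- The curation pipeline is sequential and single-pass by design; it does not
  re-estimate thresholds after removals.
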