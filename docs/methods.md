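# Methods

## The cascade

The core computation is a sequential risk-factor accounting within ten
canonical age bands (half-open in completed years: [0,10), [10,15),
[15,16), [16,20), [20,25), [25,35), [35,45), [45,65), [65,75), [75,∞)).
Within a band, ordered factors with effective prevalences p₁…p_K are
applied one at a time; the fraction still unflagged after step k−1 is
multiplied by p_k and removed. Effective prevalence is 0 outside a
factor's age scope and 1 for *wholesale* factors (whole band counted, e.g.
age < 10). The flagged total per band equals 1 − Π(1 − p_k), the
inclusion–exclusion total for independent factors; independence is a
modelling assumption, not an estimate — where dependence matters the user
must supply prevalences already conditioned appropriately (the
chronic-disease union, estimated per respondent before weighting, is the
one place joint occurrence *is* handled exactly).

Factor order changes only the decomposition, never the total (the product
is symmetric); the shipped presets place the two wholesale age factors
first, then chronic disease, pregnancy, outdoor work, education, vitamin C,
and — inclusive criteria only — a final wholesale "remainder" over the
10–14, 15, 16–19 and 65–74 bands. That remainder implements the inclusive
age criteria (< 20 and ≥ 65) as *what is left* in those bands after the
substantive factors, so the decomposition still reports, e.g., chronic
disease among teenagers separately. Whether the wholesale age factors come
before or after the others is immaterial for totals and was fixed for the
decomposition's readability.

All internal arithmetic is full precision; percents are rounded to one
decimal only at CSV/console output. A zero-population stratum carries
well-defined cascade fractions but contributes nothing to totals.

## Prevalence inputs

* **Survey-weighted** (chronic disease, low education): Σwᵢxᵢ/Σwᵢ over the
  region × stratum domain, complete-case per indicator; for the
  chronic-disease union, respondents missing any of the four components
  are dropped from the union estimate. An empty domain raises rather than
  returning 0; the table builder's fallback is the national pooled
  estimate, tagged `survey-national-fallback` in the provenance column.
* **Pregnancy**: point prevalence among females per stratum =
  (births·d_b + fetal losses·d_l + abortions·d_a) / female population,
  with gestational durations d = 40/52, 11/52 and 10/52 years by default —
  configuration values, not constants. Stratum-wide prevalence is the rate
  times the band's female fraction. Pregnancy applies to the 15 band
  through 45–64; supplying near-zero rates at high ages (the default)
  makes the exact upper scope numerically minor.
* **Education** applies from the 20–24 band upward by default: the
  remainder factor already covers 10–19 under inclusive criteria, and a
  high-school-completion indicator is not meaningful for children. Both
  scopes are config-overridable via custom `FactorSpec`s.
* **Supplied national tables**: low vitamin C by age (broadcast to
  regions); outdoor work by age × urban/rural, mixed per region as
  uf·p_urban + (1−uf)·p_rural with the region's urban fraction uf.

## Exposure and cross-classification

Regional concentration = mean over years of the mean over the region's
grid cells within each year (area-weighted if a weight column is given;
unweighted by default — population weighting of cells is deliberately not
assumed). Missing cell-years are an input error, never imputed; with
balanced data the averaging order is immaterial. Quartile thresholds are
linearly interpolated order statistics (numpy's default, "type 7");
labels are 1 + [v > Q25] + [v > Q50] + [v > Q75], so ties at a threshold
take the lower quartile, and labels are invariant under strictly
increasing transforms. All-identical values degenerate to quartile 1 with
a logged warning. The stability diagnostic is the squared Pearson
correlation of regional means between a short and a long averaging
window.

## Rank correlations

Spearman rho is the Pearson correlation of midranks. The two-sided
p-value is exact for n ≤ 8 — computed from the full n! permutation
distribution of one margin's ranks — and a t-approximation with n − 2
degrees of freedom above that. The exact small-n path exists because the
t-approximation is badly calibrated there (for n = 5 and ρ = 0.9 it gives
0.037 where the permutation distribution gives 0.083). Degenerate pairs
(zero rank variance) raise; the batch report catches per pair and emits
NA with a note instead of aborting.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults emulate a Canadian-scale setting: 110 regions,
log-normal region populations (median ≈ 165k), national age shares
summing to 1 over the ten bands, urban fractions uniform on [0.10, 1],
and factor prevalences set so the national restrictive and inclusive
totals land near one third and two thirds (chronic disease rising from
~10% in youth to 33% at 65–74; outdoor work ~24–33% of adults, higher
rural; education 7–21% by age band; low vitamin C ~12–14%; age-specific
pregnancy rates peaking at 6.5% of females 25–34). These were fixed from
the published prevalence ranges for this setting before any tests were
written and are not tuned thereafter.

Structure deliberately built in:

* **Regional heterogeneity** — age shares are Dirichlet(h · national
  shares) with h = 150 (h → ∞ gives identical regions); survey-estimated
  factors get one logit-scale N(0, 0.15) shift per region × factor,
  shared across strata, so regions are coherently healthier or sicker.
* **Urbanicity–PM₂.₅ association** — regional PM₂.₅ mean = 4.5 + 5.0·uf +
  N(0, 1.5) µg/m³, calibrated to a rank correlation with urban fraction of
  about 0.65 at n = 110; O₃ (33 ± 5 ppb) has no urban gradient.
* **Informative sampling** — respondents are drawn from age × urbanicity
  cells with log inclusion rates tilted by `weight_dispersion` (older and
  rural cells oversampled); recorded weights are the exact design weights
  N_cell/(n·p_cell), so weighted margins match population margins in
  expectation and `weight_dispersion = 0` reproduces equal weights.
  Because true prevalences are constant within a stratum, per-stratum
  weighted estimates are unbiased regardless of the tilt; the weights
  matter for any cross-stratum domain.
* **Exact union truth** — the four chronic components are drawn
  independently with a common rate chosen so their union prevalence
  equals the configured truth, giving realistic multimorbidity.
* **Self-consistent truth** — pregnancy event counts are real-valued and
  back-converted through the gestational durations so the point-prevalence
  operation recovers the configured rates exactly, and the stored true
  regional totals are produced by running the cascade on the true
  prevalence table.
* **Surfaces** — cell-year value = regional mean + fixed spatial cell
  offset N(0, σ_s) + region-wide inter-annual shock N(0, σ_a), truncated
  at zero (a pragmatic choice over log-normal concentrations; at the
  default means truncation is almost never active). Each region owns
  `cells_per_region` cells; a region with zero cells raises.

One global seed fans out to the region, survey and surface stages through
fixed offsets, so each stage is individually reproducible; identical
config + seed gives byte-identical outputs.

**What the generator does not emulate:** spatial autocorrelation
(kriging) in the surfaces, survey bootstrap replicate weights, household
clustering, within-respondent dependence between risk factors (a hook is
the natural extension point — the truth table format already carries
per-region factor prevalences), and urban/rural differences in
survey-estimated factor prevalence within a stratum. Passing recovery
tests therefore show the estimators are correct under independent,
MCAR-missing, stratified-sampled data — not that real survey artefacts
(informative non-response, self-report error) are handled.

## Problem sizes

Validation runs use 110 regions × 2,000 respondents for the full-pipeline
reproduction, 20 regions × 20,000 respondents × 20 seeds for truth
recovery (region-level totals within 1 percentage point of truth for
≥ 95% of comparisons), 1,000 random instances against the exact
enumeration oracle (≤ 6 factors, agreement to 1e-9), Monte-Carlo checks at
10⁵–2·10⁵ draws (3-SE criterion), and full permutation enumeration for
rank-correlation p-values up to n = 8. These sizes are the package's own
test design and give comfortable statistical margins at interactive
runtimes.

## Known limitations

* Point estimates only: no design-based variance or confidence intervals
  for survey prevalences, and no uncertainty on cascade totals.
* No quantitative susceptibility weights per factor — susceptibility is
  "≥ 1 risk factor", with the restrictive/inclusive contrast as the
  sensitivity analysis.
* The cell → region map is an input; no regridding, projections, raster
  or shapefile I/O.
* The t-approximation p-values at n ≈ 100 can differ in the far tail from
  other software's conventions; rho is convention-free given midranks.
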