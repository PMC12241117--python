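# Methods

## Cover estimation

Floristic tables record, for each species in each vegetation community,
a Roman frequency class (I–V, the proportion of quadrats occupied in
20%-wide bands) and a Domin cover-abundance score (1–10). The cover
estimate multiplies the band midpoint (I → 0.10, II → 0.30, …,
V → 0.90) by Currall's Domin conversion, percent cover = Domin^2.6 / 4,
expressed as a proportion. The midpoints are the equally spaced band
centres; the largest possible estimate (class V, Domin 10) is
0.90 × 0.99527 ≈ 0.896, so covers never reach 1.

Per-habitat cover is the arithmetic mean of these estimates over the
communities of the habitat *in which the species occurs*. Floristic
tables record occurrences only, so the occurrence-conditional mean is
the default; `zero_pad_communities=True` instead averages over every
community of the habitat, counting absences as zero — both readings of
"mean over the habitat's communities" are available because the choice
changes W-A/W-AH weights. A community mapped to several habitats
contributes its full estimate to each; the weighting stage renormalises
per species, so no double counting of total weight results.

## Weighting schemes

All four schemes share one support — the (species, habitat) cells with
strictly positive cover — and satisfy exact conservation contracts
(tested to 1e-12): W-S, W-A and renormalised W-AH rows sum to 1 per
species; Unw rows sum to the species' habitat count. W-A and W-AH are
invariant to rescaling any one species' covers, and rank a species'
habitats by cover and by cover × area respectively.

W-AH's renormalisation is a genuine modelling choice: the raw
area-scaled weights give species in small habitats less *total* weight,
whereas renormalisation keeps every species' total at 1 and only
redistributes it towards the habitats holding most of its population.
Renormalisation is the default (`renormalize=False` gives the raw
product) because equal total weight per species is the stated purpose
of weighting; the flag is echoed in the run manifest.

## Distribution Index

DI is the weighted geometric mean of annual occupancy scores over the
species weighted into a habitat; spread is the weighted geometric SD
using the biased (population) variance of logs, reported as a
multiplicative factor ≥ 1. Both are invariant to scaling a habitat's
weights by a positive constant, so schemes differ only through how mass
is distributed. Occupancy is clamped to [1e-6, 1 − 1e-6] before logs
(geometric means are undefined at 0; occupancy-model output is interior
but synthetic edge cases must not crash), with the clamp count logged.
Species-years missing from the occupancy table are dropped for that
year with the remaining weights renormalised; a `coverage` column (the
fraction of habitat weight present) exposes the gaps rather than
imputing them. A single-species cell has no defined spread and reports
gsd = NaN.

## Trend estimation

Each species' series is smoothed with a cubic smoothing spline — the
one-dimensional form of a thin-plate spline — in the Green & Silverman
fitted-value parameterisation: f minimises ||y − f||² + λ f′Kf, where K
is the natural-spline roughness penalty built from second differences.
One eigendecomposition of K yields the full profile of fits, effective
degrees of freedom (trace of the smoother) and GCV score
n·RSS/(n − edf)² over a λ grid of 81 points spanning 10⁻⁸–10⁸. The
minimiser of GCV is taken subject to edf ≥ 3, so the fit can flex
beyond a straight line even when GCV is flat; linear series are
reproduced exactly at any λ (they lie in K's null space), λ → 0
interpolates, λ → ∞ gives the least-squares line — all tested.
Series need at least 4 distinct years.

The trend between the first year of an assessment window and the
penultimate year of the species' own series (its last smoothed year is
considered edge-unstable and never used) is annualised by default,
(v_pen/v_start)^(1/Δt) − 1, making long- and short-term values
comparable per year; `metric="total"` gives the unannualised change.
Long-term windows start at each species' first year of data; short-term
windows at a fixed start (default 2005), and the penultimate year can
be capped (default 2015) to fix a common assessment end. Species whose
data begin after the short window start get no short-term trend and are
flagged in the log.

On synthetic logit-linear species (45-year series), noise-free trends
are recovered to better than 1e-3/yr and, at logit-scale noise SD 0.1,
with median absolute error well under 0.01/yr.

## Statistical comparison

The index comparison is a REML linear mixed model DI ~ method with
random intercepts for habitat and year-within-habitat (statsmodels
MixedLM; the year-within-habitat term enters as a variance component
within the habitat grouping). The unweighted scheme is the reference
level, so coefficients are each method's shift of the index. t-test
degrees of freedom use the residual approximation — no Satterthwaite
correction is available in this stack; the choice is recorded in the
result metadata, and on balanced designs the fixed effects equal cell-
mean differences regardless. Per-habitat models use year as the random
intercept.

The trend comparison stacks (species, habitat, method, trend, weight)
rows and fits weighted least squares trend ~ habitat × method with the
scheme's own weights, reporting a type-II ANOVA for habitat, method and
interaction, and marginal means per habitat × method with 95% CIs. For
this saturated design the marginal means equal direct weighted cell
means (tested to 1e-8), matching the estimated-marginal-means
convention. p-values are raw; no multiple-testing correction is
applied, so families of habitat contrasts should be read accordingly.

## Synthetic data

The generator emulates the structure of the real inputs without any
download: specialists confined to one habitat, generalists spread over
a configurable number of habitats with frequency/Domin drawn
independently per community (making abundance weights non-uniform by
construction); habitat areas log-spaced over a configurable number of
decades (default 2.5, summing to a country-scale 7.8 × 10⁶ ha);
occupancy following expit(logit(b) + m·t + ε) with ε ~ N(0, noise_sd²)
on the logit scale, which keeps scores in (0,1) and mimics
occupancy-model output noise. Default dynamics are declining
specialists (baseline 0.15, −0.02 logit/yr) and rising, commoner
generalists (0.35, +0.03 logit/yr) over 1970–2016, with per-species
slope jitter (SD 0.01/yr) and year noise SD 0.1. One global seed feeds
a fixed-index substream per operation, so adding draws to one stage
cannot shift another; ground truth (class, habitats, baseline, realised
slope) is always returned.

What the generator does *not* emulate: spatial structure, record-level
detection, correlated year effects across species (real occupancy
models share detection covariates), taxonomic drift, and habitat-area
change through time. Tests passing on synthetic data therefore
demonstrate the pipeline's arithmetic and its qualitative behaviour
under known specialist/generalist contrasts — not calibration against
any real survey.

The packaged demonstration (`habindex demo`) sharpens the defaults into
a scenario where the generalist bias is analytically guaranteed: 40
generalists per study (~12 per habitat) rising at +0.03 logit/yr
against 3 specialists per habitat declining at −0.01/yr. There the
unweighted habitat trend mean is dominated by generalists and clearly
positive, while area weighting in small habitats concentrates mass on
the few specialists, widening the CI until the trend is
indistinguishable from zero — the qualitative phenomenon the weighting
schemes exist to expose.

## Problem sizes and numerical choices

Default study sizes (10 habitats, 4 communities each, 50–70 species,
47 years) keep a full pipeline run to a few seconds while preserving
the structure that matters: several species per habitat, habitat areas
spanning decades, and decades-long series for spline smoothing. CSV
output uses 12 significant digits — enough to round-trip doubles for
all quantities used here; rerunning a config yields byte-identical
files, while re-reading written CSVs reproduces downstream results to
~1e-9 relative. Ties and degenerate inputs: all-zero-cover species,
missing areas, zero-area habitats and sub-4-year series raise typed
errors rather than propagating NaNs; habitats with no weighted species
emit no rows and a warning.
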