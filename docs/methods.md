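# Methods

## Wintering-cost model

The seasonal cost of wintering for one sex at one site is maintenance
metabolism integrated over the winter plus the round-trip migration cost:

    total (kJ) = (BMR + H_sm) · winter_days · 86.4 + (2·D/S) · C_sex

**BMR.** The allometry for shorebirds wintering in temperate Europe,
BMR (W) = 5.06 · BM^0.729 with body mass in kg.  The exponent below 1 is what
makes the comparison interesting: the heavier female has the higher absolute
BMR (2.22 vs 1.95 W) but the lower mass-specific one — the energetic basis of
the Bergmann argument.

**Standardized heat loss.** Extra thermoregulatory power,

    H_sm = max(0, K_es·(T_b − T_a) + K_u·u^exp − K_r·R_g),

a conductance term down the body–air gradient (T_b = 41 °C for both sexes;
K_es = 0.0914 W/°C male, 0.1111 W/°C female), a convective wind penalty and a
radiative subsidy.  H_sm is floored at zero before it enters the maintenance
sum so that maintenance never drops below BMR at thermoneutral sites: the
term models *extra* cost only.  The wind and radiation coefficients are not
published for this species; the package treats them as required configuration
with documented placeholder defaults K_u = 0.2 W·(m s⁻¹)^−exp, exp = 0.5
(convective transfer roughly with the square root of wind speed) and
K_r = 0.01 W/(W m⁻²) (small: winter insolation at these latitudes averages a
few tens of W m⁻²).  Every pipeline report echoes the coefficients actually
used, so published-figure analogues are always reproducible from the echo.

**Migration.** Distances are one-way great-circle kilometres from each site
to the fixed breeding-ground reference (70°16′N, 24°05′E) on a sphere of
6371 km, haversine form (numerically stable at short range).  A per-site
`distance_km_override` column reproduces published distances exactly when the
original measurement tool differed; the packaged site table's overrides
exceed the haversine values by ~80 km consistently, so the override is the
default for the published sites.  Cost is linear in distance:
(2D/S)·C_sex with S = 75 km/h, C_sex = 67 (female) / 55 (male) kJ/h.  With
the default coefficients, migration is ~3–5% of seasonal maintenance — a
minor term, which is itself one of the analysis' conclusions.

**Season length.** 182 days (October–March, matching the window over which
the climate forcing is averaged), converting W to kJ at 86.4 kJ per W·day.

## Benthos

Cores (0.0177 m², 30 cm deep) are sieved in two strata — top 0–4 cm
(peck-accessible) and bottom 5–30 cm (probe-only) — and each layer's sample
reduced to ash-free dry mass (dry − ash).  Records with ash mass exceeding
dry mass are flagged, logged and excluded; a core missing one layer still
counts for the other (the field data's differing ANOVA denominators between
layers imply exactly this).  Site summaries give per-layer mean ± sample SD
(n−1) of density and the **mean of per-core bottom-layer shares** — not the
pooled ratio.  The distinction matters: two cores with shares 100% and 60%
average to 80% although the pooled ratio is 63.6%, which is why a site can
show a bottom-share mean of 80% alongside layer means whose ratio is ~90%.
Empty cores (zero AFDM in both layers) are excluded from the share summary
with a log entry.

## Sex ratios

The unit of replication is the scan session.  Each session's female
proportion is transformed with the empirical logit, log(p/(1−p)) with
p = (y+0.5)/(n+1): finite for all-male and all-female scans, antisymmetric
under swapping the sexes, and exactly 0 at an even tally.  Site estimates
back-transform the mean session logit; 95% intervals use the t distribution
on session logits (df = sessions − 1), so they respect the (0, 100)% range
by construction.  Sessions are equally weighted regardless of flock size —
the session, not the bird, is the random unit; a size-weighted variant is
available as a sensitivity flag.  Within-site bias is a two-sided one-sample
t test of session logits against zero.

The site effect on sex ratios is a Gaussian likelihood-ratio test of the
session logits with versus without the site factor, χ² = n·ln(RSS₀/RSS₁),
df = sites − 1.  With one observation per session, a mixed model with a
session random effect is confounded with the residual, so this fixed-effects
test is the estimable equivalent.  The p-value is computed through the exact
monotone F transformation F = ((RSS₀−RSS₁)/(k−1))/(RSS₁/(n−k)) rather than
the asymptotic χ² tail: at the survey scale (60 sessions) the χ² reference
rejects a true null ~7% of the time, while the F form is exactly calibrated
under normality.  The χ² statistic itself is reported for comparability.

## Inference battery

Layer-biomass differences between sites use classical one-way ANOVA
((k−1, N−k) df, unbalanced groups allowed; an all-identical input reports
F = 0, p = 1 rather than failing) with Tukey–Kramer all-pairs contrasts as
the only multiplicity adjustment.  Correlations are Pearson r with the
two-sided t-based p (df = n − 2); zero-variance input raises an
undefined-correlation error, which the hypothesis panel converts into a
flagged NaN result instead of crashing.  Linear models (cost ~ distance;
score ~ cost × sex) are ordinary least squares; rank-deficient designs are
rejected rather than silently repaired.  p-values below 1e−16 are reported
as bounds, never as zero.

The four-way hypothesis panel correlates the per-site percentage of females
with (a) site wintering cost (site-level, n = sites; cost is the sex-averaged
seasonal total), (b) per-core bottom AFDM and (c) per-core top AFDM — each
core paired with its site's %F, matching the sample-level degrees of freedom
the field analysis reports — and (d) the site bottom-layer share.  A
site-level variant of (b)/(c) sits behind a flag.

## Synthetic generator

The generator emulates the field campaign's design: 6 sites spanning
0–7 °C and 1940–3093 km (temperature rising with distance — colder sites are
closer to the Arctic), 10 cores and 10 scan sessions per site, scan sizes
truncated-normal 117 ± 108.4 with a floor of 10 birds (below which logits
degenerate), wind 4–8 m/s and radiation 30–80 W/m² uniform.

Benthos: site i draws a bottom share s_i (logit-normal, mean logit 1.1,
SD 1.3) and total density T_i (lognormal around 7 g AFDM/m², SD-log 0.4) with
a positive loading (0.65) of the share on log-total — bottom-heavy flats are
biomass-rich, as the deep-living large polychaetes dominate mass.  Layer
expectations are T·(1−s) and T·s; each core multiplies both layers by a
shared lognormal factor (SD-log 0.7) plus per-layer noise (SD-log 0.2).
These five numbers were calibrated once, against the field study's own
reported correlation structure: at the survey scale (60 cores) the median
core-level top–bottom correlation is ≈0.47 (field value ≈0.5), while the
share still varies enough across sites to drive the sex-ratio link.  The
construction makes the top layer correlate *negatively* with the bottom
share (top ∝ 1−s) — the mechanism behind the panel's negative top-layer
correlation — even though the two layers correlate positively across cores.
Ash fractions are uniform 10–30% of dry mass, so cores round-trip through
the dry/ash CSV format.

Sex-ratio links (per-site probability that a scanned bird is female):
resource partitioning, logit pF = −2.9 + 4·(bottom share), spanning
pF ≈ 0.3–0.8 across typical share draws; Bergmann, logit pF = z-scored
sex-averaged site cost; null, constant 0.5.  Female counts are binomial per
session; an optional overdispersion SD adds session-level logit noise
(default 0 — the field data give no within-site variance to match).

Condition scores: a latent Gaussian with mean
3.0 + 0.4·cost_z − 0.2·male + 0.25·cost_z·male (cost standardized across the
sex-site table, SD 1) cut at 1.5/2.5/3.5/4.5 into scores 1–5, 50 records per
sex-site group (600 per survey).  The positive interaction makes male scores
steepen with cost — males carrying relatively larger safety stores at
expensive sites.  Because the score is a cut Gaussian, the OLS fit of
score ~ cost × sex estimates the *implied mean-score* coefficients (the
linear projection of 1 + ΣΦ((m−c_j)/σ) onto the design), which are slightly
flatter than the latent coefficients near the scale ends; the recovery
experiment therefore computes that projection analytically as its truth, and
uses heteroscedasticity-robust (HC1) standard errors, which match the
analytic sandwich for this design (classic SEs run ~3% low because score
variance shrinks in floor/ceiling cells that sit at high leverage).

Determinism: all stages draw from named streams spawned from the root seed
(sites, benthos, counts, aps), so a fixed scenario yields byte-identical
CSVs and any stage can be regenerated independently.

## What the synthetic experiments do and do not show

Passing calibration and recovery under this generator shows the pipeline's
statistics are correctly implemented and adequately powered *for surveys
shaped like this one*.  The generator deliberately omits spatial
autocorrelation within mudflats, temporal turnover across the winter,
observer error in scans beyond binomial noise, and any taxon-level prey
structure — so the experiments validate the machinery, not the field
conclusions themselves.  Problem sizes in the replicated experiments (2000
null surveys for type-I calibration, 200 per hypothesis for the signature
frequencies, 500 for coefficient recovery) were chosen to bound Monte-Carlo
error near 0.5 percentage points on the reported rates.

## Numerical choices and edge cases

* Heat loss floored at 0; maintenance ≥ BMR always.
* Haversine clipped into [0, 1] before arcsine; verified against a
  spherical-law-of-cosines oracle to 1e−6 relative on 1000 random pairs.
* Sample SDs use n−1; single-core or single-session groups report SD 0 with
  an explicit `sd_defined` / `ci_defined` flag rather than NaN.
* Sessions with one bird are rejected at load; count tables must satisfy
  n_male + n_female ≥ 1.
* Output ordering is fixed (sites by distance ascending, mergesort
  throughout), so identical inputs give byte-identical reports.

## Known limitations

The heat-loss coefficients K_u, K_r and the wind exponent are placeholder
defaults, not species-fitted values; absolute maintenance levels (and hence
the migration-share percentage) shift with them, though the qualitative
structure (female > male, colder = dearer, migration minor) is robust across
reasonable choices.  The great-circle distances from the stated breeding
coordinate undershoot the packaged published distances by ~80 km; the
override column exists for exact reproduction.  The sex-ratio model treats
sessions as independent; repeated scans of partly overlapping flocks would
violate this.
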