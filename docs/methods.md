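# Methods

## Scope and data model

`alrisk` analyses a series of consecutive rectal cancer resections with a
primary anastomosis and no diverting stoma. One row per operation carries:
sex, age (years), BMI (kg/m²), ASA physical-status grade (1–3), AJCC stage
(0–4), maximum tumour size (cm), tumour location (upper 8–12 cm, mid
4–8 cm, low 0–4 cm from the anal verge), operative time (min),
perioperative transfusion, neoadjuvant chemoradiotherapy, linear stapler
firings, a 1-based consecutive operation index `seq`, and the binary
clinical anastomotic-leak outcome. `seq` is the time axis of the RA-CUSUM
chart and of the strategy "eras" (fibrin glue, reinforcing sutures,
extended splenic flexure mobilization, transanal drainage tube), each of
which stays in use from its first case onward.

## Synthetic cohort generator

The generator emulates a 736-patient single-surgeon series:

- **Categorical marginals** follow the published denominators out of 736
  (male 464, mid 215, low 74, transfused 62, CRT 85, ≥2 stapler firings
  360). The source ASA row sums to 836, so its as-printed counts
  (280:517:39) are normalised to probabilities. The AJCC split inside the
  printed 0–II (439) and III/IV (297) groups is not published; we use
  (20, 160, 259) and (260, 37) — stage 0 and IV rare, as expected in a
  resection-with-anastomosis cohort.
- **Continuous marginals** are clipped normals/log-normals whose published
  dichotomisation fractions are matched: P(age ≥ 70) = 330/736 via
  N(68.7, 10²); P(BMI ≥ 25) = 229/736 via N(23.7, 2.6²); P(size ≥ 4 cm) =
  416/736 via logN(ln 4.3, 0.5²); operative time logN(ln 200, 0.177²) so
  the median is 200 min and P(≥ 240 min) = 112/736.
- **Outcome model**: leak ~ Bernoulli(σ(β₀ + xᵀβ + era(seq))). Effects are
  odds ratios: female 0.272, ASA ≥ 3 3.818, mid 1.757, low 3.721,
  transfusion 3.495, and 1.343 per unit of operative time. The published
  estimate is labelled "(min)" but a per-minute OR of 1.343 is impossible,
  so the unit defaults to 60 min (configurable); operative time is centred
  at its 200-min median so that β₀ stays interpretable (centring does not
  affect the ORs). All other covariates are null (OR 1), matching the
  non-significant univariate results.
- **Intercept**: not published. When left unset it is solved by Brent root
  finding so that the Monte-Carlo mean risk (200,000 covariate draws with a
  fixed internal seed, seq sampled uniformly) equals the 8.8% target leak
  rate. Resolution is therefore deterministic and independent of the
  cohort seed, and `true_risk` reproduces the exact Bernoulli parameter
  used for any record.
- **Era shifts** are additive cumulative log-odds offsets. The defaults,
  boundaries (71, 155, 397, 480, 584) with shifts (−0.8, 0, 0, −0.7, 0),
  encode a learning-curve improvement after case 70 and a protective
  extended-SFM effect after case 480 — the two slope changes the monitored
  series is meant to exhibit — with null effects for the other strategy
  introductions.
- Covariates are drawn independently (only marginals are published); there
  is no correlation structure, no missingness, and no time trend in
  case mix. Passing tests therefore demonstrate correctness of the
  *methods* under these idealised conditions, not performance on real
  surgical data, where confounded covariates and era-by-case-mix
  interactions can move every estimate.

## Univariate screen

Continuous variables are screened on the published dichotomisations
(age 70 y, BMI 25, size 4 cm, time 240 min, firings 2). Pearson's χ² is
used with the Yates continuity correction on 2×2 tables — the corrected
statistic is what reproduces the published p-values (e.g. 0.002 for sex) —
and without correction on larger tables. The entry gate is strict:
p < entry_alpha, default 0.10. Yates makes the 2×2 gate mildly
conservative (measured type-I rate ≈ 7.6% at n = 736); this is inherent to
the correction, not a defect.

## Logistic model and stepwise selection

Multivariate coding mirrors the published presentation: male, ASA 1/2 and
upper rectum are reference levels; ASA is collapsed to ≥3 vs ≤2; operative
time is continuous per 60 min. Fitting is maximum likelihood (Newton) with
gradient tolerance 1e-10, delegated to `statsmodels.Logit`; Wald 95% CIs
are exp(β ± 1.96·SE). Perfect separation and rank-deficient designs raise
typed errors naming the offending terms; records with missing model
covariates are dropped complete-case with a recorded count.

Backward elimination removes one term per iteration — the one with the
largest removal p ≥ stay_alpha (default 0.05; the removal threshold is not
published, so it is exposed as configuration). Single-column terms use
their Wald p; multi-column categorical terms use a block likelihood-ratio
test, which is why a non-significant middle level (mid rectum) can remain
in the final model alongside its significant sibling. Exact p ties break
alphabetically, making selection fully deterministic.

## Nomogram

For each term the contribution β·x is evaluated over its domain (levels for
categoricals; the observed cohort range — or an explicit plotted range —
for continuous terms, discretised at round-number breakpoints). The
largest contribution span maps to 100 points and fixes the global
points-per-log-odds scale; each variable's minimum contribution maps to 0.
The probability axis inverts total points through
σ(β₀ + Σᵥ minᵥ + total/scale), so scoring is an exact inversion of the
model: points are kept as reals internally and only rounded in rendered
output, which keeps the round trip accurate to 1e-9. Out-of-domain
continuous values are clamped to the axis ends by default (configurable to
raise). Which variable reaches 100 points depends on the fitted
coefficients and the plotted ranges; with coefficients at the configured
effect sizes and a 1–8 h operative-time axis, operative time is the
dominant axis.

## Internal validation

The C-index is computed by mid-ranks (Mann–Whitney identity), so tie
credit of ½ is exact; its default CI is the Hanley–McNeil normal
approximation (the published interval's method is unstated; a bootstrap
percentile CI can be substituted). Dxy = 2(C − ½).

Optimism correction follows Harrell: for each of n_boot (default 240)
resamples, fit on the resample, score on both resample and original, and
average the difference; corrected C = apparent C − mean optimism. The
default `refit_policy` refits only the final model's coefficients per
resample; whether the original analysis repeated the stepwise search inside
the bootstrap is unknown, so a `full_stepwise` mode is provided for
sensitivity analysis. Resamples with a constant outcome or a failed fit
are redrawn (counted, capped). With a fixed seed the report is
bit-reproducible. Calibration uses 10 quantile bins by default (the
original smoothing method is unstated); duplicate quantile edges merge
bins, and constant predictions collapse to a single bin.

## RA-CUSUM and change-point detection

The chart is the unbounded observed-minus-expected sum Sₙ = Σ(Xᵢ − p0ᵢ),
with no holding barrier or decision limit. p0ᵢ come from the final
multivariate fit on the full cohort — an in-sample, retrospective
adjustment, acknowledged as such. When outcomes follow their p0ᵢ the
increments are martingale differences with E[Sₙ] = 0.

The original cut-off points were read visually; the algorithmic
replacement here fits piecewise-constant means to the increment series —
equivalent to a continuous piecewise-linear fit to Sₙ — by exact dynamic
programming over candidate knots (minimum segment length 30 cases), and
selects the number of segments k ≤ 5 by BIC = n·ln(SSE/n) + (2k − 1)·ln n.
Detection is deterministic; exact ties resolve to the earliest knot.

**Localization limits.** At leak-level event rates the change-point
location carries little information: for a risk doubling at p ≈ 0.09 the
per-case Kullback–Leibler divergence is ≈ 0.04 nats, so even an oracle
likelihood estimator that knows both regimes exactly localizes the change
within ±30 cases only ~59% of the time (measured over 300 replicates);
any practical detector does worse. Detected cut-offs on such series
should be read as ±50–100 case intervals, not points — consistent with a
monitored series reporting one strategy's start at case 480 and the
detected slope change some 20–30 cases later. The BIC penalty keeps the
false-alarm rate near zero on null series (100/100 single-segment in the
reference simulation) at the cost of ~50% power against a doubling of a
~9% risk over 300 cases; series with larger shifts or higher event rates
are detected reliably (see the identifiable-case tests).

## Determinism and outputs

A single integer seed drives cohort generation and the bootstrap; all
stages are otherwise deterministic, so a full pipeline run writes
byte-identical artifacts when repeated. For that reason run metadata
records package and library versions, the seed and the configuration — but
no wall-clock timestamps. Reports are plain CSV/JSON with a SHA-256
manifest.

## Problem sizes used in the test suite

Effect-size recovery uses 20 cohorts of n = 20,000 (seed-averaged ORs
within 10% of truth); oracle-equivalence checks use ≤30-record instances
against brute-force enumeration and a generic BFGS optimizer; RA-CUSUM
operating characteristics use 100–1,000 replicates of 600-case traces; the
overfitting demonstration uses n = 60 with seven model terms. These sizes
make every distributional claim measurable with comfortable Monte-Carlo
margins while the full suite completes in well under five minutes.
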