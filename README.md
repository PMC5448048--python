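# alrisk

Risk modelling and sequential monitoring of **anastomotic leakage (AL)**
after laparoscopic rectal cancer surgery.

After a rectal resection the bowel join (anastomosis) can break down; the
leak rate varies several-fold between patients, so both individual risk
counselling and the monitoring of a surgeon's evolving results require a
*risk-adjusted* view of the outcome series. `alrisk` implements that
workflow as a tested, reusable pipeline for cohorts of consecutive
operations:

1. **Univariate screen** — each candidate factor is cross-tabulated against
   the leak outcome and tested by Pearson's χ² (Yates-corrected on 2×2
   tables); factors with *p* < 0.10 enter the multivariate stage.
2. **Multivariate logistic model** — backward stepwise elimination on the
   screened factors; multi-level categorical terms (tumour location:
   upper / mid / low rectum) enter and leave as blocks via likelihood-ratio
   tests. The fitted model supplies each patient's predicted leak
   probability p̂ᵢ = σ(β₀ + xᵢᵀβ).
3. **Nomogram** — each model term is re-expressed on a 0–100 point scale
   (points ∝ |β|·range, the widest-spanning variable reaching 100); a
   total-points axis inverts back to probability, so paper scoring
   reproduces the model exactly.
4. **Internal validation** — concordance index C (ties ½), Somers'
   Dxy = 2(C − ½), and Harrell's bootstrap optimism correction
   (default 240 resamples): C_corrected = C_apparent − mean[C(fit*, boot*) −
   C(fit*, original)]. Calibration compares mean predicted risk with the
   observed leak fraction in quantile bins.
5. **RA-CUSUM** — the risk-adjusted cumulative sum Sₙ = Σᵢ≤ₙ (Xᵢ − p0ᵢ)
   rises by 1 − p0ᵢ at each leak and falls by p0ᵢ otherwise. Change-points
   in its slope are detected by exact dynamic-programming least-squares
   segmentation with a BIC penalty, and cases are annotated with the
   surgical-strategy eras active at their sequence index.

Because consecutive-patient surgical datasets are rarely shareable, the
package ships a **seeded synthetic cohort generator** that reproduces the
study conditions this pipeline targets: published covariate marginals, a
logistic outcome model with odds ratios 0.272 (female), 3.818 (ASA ≥ 3),
1.757 / 3.721 (mid / low rectum), 1.343 per hour of operating time and
3.495 (transfusion), an 8.8% overall leak rate, and sequence-indexed era
shifts emulating a learning curve and staged strategy introductions.

## Worked example

```python
import alrisk

cfg    = alrisk.resolve_config(alrisk.default_config(seed=5))
cohort = alrisk.generate_cohort(cfg)                       # 736 consecutive operations
screened = alrisk.screen_variables(cohort)                 # chi-square gate at p < 0.10
fit    = alrisk.backward_stepwise(cohort, screened)        # stepwise logistic model
nomo   = alrisk.build_nomogram(fit, cohort=cohort)

patient = {"sex": "M", "asa": 3, "location": "low",
           "op_time_min": 300.0, "transfusion": 1}
score = alrisk.score_patient(nomo, patient)
```

prints, for this seed:

```
screened: ['sex', 'asa', 'location', 'transfusion']
  female         72.4 points
  asa3           54.6 points
  location       63.4 points
  transfusion   100.0 points
total: 290.4 points -> P(leak) = 0.727
```

A male, ASA 3, low-rectal, transfused patient with a 5-hour operation sits
at the top of every axis, and the nomogram total converts to a 72.7%
predicted leak probability — identical to `alrisk.predict_risk(fit, patient)`,
since the point scales are an exact affine re-encoding of the linear
predictor.

The same analysis end-to-end from a shell, writing every report artifact
(univariate/multivariate tables, nomogram axes, validation JSON,
calibration, CUSUM trace, change-points, manifest):

```bash
alrisk run --seed 5 --out results/
```

```
apparent C-index: 0.729
bias-corrected C-index: 0.717
change-points: [256]
wrote 10 artifacts to results/
```

Subcommands `simulate`, `screen`, `fit`, `nomogram`, `validate` and `cusum`
run individual stages on a cohort CSV (schema documented in
`alrisk/io.py`); `--plots` adds PNG figures of the nomogram, calibration
curve and RA-CUSUM chart.

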