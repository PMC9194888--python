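# tfab

Normative standardization and clinical-usability analytics for the
telephone-based Frontal Assessment Battery (t-FAB), a 0–12 point screening
test of frontal-executive functioning administered over the phone in a
motor-response (t-FAB-M) and a verbal-response (t-FAB-V) version.

The package is aimed at neuropsychologists and biostatisticians who need to

* classify raw t-FAB scores with the published Italian norms
  (demographic adjustment + Equivalent Scores),
* derive *new* regression-based norms from their own normative cohort,
* run the validation analyses such a standardization rests on
  (correlation/ICC/PCA psychometrics, TOST equivalence, ROC diagnostics),
* plan studies with the matching analytic sample-size calculators, and
* simulate realistic cohorts to exercise the whole pipeline without data.

## The method

**Demographic adjustment.** A raw score RS is corrected to an adjusted
score through regression-based correction terms,

    AS = RS + Σᵢ βᵢ · (fᵢ(xᵢ) − f̄ᵢ)

where each `fᵢ` is a transform of a demographic covariate (e.g. age³,
log₁₀ education), `f̄ᵢ` its normative-sample mean, and `βᵢ` the negated
regression slope — so the correction removes the fitted demographic effect
and a participant at the sample means is adjusted by exactly 0. Transforms
and covariates are selected by forward-stepwise regression at α = 0.05.
The published model uses age³ on the motor scores only and an education
transform on every score.

**Equivalent Scores.** Norms use non-parametric tolerance limits on the
ranked adjusted scores: the outer tolerance limit (oTL) is the order
statistic bounding the worst 5% of the population with 95% confidence
(exact binomial construction — an outer limit first exists at n = 59).
AS ≤ oTL ⇒ ES 0 ("impaired"); ES 1 is "borderline"; ES 2–4 are "normal",
with ES 4 starting at the sample median and intermediate thresholds placed
by an equal-z partition of the [5th centile, median] interval.

**Validation analytics.** Pearson/Spearman correlations chosen by a
skewness/kurtosis rule with Bonferroni-corrected flags; ICC(2,1)/ICC(3,1)
reliability; PCA of the task correlation matrix; the two one-sided tests
(TOST) procedure for motor/verbal equivalence with standardized (dz)
bounds; AUC with DeLong standard errors for case–control discrimination;
and the TOST, noncentral-F regression, and Obuchowski ROC sample-size
formulas.

## Worked example

Score a 71-year-old with 8 years of education who scored 3,2 on
Conceptualization/Mental flexibility, 2,2 on the motor
interference/inhibition tasks and 3,2 on the verbal ones:

```python
from tfab import PUBLISHED_MODEL, ScoreRecord, score_participant

rec = ScoreRecord(id="p1", age=71, education=8, sex="F",
                  conceptualization=3, mental_flexibility=2,
                  interference_M=2, inhibition_M=2,
                  interference_V=3, inhibition_V=2)
for name, entry in score_participant(PUBLISHED_MODEL, rec).items():
    print(name, entry["raw"], entry["adjusted"], entry["es"], entry["label"])
```

prints

```
tFAB_M 9 10.09 2 normal
tFAB_V 10 10.65 2 normal
tFAB_1 5 5.48 4 normal
tFAB_2M 4 4.49 1 borderline
tFAB_2V 5 5.25 1 borderline
```

The motor total of 9/12 gains +1.09 points of demographic correction
(older age, lower education) and lands in the middle "normal" band, while
the motor subtest 2 (4/6) sits just inside the "borderline" band — the
profile a clinician would flag for follow-up despite normal totals.

Deriving fresh norms from a (here synthetic) cohort takes three lines:

```python
from tfab import NormativeStandardization, NormativeCohortSpec, generate_normative

res = NormativeStandardization(generate_normative(NormativeCohortSpec(seed=7))).fit()
print(res.summary())          # equations, p-values, TL ranks, ES bands
res.to_json("my_norms.json")  # reusable model file
```

The same operations are available from the shell:

```bash
tfab simulate normative --seed 7 --out cohort.csv
tfab derive-norms cohort.csv --out model.json
tfab score cohort.csv --model model.json --out scored.csv
tfab roc cohort.csv            # per-group ROC table vs the normative sample
tfab power tost --bound-dz 0.5 # -> {"n": 52}
tfab roc-n --auc 0.7 --kappa 10
```

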