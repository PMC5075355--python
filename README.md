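# hccbayes

Prediction of early recurrence of liver cancer (recurrence within one
year of curative resection) from routine laboratory and pathology
markers, for biostatisticians and clinical-research engineers working
with small, mixed-type patient tables.

Clinical markers are a mix of continuous values (serum albumin, ICG
retention, platelet count, ...) and natively categorical findings
(portal-vein invasion +/−, liver-damage grade A/B). `hccbayes`
discretizes the continuous markers by physician-chosen cutoffs and
keeps the categorical ones as is, so a patient becomes a pattern of
*divisions* **x** = (x₁(r₁), …, x_d(r_d)) over the d selected markers.

## The decision rule

The classifier's entire fitted state is a division-count table: for
each class ωᵢ (ω₁ recurrence, ω₂ nonrecurrence), marker j and division
r, the number of training patients n_{j(r)}ⁱ falling there. For a
pattern **x**:

    P(x_{j(r_j)} | ωᵢ) = n_{j(r_j)}ⁱ / Σ_{k=1..d} n_{k(r_k)}ⁱ

— the denominator sums the counts of the divisions *this pattern*
occupies across the selected markers, so the d conditionals of a
pattern share one denominator and sum to 1 per class. Treating the
markers' divisions as independent events,

    P(x | ωᵢ) = Π_k P(x_{k(r_k)} | ωᵢ),
    P(ωᵢ | x) = P(ωᵢ) P(x | ωᵢ) / Σ_m P(ω_m) P(x | ω_m),

with equal priors P(ωᵢ) = 0.5 by default, and **x** is assigned to the
class with maximal posterior (ties go to recurrence — the costlier
class to miss). There is no iterative estimation: fitting is counting,
and discrimination is scalar arithmetic, linear in the number of
markers.

Because which markers enter the pattern matters more than how many,
the package also implements specificity-constrained marker selection:
every size-d subset of the candidate markers is scored by N stratified
half-splits of the training set into virtual training/test halves
(default N = 100), and among combinations whose mean virtual-test
specificity stays ≥ 0.5 the one with maximal mean sensitivity is the
size-d candidate; the overall optimum maximizes mean sensitivity across
sizes (ties → fewer markers). Holdout evaluation, nested-subset
learning curves, ROC operating points by marker count, a six-metric
diagnostic report (sensitivity, specificity, accuracy, Youden index,
F1, diagnostic odds ratio), and a generic summed-score staging engine
(the Tokyo Score ships as packaged config) round out the toolkit. A
reference 10-marker cutoff scheme and its 29 + 89-patient training
count table are included, along with a synthetic-cohort generator, so
everything is runnable without access to patient data.

## Worked example

Two markers: ALB (division 1 = "ALB > 3.5") and tumor burden
(number × size; division 3 = "> 9"). Reference counts: 15 and 12 in
the recurrence class (n¹ = 29), 60 and 13 in the nonrecurrence class
(n² = 89).

```python
import hccbayes as hb

counts = hb.reference_counts()
model = hb.fit(counts, (1, 2))
pattern = hb.DiscretizedPattern.from_mapping({1: 1, 2: 3})
res = hb.posterior(model, pattern)
```

prints, via `f"{res.posteriors[0]:.4f}"` etc.:

    P(x|w1) = 0.24691        # (15/27)·(12/27)
    P(x|w2) = 0.14637        # (60/73)·(13/73)
    P(w1|x) = 0.6278  ->  recurrence

The shared denominator 27 = 15 + 12 is the sum of the two division
counts of this pattern in ω₁ — not the class size 29.

Scoring the same package's Tokyo Score table for a patient with
albumin 3.0 g/dL, bilirubin 1.5 mg/dL, tumor size 1.0 cm and 4 tumors:

```python
rec = hb.PatientRecord(values={"albumin": 3.0, "bilirubin": 1.5,
                               "tumor_size": 1.0, "tumor_number": 4})
table = hb.tokyo_score_table()
hb.total_score(rec, table)          # 4   (= 1 + 1 + 0 + 2 points)
hb.diagnose(4, table)               # 'recurrence'  (cutoff 2)
```

A CLI mirrors the library: `hccbayes simulate | fit | classify |
select | evaluate | learning-curve | roc | score` (see `--help`).

## Acceptance script

`scripts/acceptance.py` re-runs the package from scratch — loading the
packaged cutoff scheme, point table and count table, materializing a
cohort and scoring the worked-example patient — and writes the
recomputed headline quantities as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model's assumptions, the synthetic-data
design and numerical choices.
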