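# Methods

## Model

`hccbayes` implements a discrete Bayes decision rule for two-class
prediction (recurrence within one year, ω₁, vs nonrecurrence, ω₂) over
categorical patterns. Each marker's range is partitioned into
mutually exclusive, jointly exhaustive divisions by fixed cutoffs; a
patient is the tuple of division indices of the d selected markers.

The per-division class-conditional probability is

    P(x_{j(r_j)} | ωᵢ) = n_{j(r_j)}ⁱ / Σ_{k=1..d} n_{k(r_k)}ⁱ,

whose denominator is **pattern-dependent**: it sums the counts of the
divisions the pattern occupies across the d selected markers, not the
class total nⁱ. This is a deliberate departure from standard naive
Bayes (which would divide by nⁱ); the d conditionals of one pattern
share a denominator and sum to exactly 1 per class, an identity the
test suite enforces. The joint conditional is the product of the d
terms (independence assumption), and the posterior follows from
Bayes' theorem. Two consequences worth knowing:

* With d = 1 the joint conditional is identically 1 for any division
  with positive count, so single-marker models carry no information
  under this rule; selection therefore starts at d ≥ 2 (default 3).
* Classification is invariant to scaling all counts of both classes by
  a common positive integer.

Assumptions: divisions of different markers are treated as independent
within each class (real liver-function markers are correlated; the
rule ignores this), cutoffs are fixed a priori by physicians and are
not optimized, and priors are equal by default so both classes are
weighted evenly regardless of cohort imbalance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| priors | (0.5, 0.5) | class priors in the posterior; equal to avoid penalizing the rarer recurrence class |
| smoothing | 0 | add-s count smoothing; 0 reproduces the raw-count rule, where a zero-count division annihilates its class's likelihood |
| tie_break | recurrence | decision on posterior ties and on degenerate (both-zero) patterns; missing a recurrence is the costlier error |
| selection N | 100 | virtual-resampling trials per combination |
| selection fraction | 0.5 | stratified virtual-split fraction; the larger half goes to virtual training on odd counts (so 29 → 15/14, 89 → 45/44) |
| specificity threshold | 0.5 | constraint on the mean virtual-test specificity; compared with a 1e-9 guard so an exact 0.50 qualifies |
| sizes | 3..M−1 | combination sizes searched among M candidates |
| learning-curve trials | 30 | independent nested-chain draws |

## Numerical choices

* Joint conditionals are computed as (Π numerators) / denominatorᵈ —
  one rounding for the denominator power — and in log space for
  d ≥ 50 to avoid underflow; at small d the two agree within 1e-12
  relative tolerance.
* Degenerate patterns (zero count mass in both classes) yield
  undefined posteriors, a set tie flag, and the tie-break decision.
* Boundary conventions follow the division labels literally: "> c" is
  strict, "≤ c"/"≥ c"/"< c" as written, and the interval "4~9" is
  closed [4, 9] because its neighbours are "< 4" and "> 9".
* Reported tables round metrics half-up to 2 decimals (Decimal
  arithmetic, not banker's rounding); raw values are always available.
  `reconstruct_confusion` inverts printed sensitivity/specificity to
  integer matrices with the same half-up convention; at test-set sizes
  28/88 this inversion is exact (verified exhaustively over all
  29 × 89 matrices).
* Records missing a value for a counted marker are dropped from that
  tally with a warning, preserving the column-sum invariant
  n_{j(1)}ⁱ + ... + n_{j(k)}ⁱ = nⁱ on the retained records.

## Marker selection

Selection scores each combination on virtual samples: N stratified
half-splits of the training set, refit on the virtual training half,
tally sensitivity/specificity on the virtual test half, average. The
virtual-split sequence is a pure function of (seed, data, fraction) and
**not** of the combination, i.e. all combinations of a search are
scored on common random numbers. This is a design choice (the
procedure's description leaves it open): it removes between-combination
Monte-Carlo noise from the comparison, makes the exhaustive search
cheap (per-trial count tables are shared across the ≤ 1000
combinations), and makes `search_per_size` exactly reproducible by
`evaluate_combination` calls with the same seed. Per-size sensitivity
ties break toward higher specificity, then lexicographic marker ids;
the overall optimum breaks sensitivity ties toward fewer markers. A
size with no combination meeting the specificity constraint yields no
candidate (rendered as dashes in the CLI table).

## Evaluation protocol

Holdout: one stratified random halving (larger half to training, so
57/177 patients give 29 + 89 training and 28 + 88 test). Learning
curves use nested training subsets realized by prefix sampling of one
per-class permutation per trial — S₁ ⊂ S₂ ⊂ … by construction —
starting at (5, 15) then (6, 17); the remaining four steps linearly
interpolate to the full training size because only the first two and
the nesting relation are fixed by the protocol, and the schedule is
fully configurable. Confidence intervals are normal-approximation 95%
over trial means by default, with a percentile alternative. ROC
points place one (1−specificity, sensitivity) operating point per
marker count — either from supplied per-size combinations or by
re-running the per-size search — plus (0,0)/(1,1) anchors. The
balanced-resampling comparison re-scores fixed test-set predictions on
100 class-balanced subsamples (all min(n₊, n₋) positives, equally many
sampled negatives) and reports means with 95% CIs.

## Scoring systems

The staging engine evaluates any table of per-marker
(condition → integer points) bands plus a diagnosis cutoff
(default: total ≥ cutoff flags possible recurrence, matching the
worked example "score 4, cutoff 2 → possible recurrence"; a strict
`gt` direction is available because printed comparisons such as
"system with 3" do not state the comparison explicitly). The packaged
Tokyo Score table is completed from the published system's semantics —
albumin/bilirubin/tumor-size bands worth 0–2 points, tumor number 0 or
2 — but only the four-marker set and the worked example's point values
(1, 1, 0, 2 → 4) are treated as fixed; the YAML is editable config.
Other staging systems (Modified JIS, TNM) are *not* reimplemented —
their internal point definitions live in their own publications — and
enter comparisons only through their printed sensitivity/specificity
via `reconstruct_confusion`.

## Synthetic cohorts

The generator draws each record's division in each marker
independently from per-class categorical vectors — the same
independence the classifier assumes — and can emit raw continuous
values uniformly inside each division's interval so discretization
round-trips. It does **not** emulate between-marker correlation,
missingness, or values concentrated near cutoffs; green tests on
synthetic cohorts establish procedural correctness, not clinical
performance. Defaults mirror the reference cohort: class sizes
29/89, and the packaged count table's frequencies where marginals are
needed. The parameter-recovery settings are one informative marker at
(0.9, 0.1) vs (0.1, 0.9) among nine uniform-noise markers for the
selection-recovery check, and all-marker separation at the same odds,
500 patients per class, for the end-to-end fit check ("well-separated
class vectors"; a single informative marker cannot exceed 0.9
sensitivity and specificity simultaneously at that effect size, since
accuracy is bounded by the marker's 0.9 purity).
`materialize_exact_counts` realizes a count table exactly by repeating
each division its count times and shuffling each marker's column
independently within class — marginals carry no joint information, so
any consistent joint is a valid realization; the one known joint datum
(7 recurrence patients in both "ALB > 3.5" and "tumor burden > 9") is
recorded as a comment in the fixture, not enforced.

## Known limitations

* The reference count table is the published training tally; the
  underlying patient records are not public, so published holdout
  performance (e.g. sensitivity 0.86 / specificity 0.49) is not
  recomputable and is consumed only as printed comparator input.
* The independence assumption is untested on real data here; with
  correlated markers the posterior is miscalibrated even when the
  decision is reasonable.
* Cutoffs are taken as given; no cutoff optimization is provided.
* The selection search is exhaustive and intended for tens of
  candidate markers, not thousands.
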