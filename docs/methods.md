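# Methods

## The stratification rule

Each of the 16 questionnaire items is assessed independently on levels
{1, 2, 3}; eleven yes/no items admit only {1, 2}, maximum activity and
exercise cardiac symptoms admit only {1, 3}, and age, BMI and medication
count admit all three. The stratum is a pure function of the level-2 and
level-3 counts (n₂, n₃): green iff n₂ = n₃ = 0; red iff n₃ ≥ 1 or n₂ ≥ 3;
orange otherwise. The red rule takes precedence over orange, so orange is
effectively n₂ ∈ {1, 2}, n₃ = 0. The admissible space of level vectors is
finite (3³ · 2¹³ = 221,184), which makes two global properties checkable by
exhaustive enumeration rather than sampling: the cascade formulation equals
the count formulation everywhere, and raising any single item's level never
moves the stratum toward green.

Interval cut points written as ranges (age "65 to 80", BMI "30 to 40",
"1 to 5" medications) are treated as closed: both endpoints take level 2.
This is the only reading consistent with the strict `<`/`>` bounds of the
neighboring levels.

**Missing answers.** The default policy is `escalate_to_level2`: a missing
item takes its lowest admissible elevated level (2, or 3 for the two items
without a level 2). Missing information therefore raises, never lowers,
the assessed risk. `error` and `treat_as_level1` are selectable. The
escalation to level 3 for the two {1, 3} items is deliberate — those items
have no milder elevated level — and makes a missing activity or
cardiac-symptom answer decisive (red), which is the conservative reading.

**Ancillary scores** are configured item sets, not hard-coded rules,
because the self-report adaptations of the source instruments are not
standardized item-by-item: modified STOP-BANG counts snoring, tiredness,
observed apnea, hypertension, BMI > 35, age > 50 and male sex (neck
circumference, the one item a patient cannot self-measure, is excluded);
modified Lee counts ischemic heart disease, heart failure, cerebrovascular
disease and insulin-treated diabetes; modified Apfel counts female sex,
nonsmoking and PONV/motion-sickness history; the APAIS anesthesia subscale
sums three of the six 1–5 Likert items (default items 1–3). The STOP-BANG
BMI and age thresholds follow the original instrument, independent of the
16-item cut points. All defaults are overridable per call.

## The synthetic cohort generator

The generator emulates the published cohort structure, not any real joint
distribution. Sampling is stratum-first: the stratum is drawn from
(0.257, 0.386, 0.357); a level vector is drawn uniformly from that
stratum's admissible set (enumerated once and cached); levels are
back-mapped to raw answers; the complication is Bernoulli with the
stratum's rate (0, 4/150, 12/139). Because the level vector determines the
stratum by construction, re-scoring a generated record recovers the true
stratum for every patient at every seed — the self-consistency property the
test suite checks at n = 5000.

Back-mapping choices: level-1 ages are piecewise-uniform across four
equal-mass bands between the configured quartiles (27/39/54) inside
[18, 65); level-2 ages uniform on [65, 80]; level-3 on [81, 95]. Level-1
BMI is the configured normal (25, 4) truncated to (10.05, 29.95) — the
pulled-in bounds keep one-decimal rounding from crossing a cut point — so
the level-1 band's empirical mean/SD match the truncated-normal moments,
not the parent's. Elevated BMI bands are uniform. The cohort-level age/BMI
marginals are therefore mixtures whose non-elevated component follows the
configured marginal; the generator cannot force both the raw marginals and
exact stratum structure simultaneously, and stratum structure wins.
Ancillary items are Bernoulli draws with plausible dependencies (observed
apnea and snoring elevated under sleep apnea; insulin use only with
diabetes; ischemic heart disease/heart failure only with cardiac disease);
APAIS Likert items are skewed low (P = .35/.25/.20/.12/.08) so the
anesthesia subscale centers near 5–6 of 15. One root generator seeded from
`CohortConfig.seed` drives all draws in fixed code order, so identical
configs serialize to identical files.

**Planted signal.** With `signal_strength` s > 0, level vectors within each
stratum are drawn with weight exp(s·d(v)), where d(v) counts how many of
four designated items (hypertension, cardiac disease, respiratory disease,
diabetes) are elevated, and the outcome log-odds shift by s·d(v). At s = 0
(default — the study-structure condition) sampling is exactly uniform and
outcomes depend on the stratum alone. The planted regime exists to give
feature selection and reclassification a recoverable ground truth: the
recovery tests use s = 3, at which red patients nearly always elevate the
designated items and other items are rarely elevated. Passing those tests
shows the machinery recovers a strong planted structure; it says nothing
about effect sizes recoverable from real questionnaire data.

**What the generator does not model:** real inter-item correlation beyond
the stratum mechanism and the planted dependencies, surgical covariates,
event times, or informative missingness (masking is independent per field
via `inject_missingness`).

## The reclassifier

Preprocessing keeps the first occurrence of a duplicated patient_id, drops
columns with missingness strictly above 0.70, one-hot encodes the two
nominal fields and leaves missing values as NaN (XGBoost routes them
natively; no imputation). Orange patients are retained in the matrix but
flagged out of training.

RFE re-splits the green/red rows 80/20 (stratified, per-step seed derived
from the root seed) at every step, fits the classifier, records train/test
accuracy, and removes the single feature with the smallest mean absolute
Shapley attribution over the training rows, ties broken by column order.
The default working classifier is 50 trees of depth 3 at learning rate
0.3; the final model is chosen by 3-fold grid search over depth {2, 3, 4},
learning rate {0.1, 0.3} and {50, 100} trees (12 combinations, accuracy
scoring) on an 80/20 split. No class reweighting is applied by default.
Reclassification thresholds the predicted red probability at 0.5.

**Attributions** use XGBoost's built-in path-dependent TreeSHAP
(`pred_contribs=True`), on the margin (log-odds) scale, with the bias term
reported as the baseline. Efficiency (baseline + Σφ = margin output) holds
to float32 precision on every row. For trees in which no root-to-leaf path
splits twice on the same feature — always the case for binary/one-hot
features, and for depth-1 stumps — these attributions equal the exact
Shapley values of the coalition game valued by the cover-weighted tree-path
conditional expectation, which the test suite verifies against exhaustive
2ⁿ enumeration at tolerance 1e-6. When a continuous feature is split
repeatedly along one path, path-dependent TreeSHAP's per-path unwinding is
known to deviate from that global-game enumeration; attributions remain
additive and efficient and are used only for ranking in RFE, so this does
not affect the pipeline, but it is the reason the exactness guarantee is
stated for the binary-feature regime.

## Evaluation conventions

Positive means red (or {red, modified red} after reclassification); the
event is any complication within 6 months. Metrics with zero denominators
are returned as explicit `None` flags. The binarized AUC is (Se + Sp)/2
identically; the ordinal AUC is the Mann–Whitney probability with ties
counted ½ (midranks), and the two coincide for binary scores to 1e-12.
Crude odds ratios use the Woolf log-scale 95 % CI; any zero cell triggers
the Haldane–Anscombe +0.5 correction and a flag (relevant in practice: a
green stratum with zero complications makes the uncorrected OR infinite).
Fisher's two-sided p is the sum of hypergeometric probabilities of tables
no more probable than the one observed; chi-square is Pearson's without
continuity correction. Percentages for table comparison round half-up to
the integer, AUC to two decimals.

A multivariate stepwise logistic regression over clinician-assigned
covariates is out of scope: it requires patient-level covariate data that
are not published, so its adjusted odds ratios are not recomputable here.

## Problem sizes

Default test and acceptance runs use cohorts of 400–5000 patients,
RFE from ~33 encoded features down to 4–10, and 10 replicates for the
stochastic recovery experiments; these sizes give stable statistics while
keeping the full suite under a minute of compute.

## Known limitations

- The generator's inter-item independence (within a stratum) understates
  real comorbidity clustering; diagnostic metrics on synthetic cohorts
  match the published ones only in expectation through the stratum rates.
- Green-vs-red discrimination on synthetic data is near-perfect because
  the label is a deterministic function of the features; published
  training/test accuracies from a real clinical database are not
  reproducible and are not targeted.
- The ancillary score item sets are declared assumptions; swap in your own
  via the `items` arguments if your instrument differs.
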