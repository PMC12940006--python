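# Methods

## The model

`cscc_bn` ships a discrete Bayesian network for a single clinical question:
given a patient with cutaneous squamous cell carcinoma (cSCC) or basal cell
carcinoma (BCC), how strongly is each of two treatment options — surgical
resection and the anti PD-1 antibody Cemiplimab — indicated?

The network has eight nodes. Six are observable roots: histology
(cSCC/BCC), the AJCC/UICC 8th-edition T, N and M categories, and the two
PD-L1 expression markers CPS (Combined Positive Score) and TPS (Tumor
Proportion Score), each binary positive/negative. Both treatment nodes
(`Surgery`, `Cemiplimab`, states `recommended`/`not_recommended`) are
children of all six roots and share no edge: each option is scored
independently, and the final recommendation is made by comparing the two
posteriors (higher wins; an exact tie goes to surgery, the conventional
primary treatment for resectable skin cancer, and is flagged as
`tie_break`). Reported probabilities are clamped to the 1–99% band used
when the tables were elicited; the model never asserts certainty.

The joint distribution factorizes node-wise into conditional probability
tables (CPTs), `P(X1..Xn) = prod_i P(Xi | Pa(Xi))`. Inference is exact:
a factor-based variable-elimination routine (min-degree order,
lexicographic tie-break, chosen purely for reproducibility — the result is
order-invariant) that the test suite holds to within 1e-10 per state of a
brute-force enumeration oracle on randomized small networks. All
arithmetic is double precision; at eight nodes log-space accumulation is
unnecessary, and the code documents 10^4 joint factor entries as the
threshold at which it would become worth revisiting. Evidence with zero
probability under the model raises `ZeroEvidenceError` rather than
returning NaNs.

### Missing PD-L1 evidence

An untested PD-L1 marker is *absent evidence*, not a third network state:
`case_to_evidence` simply omits it and inference marginalizes the marker
over its prior. This is the behavior the network family is chosen for —
partial evidence needs no imputation step — and it matters in practice,
since roughly nine of ten patients in the anchoring cohort had no PD-L1
testing.

## Parameterization

Root priors are the 66-patient cohort frequencies, stored as exact count
fractions (the printed one-decimal percentages sum to 100.1% for the T
category, so counts are the cleaner source). Two degenerate margins need
floors: N1 was never observed but is a legal category, so its prior is set
to the 1% floor with the observed categories rescaled by 0.99; CPS was
positive in all seven tested patients, so its prior is clamped to
0.99/0.01.

Treatment CPTs are authored as compact wildcard rules compiled to full
960-row tables (8 T × 5 N × 3 M × 2 × 2 × 2 parent combinations). The
most-specific matching rule wins; two equally specific conflicting rules
are a hard compile error (`AmbiguityError`), never resolved by priority
numbers, so a model file always has one auditable answer per combination.

The rule values come from per-category severity anchors:

* **Cemiplimab** combines anchors by `max` — any single sufficiently
  advanced category (large/invasive primary, heavy nodal disease, distant
  metastasis) is reason enough for systemic therapy. Anchors:
  T: 1/1/1/1/5/60/90/95% for Tx..T4b; N: 1/1/30/80/90% for Nx..N3;
  M: 1/1/95% for Mx/M0/M1.
* **Surgery** combines anchors by `min` — the least resectable category
  limits operability. Anchors: T: 95/95/95/99/90/75/65/40%;
  N: 99/99/85/70/60%; M: 99/99/20%.
* **BCC** reduces the Cemiplimab tendency by 15 points (floored at 1%);
  surgery values are shared between histologies. The immunotherapy
  indication in BCC is narrower (second-line), and no published posterior
  constrains these rows, so they are deliberately conservative.
* **CPS positive** adds 5 points to Cemiplimab (capped at 99%), only in
  very advanced disease (T4a/T4b, N3 or M1) and only for cSCC, reflecting
  the better objective response rates reported with PD-L1 expression. At
  earlier stages PD-L1 does not move the tables at all: the two published
  audit patients at T2 N0 M0 — one with unknown markers, one CPS+/TPS− —
  print identical 90/5 posteriors, which pins any PD-L1 influence at that
  stage to below rounding magnitude. TPS is carried as an observable but
  does not shift the treatment tables (CPS counts immune as well as tumor
  cells and subsumes it).

The anchors were chosen so that exact inference reproduces, after half-up
integer rounding, all ten published posteriors: the advanced worked example
(cSCC T4a N3 M0, CPS+/TPS+ → surgery 60%, Cemiplimab 95%), the early one
(cSCC T1 N0 M0, PD-L1 unknown → 99%/1%), and the three audited discordant
patients (90/5, 90/5, 70/80). Calibration is authored, not fitted: there
is no optimizer, and `cscc-bn calibrate-check` re-verifies the ten pins
plus the monotonicity ladders after any model edit. Unpinned rows
(Tx/T0/Tis, Nx, Mx, all BCC rows) are surgery-favoring defaults and should
be treated as unconstrained by any published value.

Percent output uses half-up rounding to integers because every published
posterior is an integer percent; raw decimals are available behind `--raw`
and in the `Recommendation.raw_*` fields.

## Synthetic cohorts

The 66-patient validation cohort is not public, so cohort-level machinery
is exercised on synthetic cohorts that reproduce the published *marginal*
frequencies. Fields are sampled independently — only marginals were
published, so independence is the honest default — except that PD-L1
unknown-ness (59/66) is drawn once per record and applied to CPS and TPS
jointly, because real testing yields both scores or neither. An optional
`coupling` knob upweights N2/N3 under T3+ primaries for users who want a
correlated cohort; it defaults off. All randomness flows through a single
PCG64 generator, making cohorts byte-identical across runs and platforms
for a given (spec, seed).

Treatment labels come from a policy: `stage_based` (Cemiplimab iff
T3/T4a/T4b, N2/N3 or M1), `model_based` (the model's own recommendation,
flipped per record with probability ε — cohorts whose recoverable accuracy
is 1−ε by construction), or `fixed_labels`. The closed-loop tests use
ε ∈ {0, 0.05, 0.2} at n = 2000, sized so that three binomial standard
errors give a tight but stable acceptance band.

What passing these tests shows — and does not show: they verify that the
evaluation pipeline measures what it is fed (a cohort with planted
accuracy 1−ε is measured at 1−ε) and that the generator hits its targets.
They say nothing about performance on real patients, whose T–N–M
correlations, tumor localizations and comorbidities the generator does not
model; the three published discordant patients were discordant precisely
because of such unmodeled features.

## Evaluation statistics

Confusion counts compare predicted-positive (primary recommendation by
default, or a posterior threshold) with the administered therapy.
Sensitivity, specificity, accuracy, PPV and NPV are the usual ratios;
undefined ratios (zero denominators) are carried as `None`/`"n/a"`, never
as zero. When both treatment flags are set (surgery followed by systemic
therapy after recurrence), concordance counts the first-line therapy —
surgery — and such records appear in the audit output.

The published per-node surgery statistics are internally inconsistent with
the cohort margins (a specificity of 90.1% where the margins force
multiples of 1/11, and an accuracy incompatible with 100% sensitivity at
the stated prevalence), so they are not reproduced anywhere in this
package; the Cemiplimab triple (81.8/98.2/95.5) is, via its back-solved
confusion matrix tp=9, fn=2, tn=54, fp=1.

ROC curves sweep descending score thresholds, adding one point per
distinct score; the trapezoidal AUC then equals the Mann–Whitney pairwise
concordance statistic (ties at one half) and the tests hold the two to
1e-12 against a brute-force pairwise oracle, with a scikit-learn
cross-check. The published real-cohort AUC of 90.6% cannot be recomputed
without the records and is not a test target.

## Numerical and degenerate-input choices

* CPT rows must sum to 1 within 1e-9; rule distributions likewise.
* Posterior agreement between inference routes: 1e-10 per state.
* Zero-probability evidence: loud `ZeroEvidenceError`.
* Mixed-radix row order (first parent most significant, declared state
  order) fixes the on-disk table layout bit-exactly.
* Duplicate identical rules are idempotent; conflicting ones are errors.
* Chi-square goodness-of-fit on generator marginals excludes
  zero-probability categories (N1, CPS negative), whose observed counts
  are structurally zero.

## Known limitations

* The network models exactly two options; radiotherapy, systemic
  alternatives and combination schedules are out of scope.
* No patient preferences, comorbidities or tumor localization — the very
  features that explained the published discordant cases.
* Expert-style authored tables, not learned parameters: the package
  deliberately contains no CPT fitting.
* The XDSL export is write-only and best-effort; the YAML dialect is the
  source of truth.
* Whether the original graphical model used explicit "unknown" marker
  states is not documented; this implementation commits to binary latent
  markers with marginalization, which reproduces all published posteriors.
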