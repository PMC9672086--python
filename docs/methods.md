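# Methods

## Problem and data model

One cohort row per patient: demographics (age, sex, BMI), two free-text
motivation statements (therapy aims; why online treatment), two ordinal
motivation labels on the 4-level SDT scale
(external < introjection < identification < integration), sessions
completed (0–10) plus a follow-up flag, and pre/post scores on four
instruments (BED-Q 0–35, EDE-Q global ≥ 0, MDI 0–50, VAS 0–100).
Motivation labels are *inputs* — the human coding that produces them is
out of scope. Post scores may be missing for non-completers; analyses
drop incomplete pairs pairwise and report the count in the bundle
metadata and run log.

Age strata: `young_adult` is age < 25, `adult` otherwise. The cut is a
package default (`instruments.YOUNG_ADULT_CUT`), chosen to match the
usual brain-maturation rationale for singling out young adults; it is
configurable because no universal boundary exists.

## Sentiment polarity

The scorer is a hybrid lexicon/rule algorithm in the Sentida family.
Tokenisation lower-cases, splits on non-letter characters (Danish æøå
preserved, digits and hyphenated compounds split away), and segments
sentences on terminal `.!?` runs; a sentence is interrogative iff its
terminal run contains `?`.

Rules, in order:

1. **modifier** — multiplies the next valence-bearing token in the same
   sentence by its factor (e.g. ×1.5);
2. **negation** — multiplies valence-bearing tokens among the following
   `negation_window` (default 3) tokens of the same sentence by −1,
   *unless* the sentence is interrogative (a negated question does not
   commit the writer to the negated sentiment). Stacked negators cancel
   pairwise;
3. **exclamation** — each sentence-terminating `!` (capped at 3)
   multiplies the whole sentence by `exclamation_factor` (default 1.5).

The window, factor and cap are package defaults chosen to be
conventional for this algorithm family; all are config keys on the
`Lexicon`.

Pooling is applied once per document (one patient answer). Besides sum
and arithmetic mean, the default `gmean` pooling is a **partitioned
signed geometric mean**: with P the positive adjusted valences, N the
negative ones, n the total scored count (zeros included),

    g+ = gmean(P)   (0 if P empty)
    g- = gmean(|N|) (0 if N empty)
    score = (|P| * g+ - |N| * g-) / n

Ordinary geometric averaging is undefined on zeros and negatives; this
member of the generalised family reduces to the ordinary geometric mean
on all-positive input, is sign-symmetric, treats zeros as neutral mass,
and is less outlier-driven than the sum. The choice is surfaced in the
bundle metadata as `pooling=partitioned_signed_gmean`, not hidden.
Documents with no lexicon hits score exactly 0 under every method.

## Ordinal inference chain

Motivation types are an ordered sequence, so each grouped variable is
tested for an ordered alternative rather than any-difference.

**Jonckheere–Terpstra.** Raw statistic J = Σ_{i<j} U_ij over ordered
group pairs, U the Mann–Whitney count with ties worth 0.5. The signed
z = (J − μ)/σ uses the standard tie-corrected null variance; positive z
means ascending. p-values are two-sided (the study reports both
ascending and descending alternatives); the normal-approximation tail
applies a half-lattice-step continuity correction (J moves on a lattice
of step 1, or 0.5 with ties), which brings it within ~0.01 of the
permutation p for balanced groups of 15. `method="permutation"`
relabels observations across groups with sizes fixed; when the number
of distinct arrangements is ≤ 10⁵ the enumeration is exhaustive and the
p exact. An all-constant input returns z = 0, p = 1.

**Brown–Forsythe** is scipy's Levene test with median centering
(df1 = k−1, df2 = n−k). When p > 0.05 the groups are treated as
homoscedastic and the mean-rank ordering statement extends to group
medians (`medians_extend` on the verdict). The all-equal-deviations
degenerate case returns F = 0, p = 1 rather than 0/0.

**Kendall τ_B** (scipy point estimate) is the effect size; ties are
heavy by construction (4-level grouping variable), hence the b variant.
The 95% CI is a seeded percentile bootstrap over (x, y) pairs, default
B = 2000. Internally a resample is represented by its multinomial count
vector c, and both C − D and the tie counts are quadratic forms cᵀMc in
precomputed pairwise sign matrices, so the whole bootstrap is three
BLAS products; tests verify agreement with direct pairwise resampling
and the point estimate against an O(n²) brute-force pair classifier.
All-tied margins yield an explicit degenerate result, never a number.

**Dual significance rule.** A grouping is `overall` significant only if
(1) p(T_JT) ≤ 0.05 and (2) the effect passes: |τ_B| > RMPE = 0.2 and
the CI does not reach both −0.2 and +0.2 (otherwise an inversely signed
association of practical size remains plausible). Stars count the
ladder thresholds 0.2/0.5/0.8 strictly exceeded. Note the rule does
*not* require the CI to exclude zero — it mirrors the study's reporting
convention exactly, which matters for the false-positive arithmetic
below.

**Mixed ANOVA.** Pre/post outcomes get a two-way mixed ANOVA (time
within-subject, motivation group between). With two timepoints the
interaction test is algebraically a one-way ANOVA on change scores;
the classical decomposition is implemented directly with
numDF = k−1, denDF = n−k, and cross-checked against pingouin and
scipy's `f_oneway` in the tests. The source study prints denominator
dfs (774, 618) that cannot arise from 148 subjects × 2 timepoints under
any classical decomposition; this implementation follows the classical
formula and does not imitate them. Degenerate zero-variance inputs
return F = 0, p = 1 (no signal) or F = ∞, p = 0 (signal with zero
error).

**Normality.** Shapiro–Wilk plus detrended QQ deviations (ordered
sample minus fitted normal quantiles at Blom positions) are computed
per cell and reported in the bundle metadata. Following the study's
argument that ANOVA is robust to non-normality at this n, the check
annotates and never gates.

No multiple-testing correction is applied anywhere — the study applies
none — so the pipeline reports raw p-values and records the family size
in the bundle metadata. Consequence, quantified on null synthetic
cohorts: the 19-subject young-adult stratum contributes ~18 grid cells
whose joint per-cell false-positive rate under the dual rule is ≈ 4–5%,
so roughly half of all null *runs* show at least one spuriously
significant young-adult cell. This is a property of raw-p reporting at
this grid size, not of the implementation; consumers comparing many
cells should apply their own correction.

## Synthetic cohort generator

The generator emulates the study conditions; defaults are frozen, not
tuning knobs:

* n = 148, 19 young adults, 17/148 male;
* motivation labels drawn per question from the printed distributions —
  therapy aims proportional to (0, 50, 50, 48) (the external level is
  absent there: screening excluded purely externally regulated
  applicants), why-online proportional to (31, 21, 81, 15);
* latent polarity = baseline + link × level + N(0, 1), the simplest
  monotone (linear) link consistent with ordered-alternative testing.
  The default link 0.61 was fixed by `calibrate_polarity_link`, which
  bisects the link against the population τ_B between gmean-scored
  statements and therapy-aims level measured on a 20 000-statement
  probe, targeting τ_B = 0.31; at n = 148 the bootstrap CI covers that
  population value in ~95% of cohorts;
* statements are token streams from a seeded synthetic lexicon (≥ 240
  valence words gridded over [−5, 5], disjoint modifier/negator/filler
  classes): valence tokens target N(latent, 1.5) quantised to the
  nearest lexicon word, fillers at rate 0.3, and at rate 0.1 a negator
  followed by the token nearest the *negated* target (the rule engine's
  flip restores the intended contribution; fillers pad the negation
  window so the flip never bleeds). Mean-scored polarity correlates
  with the latent at r ≳ 0.95. No linguistic fluency is attempted;
* pre outcomes are truncated normals inside instrument ranges — BED-Q
  mean 16 sd 3 on [10, 21] (mild–moderate band, eligible by
  construction), MDI mean 23 sd 8 on [2, 40], EDE-Q mean 3.5 sd 1,
  VAS mean 50 sd 15, BMI mean 37.5 sd 6. The study prints only the MDI
  mean and ranges; dispersions are chosen for testability and labelled
  as such in `groundtruth.json`;
* post = pre − treatment_effect + motivation_outcome_effect × level +
  noise, clipped to the instrument range; the default motivation effect
  is **zero** (the study's null), and ~20% of low completers lose their
  post scores;
* adherence: a standard-normal propensity mapped to sessions with mass
  ≈ 0.37/0.38/0.25 over Low/High/Full; for young adults only, the
  propensity is shifted by `young_adherence_link` × standardised
  why-online polarity. The link is a latent regression coefficient;
  the default −0.5 makes the realised young-adult τ_B between polarity
  and completion ≈ −0.31, and its sign is recovered in ~95% of cohorts.

Everything is deterministic per seed, and emitted CSVs re-parse through
the cohort reader with zero validation errors.

What passing tests on this generator do **not** show: anything about
real Danish prose (sarcasm, idiom, spelling), about the validity of the
human motivation coding, or about the true dispersions of the clinical
instruments. The generator demonstrates that *if* data have the assumed
structure, the pipeline recovers it at the configured sizes.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use sizes chosen to keep the whole
suite a few minutes on one core while leaving the Monte-Carlo error
well inside the asserted bands: 2000 replicates for type-I error checks
(3σ band ±0.015 around 0.05), 20 000 permutations for p-agreement
checks, 200 cohorts for CI coverage, 60 runs for the null-pipeline
check. Bootstrap draws that are degenerate (all-tied margin) are
dropped from the percentile computation. Per-cell seeds are derived
from the run seed and the cell identity (CRC32), so results are
reproducible cell-by-cell and independent of iteration order. p-values
below 10⁻³ are formatted in scientific notation in the CSV grids; the
JSON bundle keeps full precision.

## Known limitations

* The gmean pooling is one documented member of the generalised
  geometric-averaging family; other members (e.g. log-shift variants)
  would give different magnitudes, though the same signs.
* The bootstrap CI is percentile-only; BCa would be preferable near
  |τ| → 1 but is irrelevant at the effect sizes here.
* `completion_rate` enters correlations as the ordinal code
  Low = 0 < High = 1 < Full = 2; polarity-vs-outcome correlations are
  computed against both pre scores and post − pre differentials
  (negative differential = improvement), with neither privileged.
* With only two timepoints the mixed ANOVA cannot separate compound
  symmetry violations; sphericity is trivially satisfied.
* The young-adult stratum (n = 19) yields wide CIs and the raw-p
  multiplicity behaviour quantified above.
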