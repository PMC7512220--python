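# Methods

This note documents the statistical procedures implemented in `swathms`, the
choices made where the analysis design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Quantification

**Rollup.** A protein's intensity in a run is the sum of the selected
fragment-ion intensities: the 6 strongest fragments of each of the 10
strongest peptides. "Strength" is the intensity summed across *all* runs,
computed once per protein, so the same feature set quantifies every run;
per-run selection would make columns incomparable. Ties in strength are
broken lexicographically on the feature identifier so the selection is
deterministic. A fragment unobserved in a run contributes zero — in
extraction-based DIA quantification the absence of a matched peak is a zero
measured intensity, not a missing value; this zero-fill policy is the main
sensitivity point of the rollup and is deliberately explicit.

**Normalization.** Each run (column) is rescaled so its total equals the
mean of all run totals. The mean-total target (rather than 1) keeps
intensities on their original scale; any positive constant is equivalent
downstream. Within-run ratios are preserved exactly. Note the compositional
consequence shared by all total-sum schemes: planted (or real) abundance
increases in one group induce a small opposite shift in every *other*
protein of that group. It is negligible when differential proteins are a
small fraction of total signal (the realistic regime) but material if a
large share of the proteome is perturbed in one direction.

**Replicate averaging.** Technical replicates are combined by arithmetic
mean per protein, producing one column per subject; all statistics run on
this averaged matrix.

## Differential abundance

Per protein, a two-sided two-sample pooled-variance Student's *t*-test.
The test is computed on **log10-transformed** averaged intensities by
default: MS intensities are approximately log-normal and the companion
effect size is defined in log10 units. The untransformed variant is
available (`log_transform=False`) for sensitivity analysis, since the
originating software's scale is not documented; likewise pooled variance is
the default reading of "Student's t test". The effect size is
`log10(mean_case / mean_control)` computed on the intensity scale (not the
mean of logs), matching how fold-changes accompany such tables.

Filters use strict inequalities throughout: stringent `P < 0.01` and
`log10FC > 0.2 or < −0.2`; relaxed `P < 0.05` and fold-change `> 1.3 or
< 0.75`. No multiple-testing correction is applied in the primary path —
the filter grammar operates on raw p-values by design — but
Benjamini–Hochberg q-values are emitted as an informational column.
Proteins with a non-positive group mean or non-finite log intensities get
NaN statistics and a warning rather than aborting the table.

Report files round p to 2 significant figures and effects to 2 decimals,
which is why the packaged fixture tables are filtered on the fold-change
column (3 significant figures) rather than the 2-decimal printed log10
column: a true log10FC of 0.2014 prints as 0.20 and would wrongly fail a
strict `> 0.2` gate. The fixture verifier compares the two printed columns
as intervals at their printed precision (±half a last digit) with an 0.02
roundtrip tolerance.

## Stratification

**Sqrt/Pareto PCA.** Intensities are square-root transformed, then each
protein is mean-centred and divided by the square root of its standard
deviation (Pareto scaling — the standard compromise between no scaling and
unit variance for MS data; scaled variables have variance equal to their
original sd). The decomposition is a singular value decomposition of the
resulting subject × protein matrix; explained percentages are of total
transformed-scaled variance. Zero-variance proteins cannot be Pareto-scaled
and are dropped from the decomposition (with a warning), which leaves the
model identical to one fitted without them. The sign convention makes the
largest-magnitude loading of each component positive, so scores are
reproducible across runs and platforms. Held-out subjects are projected
using the training transform, centre, scale and loadings.

**Subgroup selection.** The published analyses of such cohorts select the
separating case subgroup by visual inspection of the score plot; the package
replaces this with an algorithmic rule recorded in `method_record`:
a two-means partition of the scores on chosen components (PC1/PC2 by
default). Lloyd iterations are restarted from **every distinct sample
pair** as initial centroids and the partition with minimal within-cluster
sum of squares is kept. Single-start Lloyd — including starts at the
extreme scores of one chosen component — proved sensitive to which
component carries the separation and to outlying samples; with ~20 subjects
the all-pairs restart is essentially an exact, fully deterministic optimiser
of the 2-means objective at negligible cost. The cluster holding the
majority of controls is labelled control-like; cases inside it are the
excluded set. A mean silhouette width below 0.5 flags the partition as
unstable (forced splits of unstructured score clouds typically land near
0.3, while genuinely separated cohorts exceed 0.5 comfortably), in which
case the excluded set should not be interpreted.

## Classification and permutation test

Logistic regression on the first k = 3 principal-component scores,
leave-one-out cross-validated, decision threshold 0.5. Two PCA policies are
first-class because the original wording does not say whether the PCA was
refitted within folds:

* `refit_per_fold` (default): PCA refitted on each training fold, the
  held-out subject projected through the training transform — no
  information leakage;
* `global`: PCA fitted once on all subjects, only the regression refitted
  per fold.

The regression always carries a fixed small L2 penalty (α = 0.1, i.e.
scikit-learn `C = 10`) rather than only under detected separation, so
per-fold models are comparable — 19-subject training folds separate
frequently. The fit is a damped-Newton optimiser of exactly that penalised
likelihood (intercept unpenalised); it matches scikit-learn's estimates to
~1e-8 (asserted in the tests) and exists because the resampling tests below
refit this 3-coefficient model tens of thousands of times. If a panel
restricts the matrix below k proteins, k is capped at the available rank.

The permutation test shuffles group labels over subjects (preserving group
sizes) and reruns the full LOOCV; "more extreme" means a null error count
less than or equal to the observed one. When the number of distinct label
arrangements is at most 20 000 they are enumerated exhaustively and the
p-value is exact; otherwise `n_permutations` (default 2000) random shuffles
are drawn and the +1-smoothed estimate
`(1 + #{null ≤ observed}) / (n_permutations + 1)` is reported. Because the
PCA in either policy does not depend on labels, per-fold score
decompositions are computed once and reused across permutations.

## Panel specificity

The LOOCV error of the classifier restricted to a flagged panel is compared
with the error distribution over panels of the same size drawn uniformly
without replacement from the *non-flagged* proteins (a switch allows
drawing from all proteins). The comparison statistic is the error count —
the classifier's reported performance measure — with mean held-out log-loss
reported alongside as a tie-aware secondary statistic. The empirical p is
+1-smoothed like the permutation p. Default 500 draws.

## Synthetic cohorts

The generator emulates the study design: 11 cases and 9 controls in
technical triplicate, with 9 of the 11 cases carrying the planted signal
(the remaining two are drawn from the control distribution, reproducing the
score-plot geometry in which a case minority co-clusters with controls).
Baseline abundances are drawn in log10 (protein sd 0.8, peptide sd 0.5,
fragment sd 0.35), giving the long-tailed linear-scale intensities that
make top-N feature selection non-trivial.

Parameters, defaults, and why:

| parameter | default | meaning |
| --- | --- | --- |
| `n_cases` / `n_controls` / `n_subgroup_cases` | 11 / 9 / 9 | study design |
| `n_replicates` | 3 | technical triplicates |
| `n_proteins` | 2970 | quantified proteome size of the motivating study |
| `n_de_proteins` | 99 | planted differential proteins |
| `effect_log10fc` | (0.2, 0.5) | planted \|log10FC\| range, uniform |
| `frac_up` | 47/99 | fraction of planted increases |
| `noise_cv` | 0.20 | per-(protein, subject) biological CV, shared by a subject's replicates |
| `replicate_cv` | 0.10 | per-fragment-per-run technical CV |
| `run_depth_factor_sd` | 0.15 | sd (log10) of the per-run depth factor that normalization must remove |
| `missing_rate` | 0.05 | probability a fragment is an absent row in a run |

The noise levels are not stated by the motivating study; they were chosen
once as typical for SWATH-type data (technical CVs near 10 %, biological
CVs near 20 %, a few percent missingness) and are not tuned. One seed
drives all randomness through one stream split per generation stage, so a
configuration reproduces byte-identically.

What the generator does **not** emulate: identification dropout between
spectral library and quantification, retention-time or m/z structure,
correlated protein modules (planted effects are independent across
proteins), interference/chimeric signals, or intensity-dependent
missingness. Consequently, passing tests demonstrate the pipeline's
statistical behaviour under its own model — calibration, recovery,
specificity — not performance on the idiosyncrasies of real DIA data.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations run at desk scale as the
package's own default study sizes for verification: cohorts of 40–1500
proteins (the study design otherwise unchanged), 100 seeded cohorts for
subgroup recovery, 60–2000 permutations, 40–200 random panels. Full-scale
cohorts (2970 proteins) generate in seconds but are unnecessary for the
properties being checked, which concern rates and calibration rather than
absolute proteome size.

Numerical details: normalization requires strictly positive run totals and
raises naming the degenerate run; equal group means report an effect of
exactly 0; the t-statistic with zero pooled variance maps to p = 1 (equal
means) or p = 0 (unequal); PCA reconstruction with all components is exact
to ≤ 1e-8 relative; two-means distance ties assign to cluster 0 and
equal-objective partitions keep the first in deterministic pair order;
drawn panels are sorted so draw order cannot perturb the decomposition
numerically; permutation and panel p-values are never 0 by construction.

## Known limitations

* The zero-fill policy for unobserved fragments biases low-abundance
  proteins downward in sparse runs; a re-extraction step upstream would be
  the principled fix and is out of scope.
* Total-sum normalization's compositional coupling (above) can leak a small
  group effect into every protein when many planted effects share a sign.
* The silhouette stability threshold (0.5) is a heuristic banding, not a
  test with a null distribution.
* The permutation test reuses label-independent fold decompositions; if a
  future PCA policy depended on labels, that optimisation would no longer
  be valid and would need to be disabled.
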