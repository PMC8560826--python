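# Methods

This note records the models, conventions and numerical choices behind
`alrpls`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Compositional transforms

Counts are closed to relative abundances per sample. The additive
log-ratio (alr) of feature *j* is `ln(x_j) - ln(x_ref)` (natural log
throughout); the reference column is removed, leaving J-1 coordinates.
The alr is invariant to positive row rescaling and subcompositionally
coherent: removing features not involved in a ratio and re-closing leaves
that ratio unchanged (tested to 1e-12). The inverse appends a zero column
and applies a softmax closure; the round trip reproduces the relative
table to 1e-10.

"The geometry of the full set of ratios" is represented by centered
log-ratio (clr) coordinates: the Euclidean geometry of clr rows equals
the all-pairs log-ratio (Aitchison) geometry up to a 1/sqrt(J) scale,
which the tests verify by brute force for J <= 8. This avoids
materializing J(J-1)/2 ratios at realistic J.

### Procrustes correlation

Both configurations are centered and scaled to unit Frobenius norm; the
second is optimally rotated/reflected and isotropically scaled onto the
first. With the minimized normalized residual m², the correlation is
sqrt(1 - m²), which reduces to the sum of singular values of the
cross-product of the normalized configurations. Configurations with more
columns than rows are first projected onto principal axes retaining
99.9% of variance (rigid-motion invariant, so the correlation is
unchanged at the reported precision). The value is 1 exactly under
similarity transforms; an independent SVD-based oracle cross-checks the
closed form in the tests.

### Reference search

Every feature is scored on four criteria: Procrustes correlation of its
alr configuration against the clr geometry; variance (and CV, defined as
100·sd/|mean| of ln relative abundance); Pearson correlation of its
relative abundance with the trait, with the large-sample SE
sqrt((1-r²)/(n-2)); and mean relative abundance. Selection filters on
Procrustes >= 0.99 and |r| <= 2·SE, ranks survivors by ascending log
variance and breaks ties by descending abundance. The trait filter uses
the 2·SE band rather than a p-value to match the +-SE reporting style of
the diagnostic values. When no candidate passes (the error advises
relaxation), the pipeline retries with the trait filter waived — the
geometry and stability criteria are the load-bearing ones.

The search is exhaustive over all features by default. Per-candidate cost
is kept to one small SVD by projecting each alr configuration into the
clr row space (n-dimensional), so a full scan of 500 candidates at n = 90
takes ~2 s.

## PLS engine

Single-response NIPALS PLS1. Columns are mean-centered and scaled to unit
variance (dropping constant columns); the response is centered.
Discriminant analysis codes the two classes +1/-1 (obese = +1 when the
labels are obese/lean) and assigns by the nearest code, i.e. the sign of
the prediction; with this coding the coefficient vector is identical to
the regression fit on the dummy. Deflation makes score vectors mutually
orthogonal; at full rank the fit coincides with ordinary least squares.

- **Component choice.** 7-fold cross-validation; folds are stratified by
  class in discriminant mode and fully determined by (n, folds, seed),
  so every stage of a run reuses identical folds. Components are added
  while the cumulative Q² = 1 - PRESS/TSS (PRESS pooled over held-out
  predictions, TSS about the overall mean) gains at least
  `eps_comp = 0.01`; at least one component is always kept, and the
  search stops after two consecutive non-improving components.
- **VIP.** `VIP_j = sqrt(J' * sum_a[SSY_a (w_ja/||w_a||)²] / sum_a SSY_a)`
  with SSY_a = q_a² t_a't_a; mean squared VIP is exactly 1.
- **Jackknife CIs.** Delete-a-group over the CV segments: refit without
  each fold, `SE_j = sqrt((G-1)/G * sum_g (b_j^(g) - b̄_j)²)`, interval
  `b_full ± t_{G-1,0.975}·SE`. Coefficients are expressed in raw X units
  so refits with different autoscaling factors are comparable — in
  scaled units the per-fold coefficients would differ even for an exact
  linear relation.
- **DMOD.** Per-sample residual SD after A components, normalized by the
  pooled residual SD; a sample is flagged when its squared normalized
  distance exceeds the F(J'-A, (n-A-1)(J'-A)) quantile at alpha = 0.05.
  The normalization and cutoff follow the common chemometrics
  convention; the exact constants in proprietary implementations are
  unpublished, and equivalence is not claimed. Residuals at numerical
  noise level short-circuit to "no outliers".
- **Permutation test.** Statistic = cross-validated Q² at fixed A;
  p = (1 + #{Q²_perm >= Q²_obs}) / (1 + n_perm), so p is bounded below
  by 1/(n_perm+1); at least 19 permutations are required.

## Iterative variable selection

Each iteration: choose A by cross-validation, fit, mark features with
VIP > 0.8 **or** a jackknife CI excluding zero, and drop a batch of
unmarked features (lowest VIP first, at most `batch_frac = 0.2` of the
current set). A step is accepted if the prediction ability — Q² in
regression, cross-validated misclassification (with Q² breaking exact
ties) in discriminant mode — does not degrade by more than
`eps_stop = 0.005`; otherwise the batch is halved and retried, falling
back to trying each single unmarked removal, and the loop stops when no
single removal survives. When every remaining feature is marked, the
stopping rule is still exercised by trying to remove the single least
important feature. Marked features are otherwise never removed: with a
continuous ability metric, CV jitter would otherwise let uninformative
coalitions displace genuine drivers. Batching makes the procedure
tractable at thousands of features; one-at-a-time behavior is available
by setting `batch_frac` small.

Fold assignment is computed once per run (stratified by line) and shared
by the discriminant and regression loops, so the intersection of their
final sets compares like with like, and re-evaluating the final feature
set reproduces the recorded ability exactly.

The selection-then-evaluation scheme shares folds between selection and
the reported Q², as the original procedure does; the reported ability is
therefore optimistically biased and should be read as a model summary,
not an unbiased generalization estimate.

## Bayesian line contrasts

Under a normal linear model with a single two-level line effect and flat
priors, the marginal posterior of the mean difference is Student-t with
location = difference of group means, scale = s_p·sqrt(1/n1+1/n2),
df = n1+n2-2. The 95% HPD equals the equal-tail interval (the t is
symmetric and unimodal). P0 is the posterior mass on the sign of the
location, equal to 1 - p/2 with p the two-sided equal-variance t-test
p-value — verified numerically, and against a seeded Monte-Carlo sampler
of the same joint posterior (sigma² from a scaled inverse-chi-square,
difference normal given sigma²). Differences are standardized by the
feature's **overall** sample SD (not the pooled within-group SD): "units
of SD" is read in the reporting convention where the SD includes the
between-group spread; the pooled alternative is available via
`sd_scope="pooled"`. No multiplicity adjustment is applied, matching the
upstream procedure; under the null, P0 is uniform on (0.5, 1), so ~10%
of null features exceed 0.95 by construction.

## Dual-trait specificity

Feature sets from two analyses are partitioned exactly (shared /
a-specific / b-specific). Cross-prediction fits PLS of the *other* trait
on one trait's specific features; "no predictive component" is declared
when the first component's cross-validated Q² is below `eps_comp` — the
same threshold that gates component entry, so one rule decides
"predictive" everywhere. The reported Q² is at the CV-chosen component
count.

## Synthetic-data generator

The generator emulates a two-line divergent-selection functional
metagenome at desk scale (defaults: 45 samples/line, J = 500 features,
depth ~50,000 reads; the study-scale shape of ~4,000 features, ~4M reads
is reachable through the same config):

- **Baseline.** Feature log abundances are Gaussian: means N(0, 1.6) —
  the realized min-max abundance span over hundreds of features is about
  four orders of magnitude, with the top feature holding a few percent of
  reads — and per-feature SDs uniform on (0.3, 0.8).
- **Stable feature.** One high-abundance feature (target relative
  abundance 5.6x the mean feature's, the ratio of the reported
  housekeeping exemplar) is given a *constant* log-abundance level plus
  small noise. Holding the level constant keeps every log ratio against
  it free of a shared log-total term (a housekeeping gene scales with
  biomass); its observed relative abundance then varies only through
  total fluctuation, counting noise, and the planted jitter, which is
  budgeted so the empirical CV of its log relative abundance hits the
  target (default 0.01, matching the reported reference variance of
  ~0.002) whenever the noise floor allows. At desk scale the floor
  (counting noise at depth 50k plus total fluctuation at J = 500)
  dominates and the realized CV is ~2x the target; at study-like scale
  the target is met (tested).
- **Line effects.** A subset of features is shifted between lines.
  Effects are stated in the *observed overall SD* of the feature's log
  abundance — the convention in which between-line differences are
  reported (the observed range in the motivating study is about -0.75 to
  +0.73 SD; the default "strong signal" range here is 0.5-1.0). The
  latent shift inverts the overall-SD inflation caused by the separation
  itself and budgets the feature's multinomial counting noise, which
  dominates the observed SD for rare features.
- **Traits.** Intramuscular fat and body-fat percentage are linear
  combinations of the *true* alr values (w.r.t. the stable feature) of
  their driver sets, built on SD-standardized driver alrs so every
  driver carries its nominal weight (U(0.5, 1)); the combination is
  standardized to unit SD and Gaussian noise with sd 0.5 is added,
  anchoring the achievable Q² near 0.8 — the magnitude reported for the
  final trait model. For drivers that also carry a line effect, the
  weight sign follows the effect sign: under divergent selection a
  feature responds to the line *because* it pushes the trait, so the two
  move together (this is what makes a correlated-response design
  informative); without the alignment the line component of the trait
  cancels across drivers and most of them become statistically
  undetectable at n = 90. By default the IMF drivers coincide with the
  line-affected set (`line_driver_overlap`), and half the body-fat
  drivers are shared with IMF; specificity experiments set both to
  disjoint. Traits are reported on realistic measurement scales
  (IMF 1.5 ± 0.4 g/100 g; body fat 12 ± 2.5%).
- **Counts.** Multinomial per sample at a depth drawn around
  `depth_mean` with floor `depth_min` (default 50k/25k, emulating the
  4M/2M read design at desk scale). Zero counts are replaced by 1 and
  logged, preserving the core property by construction.

What the generator does **not** emulate: taxonomic or functional
annotation structure, correlation blocks among features (drivers are
independent dimensions), overdispersion beyond multinomial sampling,
batch or sequencing-center effects, and zero-inflation (the core table
has none by definition). A green recovery test therefore establishes
that the chain works under the stated compositional and noise structure,
not that it is robust to real-data pathologies outside it.

## Degenerate inputs and tie-breaks

Zero-sum rows and non-positive entries are rejected with the offending
sample/feature named. Constant columns are dropped (with tolerance
1e-12 relative) before scaling. Duplicated columns are legal — NIPALS
handles collinearity; VIP splits importance between copies. Constant
traits flag the trait-correlation criterion as unavailable rather than
failing. Ranking ties in the reference search break by abundance;
removal order ties in the selection loop break by stable sort.

## Limitations

- The selection loop is greedy and seed-dependent; different fold draws
  give different (overlapping) final sets, as with any CV-driven
  selection at n << J.
- P0 and the HPD are exact only under the flat-prior normal model;
  heavy-tailed alr distributions would need a robust likelihood.
- The DMOD cutoff is a convention, not a calibrated test; at n = 90 and
  alpha = 0.05 occasional false flags are expected and logged.
- Desk-scale acceptance experiments run the chain at J = 500 rather than
  the study's ~4,000 features to keep the suite within minutes;
  structure, not scale, is what the assertions exercise.
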