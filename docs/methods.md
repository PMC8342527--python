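# Methods

## Scope and data model

The package analyses subject-by-variable tables at one or two timepoints.
Variables are continuous measurements or declared-level questionnaire items
(binary / ordinal / nominal); missing values are kept as a cell-level mask so
every analysis uses its own complete subset (per-analysis exclusion), never
global listwise deletion.  The file dialect is fixed — comma-separated UTF-8
with a `subject_id` column, continuous values at six decimals — so that
repeated runs are byte-comparable.  Timepoint labels are opaque strings; the
package never does date arithmetic.

## Quantifying drinking exposure

Weekly ethanol grams = (volume-band mean, g/day) × (frequency-band mean,
days/week).  Band means are configuration; the defaults use arithmetic
midpoints of closed bands, and an open-ended top band uses its lower edge
plus half the preceding band's width (e.g. "> 60 g/day" → 70).  A frequency
of "never" forces zero grams regardless of the volume answer.  Categories
partition [0, ∞) with lower-open, upper-closed bands:

| category | weekly grams |
|---|---|
| never | 0 |
| light | (0, 100] |
| moderate | (100, 350] |
| heavy | > 350 |

The 350 g/week heavy cutoff follows the convention that "more than 350 g
per week" is heavy drinking; the 100 g/week light/moderate cutoff matches
the binning used for longitudinal change reporting.  Both are overridable,
as questionnaire band edges differ between checkup programmes.

For the correlation screen, answers are encoded numerically: binary → 0/1
by declared level order, ordinal → its `numeric_map` if supplied (e.g. band
means) else the 1-based level rank, continuous → itself.  Nominal
multi-level items without a numeric map are rejected rather than silently
ordered.

## The association screen

Pearson product-moment correlations are computed over pairwise-complete
subjects (`pandas` with a minimum pair count, default 30; under-sampled or
zero-variance entries are flagged unavailable, not raised).  For a
categorical exposure against a continuous outcome the screen also reports
the correlation ratio η = √(SS_between / SS_total), the effect size of a
one-way ANOVA across answer levels.  η is reported unsigned — it has no
natural sign — and equals |r| exactly when the grouping is binary, which the
test suite uses as an internal cross-check.  No p-values or multiplicity
corrections are attached to the screen: the elimination step below is the
filter.

## PCIT edge elimination

For each unordered pair (x, y) and every third variable z:

    r_xy.z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))   (and rotations)
    ε      = (r_xy.z/r_xy + r_xz.y/r_xz + r_yz.x/r_yz) / 3
    discard x–y  ⇔  |r_xy| ≤ |ε r_xz|  and  |r_xy| ≤ |ε r_yz|

An edge must survive **all** p − 2 trios to be significant; any single z
suffices to remove it, and the first discarding z in variable order is
recorded.  Note that the rule is a *relative* tolerance: a trio with flanks
0.5 and direct 0.25 (pure confounding) discards the pair, while flanks 0.9
with direct 0.81 keeps it, because ε shrinks as the trio strengthens.

Numerical policy (the printed formulas have no guards): direct correlations
with |r| < 1e−12 are clamped to 1e−12 with sign preserved wherever they
appear as ratio denominators, and 1 − r² is clamped below at 1e−12.  Since
the discard comparison is against |ε·r|, a true-zero flank still cannot
remove a non-zero edge.  The comparison itself uses `<=` at double
precision with no tolerance; boundary ties are measure-zero on sampled
correlation matrices.  Variables with unavailable matrix entries are dropped
(logged) before elimination, since their trios cannot be evaluated;
per-entry sample sizes are carried alongside, and the matrix is otherwise
used as-is even when entries have unequal n.

The production implementation vectorizes over pairs for each z (O(p³), no
pruning — intended for tens to hundreds of variables).  A literal scalar
triple-loop transcription (`pcit_brute_oracle`) exists purely as an
independent reference; the suite checks verdict-level identity on hundreds
of sampled matrices.

## Network construction

Significant edges are ordered by |r| descending (ties broken
lexicographically on the canonical pair), a user-supplied exclusion list of
well-established correlations is removed *first*, and the top K (default
250) are retained — so an excluded pair frees a slot for the next-ranked
association.  The exclusion list is editorial by design, not algorithmic.
Export is an undirected Graphviz DOT file: sorted node statements, edges in
rank order, weight as |r| at four decimals with the sign as a separate
attribute — byte-identical across runs for equal input.

## Longitudinal change–change testing

Per-subject deltas are follow-up minus baseline; subjects missing either
value are dropped and counted.  For exposure deltas x and outcome deltas y:

    R  = Pearson correlation of (x, y)        df = n − 2
    t  = |R| · sqrt(df) / sqrt(1 − R²)
    p  = two-tailed tail probability of t under the t(df) distribution
    significant  ⇔  p < 0.05  and  |R| > 0.05

The t statistic is the standard correlation t-test written with an absolute
value (the source convention pairs it with a two-tailed lookup, which is the
unique consistent reading).  The |R| > 0.05 floor acknowledges that at
registry sample sizes (n ≈ 1765–6036) nominal significance alone admits
negligible effects.  Both thresholds are overridable.  Trend lines are
ordinary least squares of outcome delta on exposure delta.  Stratified
re-runs (by sex, by unchanged drinking category, or any deterministic
predicate over the paired subjects) apply the same machinery to the
surviving subjects and refuse strata with n < 4.  Exposure deltas use
continuous weekly grams by default; a descriptive binning (no change /
< 100 / ≥ 100 g per week) is provided for summary tables only.

## Synthetic cohort generator

One Gaussian latent per variable; the latent correlation matrix is
assembled from planted direct edges and confounder fans (source s with
strengths a to t1 and b to t2 induces the indirect correlation a·b on
(t1, t2) when that pair has no direct edge), then verified positive
definite by Cholesky before any sampling.  Marginals: thresholded step
functions for sex, smoking status and the drinking ladder; linear maps for
the continuous measurements (floored at small physiological minima, e.g.
FVC ≥ 0.5 L, affecting < 0.1 % of draws); a lognormal for CRP.  The
FEV1/FVC ratio is computed, not latent.

**Observed-scale calibration.**  A monotone transform f of a standard
normal attenuates Pearson correlation with any linear counterpart by
exactly c = corr(f(Z), Z) (the ratio of f's first Hermite coefficient to
its standard deviation), which has a closed form for step functions and the
lognormal.  Correlation targets are therefore stated on the observed scale
and each latent entry pre-inflated by 1/(c_i·c_j).  The calibration is
exact when at most one endpoint is transformed; for transformed–transformed
pairs (e.g. smoking × alcohol) the product rule is the leading-order
approximation, adequate at the default strengths (|r| ≤ 0.3) and covered by
the 0.02-tolerance calibration tests.  Infeasible targets (|latent| ≥ 1 or
a non-positive-definite joint matrix) fail before sampling.

**The drinking ladder.**  Alcohol is emitted as a (volume band, frequency
band) answer pair, the exact product grams, and the category — so the
quantification step is idempotent on simulated data.  The never mass sits
on the (none, never) rung; each category's mixture mass is split equally
over the answer combinations whose grams fall in its band (the per-category
means this induces are a modelling choice; the source bands themselves are
configuration).  Default mixtures: drinking 26.4/28.5/36.0/8.7 %
(normalized), smoking never/previous/current 49.5/39.1/10.6 %, 61.2 % male,
age 60 (SD 13), FVC 3.60 (SD 0.90) L.

**Longitudinal structure.**  Follow-up = baseline + per-variable mean
5-year decline + independent noise (defaults: FVC −0.10 L with SD 0.25 L,
FEV1 −0.16 L, age exactly +5, smoking unchanged).  Alcohol change moves
subjects along the ladder per the change mixture 53.3 % / 34.8 % / 11.9 %
(none / < 100 / ≥ 100 g per week moved, uniform over the reachable rungs in
the class; never-drinkers can only move up, and from the very top rung the
nearest non-zero move substitutes when the small class is empty).  The FVC
change is shifted by β liters per 100 g/week of alcohol change; by default
β is solved analytically from the ladder's exact delta moments so the
population delta-correlation is 0.10 (β ≈ 0.027 L), making power and
null-calibration checks interpretable.  β = 0 gives the null configuration.

**What the generator does and does not emulate.**  It reproduces the
marginal moments, category mixtures, planted cross-sectional correlations
and longitudinal decline/attenuation structure the analysis assumes — and
nothing else: no attrition or survival processes, no measurement-device
error structure, no sex-specific drinking distributions beyond the planted
sex–alcohol correlation, no missing data by default, and Gaussian latents
throughout (real questionnaire responses have reporting biases a copula
cannot represent).  Passing tests demonstrate that the *algorithms* behave
as specified under known structure, not that any particular real-world
association exists.

## Numerical and design choices

- Determinism: one seeded `numpy` Generator per generate call; identical
  configs give identical tables, and the CLI pipeline is byte-reproducible.
- Analysis problem sizes: oracle-equivalence over 200 eight-variable
  matrices; confounder elimination at n = 5000 × 100 replicates; edge
  recovery with 20 variables at n = 2000 × 50 replicates; longitudinal
  power/null at n = 1765 with 100/200 replicates — each matching the scale
  of the cohort structure being emulated while keeping a full run within
  seconds.
- Ties in edge ranking break lexicographically; edge-list files are sorted
  by (rank, pair) so serialization is order-independent.
- `pair_screen` excludes self-pairs unless asked; eta is omitted (NaN) for
  continuous exposures.

## Known limitations

- PCIT evaluates one potential confounder at a time; joint effects of
  several confounders are invisible to first-order partials (the
  longitudinal arm exists precisely as an independent line of evidence).
- The ANOVA-side effect size is reported unsigned; directional claims come
  from r.
- Observed-scale calibration between two discretized variables is
  approximate (first-Hermite); tests budget 0.02 for it.
- The generator's per-category alcohol means follow from the equal-mass
  ladder allocation, not from any published band-occupancy table.
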