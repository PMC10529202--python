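# Methods

## The model

`ordent` analyses questionnaire data in which each item is rated on a small
ordered category set (here 1 = strongly disagree … 4 = strongly agree, with
0 = no answer). The central premise is that these codes are *labels*: the
distance between "2" and "3" is not a number, so sums, means, Pearson
correlations and factor loadings computed on the codes import an
interval-scale assumption the data do not support. Everything the package
computes therefore depends only on category *proportions*.

For an item pair the subjects' responses form a Kx×Ky contingency table with
covariate item X on the rows and response item Y on the columns. With p(x)
the row-margin proportions, p(y) the column margins and p(x, y) the joint
proportions, the package computes plug-in estimates of:

* **Row-wise conditional entropy** H(Y|X=x) = −Σ_y [p(x,y)/p(x)] log [p(x,y)/p(x)],
  one value per covariate level. This vector — the *entropy profile* — is
  the primary display unit: because the levels of X are ordered, the shape
  of the profile across levels is meaningful even though the level spacing
  is not.
* **Conditional entropy** H(Y|X) = Σ_x p(x) H(Y|X=x), the p(x)-weighted sum
  of the row entropies.
* **Shannon entropy** H(Y) = −Σ_y p(y) log p(y) of the response margin.
* **Rescaled conditional entropy** H(Y|X)/H(Y) ∈ [0, 1]: 0 means X predicts
  Y perfectly, 1 means X carries no information about Y. The ratio is
  invariant to the logarithm base.
* **Mutual conditional entropy (MCE)**: the unweighted mean of H(Y|X)/H(Y)
  and H(X|Y)/H(X). It is symmetric in the two items, lives in [0, 1], and
  *lower* values indicate *stronger* association. The all-pairs MCE matrix
  drives heatmaps and association networks, where an edge between items i
  and j is drawn iff 1 − MCE(i, j) strictly exceeds a threshold (default
  0.2) with thickness proportional to 1 − MCE.

Conventions: 0·log 0 ≡ 0 throughout; the log base defaults to natural log
(nats) and is configurable to base 2; ratio measures are base-free. A
covariate level with no observations contributes H(Y|X=x) = 0 *and* an
explicit `empty` flag — plotting conventions that draw empty rows at zero
conflate "no data" with "perfectly concentrated", and downstream consumers
should not.

The weighted form H(Y|X) is implemented as a positive weighted sum of the
nonnegative row entropies; a leading minus sign on that sum would force
H(Y|X) ≤ 0 and contradict H(Y|X) ≤ H(Y), so none is applied.

## Confidence intervals

Uncertainty is quantified by a fixed-row-total multinomial resampling
scheme. The observed row totals n_x are held fixed; the row-conditional
proportions are treated as estimates of the conditional probabilities; each
replicate table draws every occupied row independently from
Multinomial(n_x, p̂(y|x)), and empty rows stay empty. Recomputing any
statistic on M replicate tables (default M = 1000) yields its empirical
distribution, from which a plain percentile interval at level 1 − α
(default 95%) is read off using linear interpolation between order
statistics — fixed so that results are bit-reproducible per seed. For
vector statistics (entropy profiles) intervals are computed componentwise
from the same replicates, preserving the dependence between levels, and the
same applies to ratio statistics, whose numerator and denominator come from
the same replicate. Column-margin statistics such as H(Y) vary through the
replicates' column margins under the same row-fixed scheme; no second
scheme is introduced for them. Replicates on which a statistic is undefined
(a degenerate margin) are dropped and counted; more than 50% invalid
replicates is an error rather than an interval.

No bias correction is applied. Plug-in entropy is downward-biased at small
counts, and the percentile interval inherits that bias; the package's own
coverage simulation (500 tables with row totals of 300, M = 500) measures
empirical coverage of the nominal 95% intervals at roughly 93–94%.
All replicate draws flow through one seeded `numpy` Generator; each row's M
replicate rows are drawn as a single batched multinomial call, rows in
table order, which is the documented draw-consumption contract.

## Missing data and filtering

"No answer" responses are never imputed. Two deletion policies are
provided: **pairwise** (default) keeps every subject and drops them only
from item pairs where either response is missing, maximising data use at
the cost of per-pair subject sets that differ (per-pair n is recorded in
exports); **listwise** drops any subject missing any item. Covariate
filters (country, age range, group labels) are applied before analysis and
the retained counts are logged at each step so the filtering funnel is
auditable. Age bins for stratified displays are configuration, defaulting
to {[15, 18], (18, 25], (25, 35], (35, 50], (50, 70]} with the closed
late-adolescent bin first.

## Covariate fusion

Two covariate items can be fused into one pseudo-item whose levels are the
|S_a|×|S_b| composite labels "a-b" in lexicographic order ("1-1", "1-2", …,
"4-4" for two four-point items); a subject's fused value is missing if
either source is. The lexicographic order is well defined for two items of
the same polarity; for mixed-polarity pairs no attempt is made to merge the
two orientations into a single ordinal order — the displays group the
fused axis by the first item's level instead and leave the interpretation
to the reader.

## The synthetic generator

`generate_likert` exists so the entire toolkit is testable without any
external dataset. It uses a graded-response-style mechanism: subject i
carries latent traits θ ~ Normal(group shift, 1); an item with
discrimination a and increasing thresholds t₁ < t₂ < t₃ is answered
1 + #{t_k < a·θ + ε} with ε ~ Logistic(0, 1), negatively posed items
substituting −θ. Responses are then masked to the missing code completely
at random.

Defaults, chosen once: a 10-item battery with the standard self-esteem
polarity pattern (items 1, 2, 4, 6, 7 positive); discrimination a = 1.5;
thresholds (−2.5, −1.5, −0.5); group mixture 32% / 68% matching the
boy/girl composition of the motivating US late-adolescent sample; ages
uniform on 15–18; missing rate 1%. The asymmetric thresholds matter: they
reproduce the agreement-heavy margins typical of self-esteem items, which
is what makes the row-entropy profile *decrease* along a positive covariate
(high-trait subjects concentrate on "strongly agree"; low-trait subjects
spread across categories) and increase along a negative one. Symmetric
thresholds would produce U-shaped profiles instead.

What the generator does **not** emulate: informative missingness,
acquiescence or other response styles, multidimensional trait structure
beyond independent block traits, and the exact category frequencies of any
real survey. Passing tests on synthetic data therefore demonstrate that the
statistics and displays recover planted ordinal structure, not that any
psychological conclusion holds.

Pilot-run calibration notes (generator-specific, re-measured with this
mechanism): two items sharing a trait at a = 3 have plug-in MCE ≈ 0.80–0.83
at n = 5000, so tests assert the stable bound MCE < 0.9; planted two-block
structure is demonstrated at a = 4, where every within-block weight 1 − MCE
clears the default 0.2 network threshold and every between-block weight
falls far below it, giving exactly two connected components.

## Numerical and design choices

* Plug-in MCE is downward-biased from 1 at finite n: independent items at
  n = 10,000 measure ≈ 0.999, tested with tolerance 0.03.
* The network threshold is strict ("above 0.2"): a weight exactly equal to
  the threshold is excluded. Isolated nodes are retained in all exports.
* Category sets are fixed by the declared scale, not the observed values,
  so zero rows are representable and profiles over subsets keep all levels.
* Force-directed network layouts use a fixed seed; layout carries no
  semantics.
* Test and simulation sizes (200 random oracle tables; 500 coverage tables
  with row totals 300 and M = 500; 100 trend replicates at n = 5000) are
  the package's chosen demonstration sizes; the statistics scale to larger
  inputs linearly in M and in table size.

## Known limitations

* All entropies are plug-in estimates; no bias-corrected or shrinkage
  estimators are provided.
* No significance tests for edges, no community detection, no chi-square
  association measures, and no comparison against rank correlations.
* Bivariate *response* variables are out of scope; fusion is implemented
  for covariates only.
* The percentile CI can exclude the plug-in point estimate in strongly
  skewed cases; this is a property of the percentile method, not a bug.
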