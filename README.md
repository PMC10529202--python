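# ordent

Conditional-entropy analysis of ordinal questionnaire data.

Likert-type ratings ("1 = strongly disagree … 4 = strongly agree") are
ordered labels, not numbers. Sum scores, Pearson correlations and factor
models quietly treat them as interval-scaled. `ordent` instead works purely
with category proportions from contingency tables, and is aimed at
psychometricians and survey analysts who want association and profile
summaries that respect the ordinal-categorical nature of rating data.

For a covariate item X (rows) crossed with a response item Y (columns):

- **Entropy profile** — the row-wise conditional entropy
  H(Y|X=x) = −Σ_y p(y|x) log p(y|x), one value per covariate level; its
  shape across the ordered levels shows where the response is concentrated
  or spread.
- **Conditional entropy** H(Y|X) = Σ_x p(x) H(Y|X=x) and its base-free
  rescaling H(Y|X)/H(Y) ∈ [0, 1] (0 = perfect prediction, 1 = no
  information).
- **Mutual conditional entropy (MCE)** — the mean of H(Y|X)/H(Y) and
  H(X|Y)/H(X): a symmetric association strength (lower = stronger) that
  fills items×items heatmaps and, thresholded on the weight 1 − MCE,
  item-association networks.
- **Percentile confidence intervals** for any of these via fixed-row-total
  multinomial resampling.
- **A synthetic Likert generator** (latent trait + ordered thresholds +
  logistic noise) so every pipeline is testable without downloading any
  survey data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

The package bundles a worked 4×4 table: responses of 1977 US
late-adolescent boys to a negatively posed item Qi ("At times I think I am
no good at all", rows) crossed with a positively posed item Qj ("I feel
that I am a person of worth", columns).

```python
from ordent import (
    table1_fixture, row_conditional_entropy, entropy_summary,
    mutual_conditional_entropy,
)

ct = table1_fixture()
print(ct.total)
# 1977
print(row_conditional_entropy(ct).h_given_x)
# [0.76602162 0.88155772 1.10221065 1.28309578]
s = entropy_summary(ct)
print(round(s.h_y, 4), round(s.h_y_given_x, 4), round(s.ratio, 4))
# 1.2357 1.0239 0.8286
print(round(mutual_conditional_entropy(ct), 4))
# 0.8373
```

Reading the profile: among boys who *strongly disagree* with the negative
item (Qi = 1, high self-esteem), the response to the positive item is
highly concentrated — H(Qj|Qi=1) ≈ 0.766 nats — while among those who
*strongly agree* (Qi = 4, low self-esteem) it is far more spread out,
H(Qj|Qi=4) ≈ 1.283 nats. Uncertainty about the positive item rises
steadily with the level of the negative covariate. Overall, conditioning
on Qi retains 82.9% of the marginal entropy of Qj (ratio 0.8286), and the
symmetric MCE of 0.837 quantifies the pair's mutual association (0 would
be perfect mutual prediction, 1 independence).

The same analysis from the command line:

```sh
ordent simulate --out data.csv --n 2000 --seed 1   # or your own CSV
ordent profile --config examples/profile.yaml      # tidy CSV + figures
ordent mce --config examples/mce.yaml              # MCE matrix, heatmap,
                                                   # edge list, GraphML
```

A profile config names the input CSV and its item/covariate columns, the
response and covariate items, optional strata (e.g. gender, age bin),
fusion pairs, and the resampling settings; subject counts retained by every
filter step are logged to stderr.

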