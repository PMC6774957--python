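# colouremotion

Classifier-based quantification of colour–emotion associations and their
cultural differences.

People associate colour terms (RED, BLACK, PINK, …) with discrete emotions
(love, anger, sadness, …), and those associations differ — a little — between
cultures. Given survey data in which each participant rates the association
between 12 colour terms and the 20 emotion terms of the Geneva Emotion Wheel
(GEW) on a 0–5 intensity scale (0 = no association), this package answers
three questions with multivariate pattern classification instead of
cell-by-cell significance tests:

1. **Are emotion associations colour-specific?** Decode the colour term a
   participant rated from their 20 emotion ratings. Accuracy above the 1/12
   guessing rate means association patterns are colour-specific and
   consistent across people.
2. **Are they country-specific?** Decode a participant's country of origin
   from their full 240-rating profile (chance = 1/K for K countries), and
   measure the *in-group advantage*: for the within/between-country accuracy
   matrix A (train country = row, test country = column; diagonal from
   within-country cross-validation), D[i, j] = A[j, j] − A[i, j]. Positive D
   means a country's own decoder beats a foreign-trained one.
3. **Which colours carry similar emotion meanings?** Invert the decoder's
   confusion matrix with Luce's biased-choice model — P(respond j | stimulus
   i) ∝ b_j · η_ij with η_ii = 1 and η symmetric — using the moment estimator
   η_ij = √(p_ij · p_ji / (p_ii · p_jj)) on the row-normalised confusion
   proportions p.

The decoder is an error-correcting output-codes (ECOC) combination of
pairwise RBF-kernel SVMs with loss-weighted hinge decoding, evaluated by
**participant-grouped** 10-fold cross-validation (folds split participants,
never rows, so no one contributes data to both sides of a split),
hyperparameters tuned by grid search over (C, kernel width) in an inner
grouped CV, and significance assessed against a label-permutation null that
preserves the repeated-measures design. Performance is reported as the
proportion of correctly classified instances and the rank-based one-vs-rest
ROC AUC (prevalence-weighted and macro).

A seeded synthetic-data generator produces rating datasets with controllable
colour specificity (s), country divergence (δ) and participant heterogeneity
(ρ), so the whole pipeline is testable and its sensitivity demonstrable
without the original survey data.

## Worked example

```python
from colouremotion import (
    GeneratorConfig, generate, colour_feature_table,
    HyperParams, cross_validate, chance_level,
    estimate_similarity, similarity_report,
)

dataset = generate(GeneratorConfig(n_per_country=100, seed=20260127))
table = colour_feature_table(dataset)            # 4800 rows x 20 features
result = cross_validate(table, k=10, grid=[HyperParams(10.0, 0.01)], seed=1)
print(f"accuracy {result.accuracy:.3f} vs chance {chance_level(12):.3f}; "
      f"AUC {result.auc_weighted:.3f}")
sim = estimate_similarity(result.confusion, smoothing=0.5)
print(similarity_report(sim, top_n=1))
```

prints

```
accuracy 0.655 vs chance 0.083; AUC 0.938
[('black', 'green', 0.16872061506333352)]
```

i.e. on this simulated cohort the rated colour can be decoded from the 20
emotion ratings in 65.5% of trials — roughly eight times the 8.3% guessing
rate (AUC 0.938) — and the most confusable colour pair (the pair with the
most similar emotion associations under the biased-choice model) is
black–green with similarity 0.17 on the [0, 1] scale.

The full analysis is laid out as numbered drivers:

```sh
python analysis/01_simulate_cohort.py     # simulate 4 x 100 participants
python analysis/02_decode_colour.py       # colour decoding + permutation null
python analysis/03_decode_country.py      # country decoding (uniform prior)
python analysis/04_transfer_advantage.py  # transfer matrix + in-group advantage
python analysis/05_colour_similarity.py   # biased-choice similarity
```

Each writes its tables to `results/` (the bulky raw rating CSV goes to
`scratch/`). The same stages are scriptable through a config file
(`colouremotion run --config run.yaml`) or the individual CLI subcommands
(`simulate`, `decode-colour`, `decode-country`, `permtest`, `transfer`,
`similarity`, `apply`).

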