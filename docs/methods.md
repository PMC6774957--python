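# Methods

## Data model

A rating dataset is a complete grid: every participant rates the association
between each of 12 colour terms and each of 20 GEW emotion terms on a 0–5
scale (0 = no association; 1–5 = increasing intensity). The long-format CSV
schema is `participant_id,country,age,gender,colour,emotion,intensity`;
validation rejects out-of-range intensities, unknown colour/emotion/country
tokens, duplicate cells, incomplete (≠ 240-cell) participants and
participants assigned to more than one country. Demographics may be missing;
ratings may not. A "no emotion" response for a colour is represented as an
all-zero 20-vector — the 0 category already encodes "no association", and
endorsing no emotion is equivalent to endorsing none individually.
Free-text "different emotion" rows are dropped at load time. Colour,
emotion and country tokens are matched case-insensitively and stored
canonically; the vocabulary ordering is part of the contract, since it fixes
feature-column order everywhere downstream.

Two flattened views feed the decoder:

* **colour task** — one row per (participant, colour): 20 emotion ratings,
  label = colour term, 12 rows per participant;
* **country task** — one row per participant: all 240 ratings colour-major,
  label = country.

Descriptive summaries use *unweighted* pooling: rating-category proportions
are computed within each country first and then averaged with equal country
weights, so a 10× difference in national sample sizes does not tilt the
pooled picture.

## Decoder

Multiclass decoding uses error-correcting output codes over binary
RBF-kernel SVMs in a one-vs-one design: one binary learner per class pair
(66 learners for 12 classes), coding matrix entries +1/−1/0. The binary
SVMs come from scikit-learn (`sklearn.svm.SVC`); the ECOC combination is
implemented here. Decoding is loss-weighted: for class c the score is the
negated mean hinge loss max(0, 1 − m·code) over the learners in which c
participates, and the predicted label is the score argmax (ties resolve to
the earlier vocabulary position). Because ROC analysis is rank-based, these
loss-derived scores are used directly as per-class scores for AUC — any
strictly monotone transform would give the same AUC, so no probability
calibration is attempted.

*Uniform prior.* With unequal class sizes (the country task), training rows
are weighted inversely to class frequency (weight n/(K·n_c)), so decision
boundaries are not tilted by prior probabilities; AUC is additionally
reported macro-averaged next to the prevalence-weighted version.

*Cross-validation.* Folds partition participants, not rows: a participant's
12 colour-task rows always land on the same side of every split. Fold sizes
differ by at most one and the assignment is deterministic given the seed.
The no-leakage condition is asserted at run time for every fold — it is the
validity condition of the whole design, since rows within a participant are
strongly correlated. Defaults mirror the standard protocol: k = 10 outer
folds, 5-fold inner grouped CV for hyperparameter tuning inside each outer
training set (avoiding the optimistic bias of tuning on the full data; a
`tuning="global"` mode tunes once globally for comparison). The grid
defaults to C ∈ {0.1, 1, 10, 100} × width ∈ {0.001, 0.01, 0.1, 1}; ties
break towards smaller C, then smaller width. Features are already on a
common 0–5 scale, so no standardisation is applied by default — this also
keeps runs free of fold-dependent scaling state. On these scales, width
0.01 suits 20-dimensional colour rows and 0.001 the 240-dimensional country
rows (squared distances grow with dimension), which is what the analysis
drivers use as fixed settings when the grid search itself is not the point.

*Metrics.* The confusion matrix stores counts with true classes as rows;
row-normalised proportions give per-class recall on the diagonal (zero rows
are flagged, not divided). Accuracy is trace/total; the guessing rate for a
balanced K-class task is 1/K. Multiclass AUC is one-vs-rest per class via
the Mann–Whitney rank formulation with midrank tie handling, averaged with
prevalence or equal weights; classes lacking positives or negatives are
skipped with a warning.

## Permutation null

Significance of decoding performance is assessed by re-running the identical
cross-validation on label-permuted data (default 10 permutations) and
reporting p = (1 + #{null ≥ observed}) / (1 + n_perm). The permutation
respects the design: colour labels are shuffled *within each participant's
own 12 rows* (each participant still rates every colour exactly once, so the
permuted data are exchangeable with the observed data under the null — a
whole-table shuffle would break the balanced repeated-measures structure and
measurably miscalibrates the test), and country labels are permuted at the
participant level. With 10 permutations the smallest attainable p is 1/11,
so a secondary two-sided one-sample t-test of the observed AUC against the
null AUC values is reported alongside, labelled as such; neither statistic
silently replaces the other.

## Transfer and in-group advantage

For K countries, the transfer matrix A holds colour-decoding accuracies:
diagonal entries are within-country 10-fold grouped-CV accuracies (never
resubstitution), off-diagonal entries train on all of country i and test on
all of country j (no CV needed — the test country is disjoint by
construction). Hyperparameters are re-tuned per training country with the
same inner-CV protocol, so the in-group advantage is not confounded by
tuning procedure. The advantage D[i, j] = A[j, j] − A[i, j] is summarised by
mean, sample sd (n − 1), min and max over the K(K−1) off-diagonal entries.
Unequal country sizes are left as-is. The package also carries the published
four-country accuracy panel as reference data; reconstructing its advantage
panel arithmetically (mean 6.1%, sd 2.2%) is a standing cross-check of the
definition, to within the 0.001 rounding of the printed inputs.

## Biased-choice similarity

Under Luce's biased-choice model, P(respond j | stimulus i) ∝ b_j · η_ij
with η symmetric and η_ii = 1. The closed-form moment estimator
η_ij = √(p_ij p_ji / (p_ii p_jj)) is applied to the row-normalised confusion
proportions after adding a smoothing count (default 0.5) to every cell —
sparse 12-class confusion matrices contain zeros and the estimator divides
by the diagonal. The response biases cancel in the product, making the
estimate bias-free by construction; the bias vector itself (geometric mean
over rows of p_ij/η_ij, normalised to sum 1) is reported for transparency
but not used downstream. Estimates above 1 signal model misfit; they are
clipped to 1 and counted. A maximum-likelihood refinement of the estimator
is deliberately out of scope: on confusion matrices sampled from the model
itself, the moment estimator recovers η with RMSE < 0.02 at 10^5 choices
per row, which is ample for the confusion-matrix sizes produced here.

## Synthetic data generator

The generator emulates the structural features of cross-cultural GEW
surveys: a universal colour-specific association profile shared by all
countries, smaller country-specific deviations, many "no association"
responses, graded intensities among responders and participant-level
response propensity. For country c, colour k, emotion e:

    U[k,e]   ~ s · N(0,1)          universal profile
    V[c,k,e] ~ δ · N(0,1)          country deviation
    π[c,k,e] = squash(logit(base) + U + V)      association probability
    μ[c,k,e] = 0.1 + 0.8 · squash(U + V)        intensity level in (0,1)

and per participant p with propensity offset a_p ~ N(0, ρ):

    associated ~ Bernoulli(squash(logit(π) + a_p))
    intensity  = 0 if not associated, else 1 + Binomial(4, q),
                 q ~ Beta(μκ, (1−μ)κ)

`squash` is the logistic clipped to [0.02, 0.98] (floor configurable, 0
disables it) so no cell is deterministic unless explicitly requested. The
zero-inflated shifted-binomial intensity model was chosen because real GEW
data show a dominant no-association category with graded intensities among
responders; the Beta mixing with concentration κ adds cell-level
overdispersion with a single extra parameter. Degenerate means (μ ∈ {0, 1})
bypass the Beta draw.

Defaults describe the study conditions the analyses run under: 4 countries
(CN, DE, GB, GR) × 150 participants (the analysis drivers use 100 per
country to keep a full run at desk scale), s = 1 (moderate colour
specificity), δ = 0.5 (country deviations smaller than the colour
structure), base association probability 0.3 (giving ≈ 2/3 zero ratings,
matching the dominant no-association category), ρ = 0.5, κ = 10. s = 0
makes colours exchangeable (colour decoding at chance), δ = 0 makes
countries exchangeable (country decoding at chance, zero expected in-group
advantage) — these limits anchor the null-calibration tests. Seeding is
hierarchical (one stream for profiles, one per (country, participant
index)), so the same seed reproduces the same dataset and growing a cohort
preserves previously generated participants. Ages and genders are
uninformative placeholders.

What the generator does **not** emulate: the marginal rating distributions
of any real survey, valence structure among the 20 emotions (cells are
independent given the participant offset), item-level response styles, or
age/gender effects. Passing tests therefore demonstrate that the pipeline
detects structure it is pointed at and stays at chance when there is none —
not that real colour–emotion associations have any particular effect size.
Simulated decoding accuracies (e.g. ≈ 0.65 colour accuracy at s = 1, and an
in-group advantage ≈ 0.18 at δ = 0.5) are properties of these synthetic
conditions, not calibrated reproductions of published survey values.

## Numerical and design choices

* Scores for classes absent from a fold's training data are set to a large
  negative finite constant so pooled rank statistics stay defined.
* Permutation p uses the add-one estimator; AUC ties use midranks.
* Tie-breaking is deterministic everywhere (vocabulary order for predicted
  labels and report rankings; smaller C then smaller width in tuning), so
  identical (data, grid, seed) give identical results, and pipeline reports
  are byte-identical across reruns of the same config.
* Problem sizes in the test suite (tens of participants per country for
  behavioural checks, 150 per country for null-calibration checks) were
  chosen as the smallest cohorts at which the relevant effects are stable;
  the analysis drivers use 100 participants per country for the same reason.
* The pipeline never seeds from the wall clock; a config without a seed is
  rejected.

## Known limitations

* The ECOC design is fixed to one-vs-one with hinge decoding; other coding
  designs (one-vs-all, random dense codes) are not implemented.
* Only grid search is available for hyperparameter selection.
* The biased-choice estimator is the moment form; for confusion matrices
  with near-zero diagonals its variance grows quickly and clipping at 1
  becomes more frequent (clip counts are reported).
* The permutation test inherits the granularity of its permutation count:
  with the default 10 permutations, p < 1/11 is unattainable.
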