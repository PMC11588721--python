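# Methods

## Windows and classes

The unit of analysis is a fixed-length DNA window over {A,C,G,T} with a
candidate adenine at the center (default L = 41, center at position 21,
1-based) and a binary label: 1 if the central adenine is N6-methylated, 0
otherwise. Fitting anything requires at least one window of each class.
Ambiguous bases are rejected rather than coerced — every encoder below is a
per-position statistic, and silently mapping N to a canonical base would
corrupt the position counts. Coordinates in reports and feature names are
1-based.

## Position-specific trinucleotide propensity (strand-reduced)

Complementary pairing identifies T with A and G with C, so each window
collapses positionwise onto a {A,C} string ("double-strand" view: a
trinucleotide and its reverse complement partner share statistics). With 8
reduced trinucleotides and L−2 start positions, the training set yields
class-conditional frequency matrices F⁺, F⁻ ∈ [0,1]^(8×(L−2)), columns
summing to 1, and their signed difference Z = F⁺ − F⁻. A window's feature
vector is the length-(L−2) sequence of Z-lookups at its own trinucleotides.
Rows are ordered lexicographically with A < C (AAA, AAC, ACA, …, CCC);
the strand-reduction map is fixed as T→A, G→C.

Z is a *label* statistic. The cross-validation harness therefore refits it
inside each fold on the training split only (`leak_mode="fold_safe"`,
asserted at run time via training-set fingerprints stored on the fitted
model). The alternative `whole_dataset` mode — fitting Z once on all
records — exists to measure the inflation this leak produces: each window's
own trinucleotides then contribute 1/n_class to its class's frequencies, a
signal a boosted tree readily exploits even on label-free data. No
leave-one-out correction is applied to training windows in either mode.

## Classical encoders

* one-hot: 4 bits per position, (A,C,G,T) order; 4L features;
* k-mer: overlapping k-mer counts normalized by the window count L−k+1
  (so each row sums to 1), lexicographic feature order; 4^k features;
* chemical properties: 3 bits per base — ring structure, hydrogen bonding,
  functional group — A(1,1,1), C(0,1,0), G(1,0,0), T(0,0,1); 3L features;
* sliding composition: base frequencies in width-w windows, stride 1 from
  position 1; (L−w+1)·4 features, each 4-block summing to 1.

All four plug into the identical pipeline API for baseline comparisons.

## Attention fusion

Every feature position u is a token. Its key is (x_u, e_u) — the feature
value concatenated with a learned positional embedding e_u ∈ R^8 shared
across heads; each of H heads owns a learned query q ∈ R^8 and matrices
Wq ∈ R^(h×8), Wk ∈ R^(h×9), Wv ∈ R^h (defaults H = 4, h = 16). Scores are
additive, a(q,k_u) = Wvᵀ tanh(Wq q + Wk k_u) (a dot-product variant
(Wq q)·(Wk k_u)/√h is available via `score="dot"`), softmax-normalized
across positions, and head-averaged into weights w̄ with Σ_u w̄_u = 1. The
transform emits d·w̄_u·x_u, rescaled by the number of positions d so that
uniform attention is the identity — the downstream classifier never has to
undo a blanket 1/d shrinkage.

Training is plain full-batch gradient descent (no momentum, fixed step) on
the mean binary cross-entropy of a logistic readout over the re-weighted
features, all parameters jointly, 200 epochs by default. Backpropagation is
hand-derived and was validated against central finite differences. Three
numerical choices matter, all visible in `AttentionConfig`:

* **Standardization.** Features are column-standardized inside `fit` (the
  training mean/SD are stored and re-applied at transform time). This makes
  the default learning rate 0.3 scale-free; the transform's *output* stays
  on the original feature scale.
* **Readout weight decay (default 0.1).** The readout coefficient β_u and
  the attention weight w̄_u enter the logit only as a product, so an
  unpenalized readout absorbs all feature weighting and the softmax stays
  uniform. Penalizing ‖β‖² makes concentrating softmax mass on informative
  positions the cheaper way to build logit magnitude, so the learned
  weights genuinely reflect feature relevance (this is what the exported
  attention maps visualize).
* **Score-path step multiplier.** The softmax Jacobian scales gradients
  reaching the scoring parameters by the attention weights (≈1/d near
  uniform). Score-path parameters therefore take a d-fold learning-rate
  multiplier so scores and readout learn on comparable timescales; without
  it the weights are still visibly uniform after the default epoch budget.

Divergence (non-finite loss or scores, runaway coefficients) raises an
error naming the learning rate. With a fixed seed, fitting is bit-exact
reproducible. Multi-head combination is the arithmetic mean of head weight
vectors, which keeps feature names and dimensionality stable;
head-concatenation was rejected for that reason. The readout is internal —
downstream classification always goes through the ensemble classifier; the
readout exists to give the attention parameters a training signal and as a
diagnostic (its loss trajectory is stored on the fitted transformer).

## Classifiers and evaluation

Back-ends: XGBoost (default), LightGBM, AdaBoost, and a single decision
tree, behind one `ClassifierSpec` (defaults: 100 estimators, depth 6 for
boosting, learning rate 0.1, fixed seed, single-threaded for
reproducibility). No hyperparameter search is performed.

Metrics follow the field's reporting convention: Sn = TP/(TP+FN),
Sp = TN/(FP+TN), Pre = TP/(FP+TP), Acc = (TP+TN)/N as percentages;
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)) in [−1,1]; AUROC by
the trapezoidal rule over grouped-tie thresholds and AUPRC by the step
(average-precision) rule, both in [0,1] — PR trapezoids would overestimate.
A metric with a zero denominator is reported as 0 and flagged in the
report rather than raising. Labels use threshold 0.5 on the positive-class
score (score ≥ 0.5 ⇒ 1); ranking metrics use the raw scores.

Cross-validation is stratified k-fold (default 5) with shuffling driven by
the CV seed; per-fold class counts differ by at most one from exact
stratification, ties broken by the shuffled order. The report carries
per-fold metrics, their mean and SD, and a full config echo.

## Synthetic benchmark generator

The generator emulates the *structure* of published 6mA benchmark sets:
equal-length windows (41 nt), fixed central A, a positive class with
position-specific composition bias and a uniform background negative
class. At each informative position (default: within ±5 of the center,
center excluded) a positive window draws its base from
(1−bias)·Uniform{A,C,G,T} + bias·δ(preferred base), with the per-position
preferred base drawn once from the seed. bias = 0 makes the classes
identically distributed (a null benchmark for calibration and leakage
experiments); bias = 1 plants a deterministic motif. Default study size in
the acceptance script is 500 + 500 windows — large enough that fold-level
metric noise is a few hundredths of MCC, small enough for quick runs.

What the simulator does *not* emulate: genomic base composition and
dinucleotide correlation, sequence redundancy between windows (real
benchmarks are identity-reduced before use; the loaders accept such files
but no clustering is re-implemented here), chromosomal context, and
negatives that are true unmethylated adenine sites rather than background
draws. Passing the synthetic checks therefore demonstrates that the
pipeline is correct, calibrated, and leak-free — not that any particular
accuracy will transfer to real genomes.

## Degenerate inputs and conventions

Empty datasets can be written/read (header-only TSV) but not encoded or
fitted; single-class data is rejected by every fitting operation; k or
window larger than L, even L with a fixed center, and bias outside [0,1]
are parameter errors. Model bundles serialize to JSON — XGBoost and
LightGBM in their native text formats, the two sklearn back-ends as
embedded base64 pickle (they have no text serialization); attention
transformers and trinucleotide models are plain JSON throughout.

## Known limitations

* The attention readout is a single logistic layer; a deeper head might
  extract more, but would blur the interpretation of the weights.
* Attention concentration is an optimization-dependent diagnostic: on data
  where few positions carry signal it is strong, but weak signals spread
  over many positions concentrate less.
* Whole-dataset leakage inflation shrinks as datasets grow (the
  self-contribution is 1/n_class), so its measured size is specific to the
  study scale.
* No reverse-complement augmentation and no handling of IUPAC ambiguity
  codes; inputs must be pre-windowed and clean.
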