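# sixma

Prediction of DNA N6-methyladenine (6mA) sites from fixed-length sequence
windows, built around a position-specific trinucleotide propensity encoding,
an additive-attention feature-fusion step, and boosted-tree classifiers —
with a leak-aware cross-validation harness and a synthetic benchmark
generator.

## The problem

6mA is an epigenetic modification of adenine whose genomic positions are
expensive to map experimentally. Sequence-based predictors take a short
window (here 41 nt) centered on a candidate adenine and classify it as
methylated or not. The package is aimed at people building or auditing such
predictors: it implements the full pipeline, and it makes the single most
common methodological pitfall in this literature — fitting label-dependent
position statistics on the whole dataset before cross-validation —
reproducible and measurable.

## The model

**Encoding.** Watson–Crick complementarity (A:T, C:G) reduces every window
to a two-letter {A,C} string, leaving 2³ = 8 possible trinucleotides at each
of the L−2 positions. From a labeled training set the encoder estimates the
class-conditional frequencies F⁺(i|j), F⁻(i|j) of reduced trinucleotide
i ∈ {1..8} at position j ∈ {1..L−2} and their difference

    z(i, j) = F⁺(i|j) − F⁻(i|j),   z ∈ [−1, 1]^(8×(L−2)).

A window is encoded as φ = (z(i₁,1), …, z(i_{L−2},L−2)), the z-values picked
out by its own trinucleotides — positive where its local context looks
methylated, negative where it looks like background. Four classical
encoders (one-hot, k-mer frequencies, nucleotide chemical properties,
sliding-window composition) are provided for comparison.

**Attention fusion.** Each feature position is scored against a learned
query by additive attention, a(q,k) = Wvᵀ tanh(Wq q + Wk k), normalized by a
softmax across positions and averaged over heads; features are re-weighted
elementwise (rescaled so uniform attention is the identity). Attention and
a logistic readout are trained jointly by full-batch gradient descent on
binary cross-entropy, so attention mass migrates to the positions that
discriminate the classes.

**Classification.** The re-weighted features feed a gradient-boosted tree
ensemble (XGBoost or LightGBM) or, for comparison, AdaBoost / a single
decision tree. Evaluation is stratified 5-fold CV reporting Sn, Sp, Pre,
Acc (percent), MCC, AUROC and AUPRC.

**Leak modes.** The z matrix is a label statistic. In the default
`fold_safe` mode it is re-estimated inside every CV fold from the training
split only. The `whole_dataset` mode reproduces the leaky protocol (fit
once on everything, test folds included) purely to quantify how much it
inflates scores — on signal-free data it lifts mean MCC visibly above
chance.

## Worked example

```python
from sixma import (AttentionConfig, CVConfig, SimulationConfig,
                   cross_validate, simulate_dataset)

ds = simulate_dataset(SimulationConfig(n_pos=200, n_neg=200, bias=0.8, seed=42))
report = cross_validate(ds, encoder="pstnpds", classifier="gbdt_xgboost",
                        attention=AttentionConfig(seed=42),
                        cv=CVConfig(folds=5, seed=42))
print(report.summary())
```

prints

```
Stratified 5-fold cross-validation (fold_safe)
==============================================================================
metric          sn        sp       pre       acc       mcc     auroc     auprc
------------------------------------------------------------------------------
mean       88.0000   91.0000   90.9461   89.5000    0.7925    0.9534    0.9659
std         5.3385    5.1478    4.9667    3.6742    0.0731    0.0122    0.0101
fold 0     77.5000   90.0000   88.5714   83.7500    0.6803    0.9363    0.9501
fold 1     90.0000   92.5000   92.3077   91.2500    0.8253    0.9437    0.9600
fold 2     92.5000   85.0000   86.0465   88.7500    0.7772    0.9537    0.9671
fold 3     90.0000  100.0000  100.0000   95.0000    0.9045    0.9644    0.9787
fold 4     90.0000   87.5000   87.8049   88.7500    0.7752    0.9688    0.9734
```

The generator planted a composition bias of strength 0.8 at the ten
positions flanking the central adenine; the pipeline recovers it at mean
MCC 0.79 and AUROC 0.95 under leak-free 5-fold CV. Sn/Sp/Pre/Acc are
percentages; MCC is in [−1, 1] and the two areas in [0, 1].

The same run from the shell:

```bash
sixma simulate --n-pos 50 --n-neg 50 --bias 0.9 --seed 1 \
      --out-pos pos.fa --out-neg neg.fa
sixma cv --pos pos.fa --neg neg.fa --encoder pstnpds \
      --classifier gbdt_xgboost --folds 5 --seed 1 --out report.json
```

Subcommands `encode`, `train`, `predict` and `attention-map` cover the rest
of the pipeline (`sixma <cmd> --help` lists defaults). Real data enters the
same way: one FASTA of positive windows and one of negatives (equal length,
A at the center), or a two-column TSV (sequence, label).

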