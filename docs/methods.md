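# Methods

## The evaluation problem

A drug-response model predicts a response value ŷ<sub>ij</sub> for a (cell
line i, drug j) pair from an omics profile and a chemical structure.  The
framework's purpose is to separate three sources of apparent performance:
patterns already present in the training truth values (drug and cell-line
main effects), information carried by omics profiles, and information
carried by chemical structures.  It does so by crossing split regimes,
metric stratifications, null baselines and model ablations over a synthetic
screen whose generative structure is fully known.

## Synthetic screens

Responses are drawn as

    y_ij = mu + a_j + b_i + g(x_i, s_j) + eps_ij

with drug effects a<sub>j</sub> ~ N(0, sd_drug_effect²), cell effects
b<sub>i</sub> ~ N(0, sd_cell_effect²), noise eps ~ N(0, sd_noise²), and an
interaction g(x<sub>i</sub>, s<sub>j</sub>) = x<sub>i</sub>[signal]ᵀ W
s<sub>j</sub>: a bilinear form over a small set of omics signal features and
a latent per-drug descriptor s<sub>j</sub> ~ N(0, I).  W is a fixed random
matrix rescaled to Frobenius norm sd_interaction, which makes
Var(g) = sd_interaction² exactly under the standard-normal feature and
descriptor distributions.  This is the simplest interaction that is
invisible to main-effect baselines (it has zero mean within every row and
column in expectation) yet learnable by a model that sees both inputs.
Each pair is dropped independently with probability `missing_fraction`;
missing measurements are represented by absence of the record, never by a
sentinel, so per-entity record counts are unambiguous.

Omics features are i.i.d. N(0,1); only the designated signal columns enter
g.  Note that under mixed-set evaluation a cell line's feature vector also
acts as a fingerprint of its identity, so feature models can in principle
memorise main effects through it — as they can on real data.

Default generator parameters (100 cell lines × 30 drugs, sd_drug_effect 2.0,
sd_cell_effect 0.8, sd_interaction 0.5, sd_noise 0.7, grand mean 2.5 ln µM,
15% missing) put roughly 70% of the response variance into drug main
effects, the regime in which per-drug means are strong predictors — the
statistical situation the null baselines are designed to expose.  All
quantities derive from a single integer seed; identical configurations
reproduce identical screens byte-for-byte.

### SMILES

Drug structures are template-grammar SMILES-like strings (chains, branches,
rings, aromatic motifs, halogens) — tokenizable decoys with no chemistry by
default.  With `smiles_informative=True` the atom composition encodes the
leading descriptor components: the nitrogen, oxygen and chlorine fractions
carry s₁, s₂, s₃ through a sigmoid.  Because the drug branch mean-pools
token embeddings, composition fractions are exactly the statistic it can
read, so chemistry-borne interaction signal is recoverable in principle —
whether a given model recovers it is the experimental question.  The
generator makes no attempt at chemically valid molecules; validity is
irrelevant to the statistical questions the benchmark asks.

### Binarization-friendly noise

`inject_binarizable_structure` redraws the noise as a mixture
λ·|z|·sign(a_j + b_i + g) + (1−λ)·z with λ = 0.35, rescaled to variance
sd_noise².  The aligned component makes sign flips around the grand mean
rarer than under a symmetric draw of the same variance, while λ < 0.5 keeps
flips possible so label agreement still degrades monotonically with noise.
The result: thresholded labels carry a higher signal-to-noise ratio than
the continuous values — the situation in which binarized training targets
can reveal chemistry that continuous targets drown.

## Splits

Mixed-set splits the *pairs* uniformly at random; the train share is
`round(0.8 n)` so the realised fraction is within one pair of nominal for
any table size.  Test or validation pairs whose drug or cell line would
otherwise be absent from training are reassigned to train (with a count) —
this coverage repair is required for per-entity means and one-hot marker
models to be well defined, and is rare on realistically dense tables.
Blind regimes split the *entities*: validation and test receive
`floor(f·n)` cell lines (or drugs) each and train the remainder, and every
pair follows its entity.  Splitting is deterministic per seed, the split
seed is independent of the model seed, and `verify_split` re-checks the
partition and blindness invariants of any assignment without raising.

## Metrics

MSE, Pearson r, R² (continuous); AUC, AUPR, binary cross-entropy (binary).
Conventions, stated exactly because they decide edge cases:

* AUC uses the tie-aware Mann–Whitney convention (ties count ½), so a
  constant scorer has AUC exactly 0.5 whenever both classes are present.
* AUPR is step-wise precision–recall integration without interpolation; a
  constant scorer's AUPR equals the positive prevalence.
* R² within a stratum uses the stratum's own truth mean in SS_tot and may
  be negative; a predictor equal to the stratum truth mean scores exactly 0.
* Pearson is undefined (not zero, not an exception) when either vector has
  zero variance or fewer than two points; AUC/AUPR are undefined with a
  single class; correlation metrics are undefined in strata of size one.
* Stratified aggregation is the unweighted mean over *defined* strata, with
  the undefined count reported; a fully-undefined report aggregates to N/A,
  never 0.  BCE clips probabilities to [1e−12, 1−1e−12].

AUC and AUPR are computed through scikit-learn's `roc_auc_score` and
`average_precision_score`, whose conventions match the above; the test
suite verifies every metric under every stratification against independent
explicit-loop references (pairwise rank counting, threshold-by-threshold PR
integration) to 1e−10.

## Baselines

Drug-average and CL-average are plain per-entity training means (no
shrinkage), stored with their per-entity counts, which differ across drugs
when measurements are missing.  They predict a constant per drug (per cell
line) and refuse unseen entities — the drug average is a cancer-blind and
mixed-set instrument, its mirror a drug-blind and mixed-set one.  The
marker baseline is an MLP (default two hidden layers of 256) over
concatenated one-hot cell and drug vectors, trained with the same loss as
the models it calibrates (MSE continuous, BCE binary) and epoch-selected on
validation loss.  It bounds what identity alone can achieve: on
interaction-free screens it approaches the additive oracle
mu + a_j + b_i, and nothing it learns can transfer to unseen entities.

## Two-branch model and ablations

The reference model mirrors the dominant DRP architecture: a three-layer
MLP over the omics profile, a drug branch of transformer encoder layers
(token + learned positional embeddings, post-norm blocks, mean pooling over
non-pad positions) on SMILES tokenized by a greedy longest-match lexer
(two-letter elements, bracket atoms, ring-closure digits matched before
single characters; vocabulary built from the drug set at hand), and a
three-layer fusion MLP producing a continuous value or a sigmoid
probability.  Desk-scale defaults: d_model 64, 2 encoder layers, 4 heads,
maximum SMILES length 128; the benchmark configurations halve the widths.
Training is mini-batch Adam (lr 1e−3, batch 256) with best-epoch
checkpointing on validation loss and patience-based stopping; runs are
bit-reproducible from (split seed, model seed).

The `minus_drug_branch` ablation replaces the encoder with a raw one-hot
drug marker — drug identity survives, chemistry does not.  `all_marker`
additionally feeds one-hot cell markers to the cell branch, structurally
severing the omics path (the prediction is invariant to any change of the
omics matrix, which a test asserts).  Everything runs on an in-package
reverse-mode autodiff engine over numpy arrays whose primitives are
finite-difference-checked in the test suite.

## Benchmark conditions

Two frozen configurations in `benchmarks.py` define the default synthetic
benchmarks; they were chosen once as study conditions with enough
statistical power at desk scale, and the test suite asserts the qualitative
findings under exactly these conditions.

* **Ablation benchmark** (cancer-blind, binarized): 150 cell lines × 40
  drugs, 30% missing, sd_drug 1.0, sd_cell 0.3, sd_interaction 2.0 (or 0
  for the null variant), sd_noise 0.3, informative SMILES,
  binarization-friendly noise, per-drug-mean thresholds.  The high
  missingness and many-drugs/few-cells shape limit how well a per-drug
  one-hot can estimate each drug's interaction map, which is precisely the
  sample-efficiency advantage chemistry pooling provides.  With interaction
  on, the full model's drug-stratified AUC exceeds the -DB ablation's mean
  across three seeds; with interaction off the two are indistinguishable
  within seed noise.
* **Mixed-set null benchmark** (continuous): 100 × 30, no interaction,
  sd_drug 2.0, sd_cell 1.0, sd_noise 0.5.  Here nothing beyond the training
  truth values is learnable, and the marker baseline matches or beats the
  feature models within two seed-level standard deviations, all close to
  the sd_noise² floor.

Model training cells in these benchmarks take seconds to ~15 s each on one
CPU; the full qualitative suite runs in a few minutes.

## What the synthetic benchmarks do and do not show

The generator reproduces the *statistical anatomy* of a screen — main
effects, a low-rank interaction, missingness, noise — not its biology or
chemistry: omics features are isotropic Gaussians rather than correlated
expression programs, descriptors are low-dimensional and linearly encoded
in atom composition, and dose–response curve fitting is not modelled.
Passing benchmarks therefore demonstrates that the *evaluation machinery*
behaves as designed (baselines capture main effects exactly, stratification
exposes constant-per-drug predictors, ablations detect chemistry when and
only when it is present and learnable), not that any architecture will rank
real drug sensitivities.  Conversely, the null results are conservative by
construction: when the generator carries no interaction, no model should
beat identity-based prediction, and the suite checks that none does.

## Numerical and design notes

* Thresholds for binarization are computed once on the full table before
  splitting — binary truth is a property of the experiment, not of a fold.
  Strict `<` decides sensitivity; a drug whose values are all equal gets
  all-resistant labels (with a warning), and a single-record drug falls
  back to the global mean threshold.
* Undefined-value bookkeeping is deliberate API: aggregate N/A is reported
  as None end-to-end and printed "N/A", never coerced to 0.
* Comparison tables print "mean ± std" across model seeds per (metric,
  stratification) column, flag the best defined value per column, and leave
  undefined cells as N/A.
* Prediction caches are written at 17 significant digits and parsed with
  round-trip float precision, so resumed and fresh runs of a plan produce
  byte-identical metric reports.
* The marker baseline's fair-null status depends on matching the compared
  models' loss; the package enforces MSE/BCE by target kind rather than
  exposing a free loss choice.

## Limitations

Single-CPU scale only; no hyperparameter search, no graph- or
convolution-based drug branches, no pretrained chemical language models, no
cross-dataset evaluation, no dose–response refitting, and no
tissue-stratified or scaffold splits.  The blind-regime entity split
applies the 80/10/10 fractions to entity counts (whole rows/columns of the
response matrix), which is one of two defensible readings of pair- versus
entity-level fractions; it is the one compatible with the blindness
invariants.
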