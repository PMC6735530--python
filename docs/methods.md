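# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `tivae`. Empirical statements below are the ones the
test suite and `scripts/acceptance.py` compute; nothing else is claimed.

## Input model and preprocessing

The unit of analysis is a set of per-tissue matrices of genetically imputed
expression: individuals × genes, signed continuous values (positive =
predicted up-regulation), with a different gene subset per tissue because
expression-prediction models exist only for genes with sufficient
cis-heritability in that tissue.

For embedding, tissues are stacked into one design matrix whose rows are
(individual, tissue) pairs over the sorted union of the tissue gene sets.
Each gene is min-max scaled to [0, 1] **across all stacked rows where it is
present**, and entries for genes absent from a row's tissue are set to
exactly 0. Scaling across tissues (rather than within each tissue) is
deliberate: a tissue's mean signature for a gene is a *between-tissue*
contrast, and within-tissue min-max scaling would centre every gene at
~0.5 in every tissue, erasing precisely the signal the latent units must
encode. Constant genes map to 0. When an explicit train/test split exists
(the supervised stages), per-gene min/max are fit on the training rows and
applied to test rows with clipping into [0, 1].

Stratified splits allocate round-half-up of `fraction × stratum` rows to
training per stratum, the remainder to test, so every stratum is within one
row of the target fraction. Cognitive-decline labels are derived from the
4-year change in MMSE score: negative change ⇒ decliner, zero or positive ⇒
non-decliner, individuals missing either score excluded. Stratum subsetting
(sex, onset age with the ≥ 65 = late-onset convention, APOE-ε4 carrier)
filters rows by a covariate predicate without touching the gene universe.

## The variational autoencoder

One hidden layer, sized to the number of tissues. Following the public VAE
lineage for transcriptome compression that this architecture adapts, the
latent layer *is* the hidden layer: each of the μ and log σ² heads is an
affine map from the gene space followed by batch normalization and a
rectified linear unit. The non-negative latent breaks the rotational
symmetry of a linear Gaussian code; empirically this is what makes single
units specialize on single tissues (a rotation-symmetric latent spreads
each tissue over many units, and the one-unit SVM match then fails). The
decoder is a single affine map with sigmoid activation back to the [0, 1]
gene space — one linear weight per (unit, gene), which is what makes
decoder-weight gene ranking well-posed.

Loss = per-gene binary cross-entropy summed over genes (the natural
negative log-likelihood for [0, 1]-scaled data under a sigmoid decoder),
averaged over the batch, plus κ times the closed-form KL divergence
−½ Σ (1 + log σ² − μ² − σ²) against the standard-normal prior. κ defaults
to 1 (a constant weight, matching the cited implementation's warm-up
semantics at κ = 1). The reparameterized sample z = μ + σ·ε is used during
training only; `encode` returns the deterministic μ (evaluation-mode batch
norm), so downstream analyses are reproducible. Training uses Adam at
learning rate 10⁻³; the final partial batch is trained on; all randomness
(init, shuffling, ε) flows from one seed. Gradients are hand-derived and
checked against central differences to < 10⁻⁶ in the test suite.

Full-scale defaults are 75 epochs at batch 500 (appropriate for a ~27k-row
stacked cohort). Desk-scale runs (pipeline defaults, tests, acceptance
script) keep 75 epochs but use batch 64, which gives the optimizer a
comparable number of Adam steps on a ~1,000-row synthetic cohort. Longer
training was examined and starts to overfit the finite-sample structure of
small cohorts (list quality degrades past a few hundred epochs at this
scale).

Cases and controls are embedded by entirely separate models; the procedure
repeats `n_repeats` times (default 75 full-scale, 10 desk-scale) with seed
= base + repeat, each repeat on a fresh 80/20 tissue-stratified split.

## Latent-unit → tissue matching

For every (unit, tissue) pair, a linear SVM (C = 1, balanced class weights)
sees only that unit's activation column and a one-vs-rest tissue label
under 5-fold stratified cross-validation; the fold-mean F1 of the tissue
class is compared **strictly** against 0.8. Activations come from encoding
all rows of the model's class (train + test), which maximizes per-tissue
counts for the folds. A unit may be associated with several tissues and a
tissue with several units; per-repeat maps are kept separate until
aggregation.

## Gene prioritization

For each tissue-associated unit, the k = 100 most positive decoder weights
give its upregulated list and the 100 most negative its downregulated list
(ties broken by gene ID; k above n_genes/2 is rejected because the lists
would overlap). Occurrence counts are accumulated per tissue and direction
over all (repeat, unit) rankings; genes with count strictly greater than
`min_count` (default 3) are retained. A unit associated with several
tissues contributes to each; a gene retained in both directions is kept in
both and flagged on export. The disease-specific signature is the per-tissue,
per-direction set difference: case-retained minus control-retained.

Two structural facts about these lists on any multi-tissue input: (i) the
most negative decoder weights of a tissue's unit are dominated by the genes
*absent* from that tissue (their zero-filled columns sit far below the
cross-tissue mean), so the down lists carry the missing-gene block and only
up-shifted differential genes are reliably recoverable; (ii) the retained
lists also contain genuine but disease-unrelated structure (other tissues'
signatures, finite-sample tissue-mean fluctuations) that recurs across
repeats because it is a property of the data, not of the initialization.
The case-minus-control signature cancels (ii) exactly, which is why it
concentrates the planted differential genes far more sharply than the raw
retained lists.

## Enrichment

The running-sum score walks the ranking of genes by descending statistic S
(ties by gene ID): a gene-set hit adds |S|^w normalized by the summed hit
weights, a miss subtracts 1/(N − |p|); the score is the extremum of largest
magnitude (positive preferred on exact ties), and the leading edge is the
hits up to (positive score) or after (negative score) the extremum. If every
hit has zero weight the increments fall back to uniform 1/|p|. w defaults to
1; w = 0 gives the unweighted Kolmogorov–Smirnov form.

Significance is empirical: n_perm uniform same-size gene sets are drawn
from the universe; p = (1 + #{same-sign permutation scores at least as
extreme}) / (1 + #{same-sign permutation scores}) — an add-one estimator
that can never return zero — and NES = ES / mean |same-sign permutation
score|. With no same-sign permutation score, p floors at 1/(1 + n_perm) and
NES is reported missing. Benjamini–Hochberg runs within one result batch
(one tissue's collection here).

The gene-level statistic the pipeline feeds this machinery is the
**differential count**: S = (case up-count − case down-count) − (control
up-count − control down-count) over all counted genes, zero elsewhere. It
is the quantitative form of the disease-specific signature: structure
shared by the two embeddings cancels exactly, and it avoids the cliff a
retention cutoff would introduce. The retained-count statistic
(S = up − down over the retained lists) is also provided.

Two design points follow from the permutation arithmetic rather than from
tuning: with n_perm = 1000 the attainable p-value floor is ≈ 1/(1 + ~500
same-sign permutations) ≈ 0.002, so a per-batch test count of ~18 (six
planted sets + twelve decoys by default) is the scale at which a floor
p-value still clears FDR 0.05; and a gene set mixing up- and down-regulated
members cancels its own signed running sum, so the planted pathway sets
default to directionally coherent (up-shifted) cores — the standard reading
of a co-regulated program.

## Classifiers

Five architectures, all ending in a two-unit softmax trained with Adam and
cross-entropy (equivalent to binary cross-entropy on two units):

- dense-1: 800/500/400/200/40/2; dense-2: 800/200/2 (ReLU hidden);
- conv-1: conv(10 filters) → conv(5) + dropout → conv(5) → dense 200 +
  dropout → dense 100 → 2; conv-2: conv(10) + dropout → conv(5) → dense 2.
  Kernel 8 and stride 4 by default (the sources do not fix them; striding
  keeps the flattened width manageable for thousands-gene inputs), clamped
  per layer so short inputs survive the stack;
- recurrent: LSTM → batch norm → LSTM → batch norm → dense 2, widths 150/10
  at full scale and 16/4 reduced for desk-scale runs. The flat gene vector
  enters the LSTM as zero-padded 64-gene chunks (timesteps = ⌈n/64⌉); a
  single-timestep mode (1 × n_genes) is available, since no convention
  exists for feeding a flat gene vector to a recurrent net.

Training is stratified k-fold (default 10) with a fresh network per fold
and a final refit on all rows; the fold-mean AUC is the "training AUC"
reported on cross-tissue diagonals. Class weighting is off by default
(matching the observed majority-class collapse of unweighted shallow
baselines) and available behind a flag. AUC uses the rank (Mann–Whitney)
formulation, exact under ties; other metrics come from the confusion matrix
at the 0.5 score threshold. Single-class evaluation partitions report AUC
as missing. Shallow baselines (logistic regression, SVM, random forest) and
the constant majority-class predictor (accuracy = majority fraction, AUC =
0.5 exactly under tied ranks) are provided for the collapse comparison.
Cross-tissue transfer zero-fills every tissue to the union universe, trains
one model per tissue, and reports the train × test AUC matrix. Filter
comparisons use a paired t-test on per-tissue AUC differences; zero-variance
differences report a missing p-value with a note.

Train/test splits follow the fixed 600/208 counts when the cohort has 808
individuals, otherwise the 0.743 train fraction those counts imply.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` draws a per-gene baseline b_g ~ N(0,1) shared across
tissues; each tissue carries a uniform random subset of the universe
(default 400 of 500 genes), a mean shift of `signature_effect` (default 3,
in units of the noise SD) on its signature genes, and a signed shift of
`diff_effect` (default 2) on its differential genes for cases only;
i.i.d. Gaussian noise (SD 1) on top. Defaults: 6 tissues, 300 individuals
with the ~65% case fraction of the motivating cohort design, 30 signature
and 25 differential genes per tissue. Pathway sets overlap the planted
differential genes (up-shifted core by default) plus uniform fillers, with
uniform decoy sets.

This emulates: distinct per-tissue gene subsets, strong tissue clustering,
signed continuous values, class imbalance, planted case/control contrasts
and enriched pathways — enough for every stage to be scored against truth.
It does **not** emulate: gene–gene correlation (LD-driven co-prediction),
heavy-tailed or heteroscedastic prediction noise, batch structure, related
individuals, or realistic pathway overlap topology. Passing tests therefore
demonstrate that each stage recovers the structure it targets under clean
conditions, not that effect sizes on real imputed transcriptomes would be
comparable.

## Numerical and reproducibility notes

- All randomness in a pipeline run derives from one global seed plus fixed
  per-stage offsets (kept below 2³¹); stage outputs are cached on disk
  keyed by a hash of the semantic configuration, so re-runs resume and
  identical configurations reproduce identical artifact checksums.
- The neural core is float64 NumPy with manual backpropagation; every layer
  and the VAE pass are verified against central-difference gradients.
- Degenerate inputs have defined behavior: constant genes scale to 0,
  single-class partitions report AUC as missing, tissues with no associated
  unit yield empty (flagged) lists, gene sets disjoint from the universe
  are skipped, zero-variance paired differences yield a missing p-value.
- Desk-scale problem sizes used by the test suite and acceptance script
  (6 tissues × 300 individuals, 10 VAE repeats, reduced LSTM widths,
  two-fold classifier CV in the calibration checks) were chosen so the full
  analysis runs in minutes on one CPU; full-scale defaults remain in the
  configuration objects.

## Known limitations

- Only the up-shifted half of planted differential genes is recoverable
  from decoder weights on cohorts with per-tissue missing genes (the
  missing-gene block occupies the negative extreme of every tissue unit's
  decoder row); the signature subtraction mitigates but cannot recover the
  down-shifted half.
- The raw retained lists carry real but disease-unrelated structure; their
  hypergeometric enrichment for planted genes at desk scale is marginal by
  construction (the case-minus-control signature is the robust read-out).
- The empirical p-value resolution is bounded by n_perm; FDR-significant
  calls in large collections need permutation counts well above 10³.
- With latent width equal to tissue count, unit specialization depends on
  the rectified latent; substantially more tissues than units would force
  multi-tissue units and blur per-tissue lists.
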