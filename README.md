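# tivae

Latent-space dissection and deep classification of **tissue-specific,
genetically imputed transcriptomes**.

Transcriptome-wide association studies impute the cis-regulatory component
of gene expression from genotypes (PrediXcan-style elastic-net models
trained on GTEx), yielding one individuals × genes matrix per tissue. This
package implements an integrated unsupervised + supervised analysis of such
matrices, built around an Alzheimer's-disease-style case/control cohort
design:

1. **Embedding** — per-tissue matrices are min-max scaled, zero-filled over
   the union gene universe and stacked into (individual, tissue) rows; a
   variational autoencoder with a single rectified latent layer (one unit
   per tissue, batch-normalized μ and log σ² heads, sigmoid decoder, loss =
   per-gene binary cross-entropy + κ·KL(N(μ,σ²) ‖ N(0,I))) is trained
   separately on case rows and control rows, many times with shifted seeds.
2. **Latent–tissue matching** — a latent unit *encodes* a tissue when a
   single-feature linear SVM (C = 1, balanced class weights, 5-fold
   stratified CV) predicts tissue membership from that unit's activation
   with F1 > 0.8.
3. **Gene prioritization** — because the decoder is one linear map, the 100
   most positive / most negative decoder weights of each tissue-associated
   unit give per-tissue up/down gene lists; genes recurring more than
   `min_count` times across repeats are retained, and case-retained minus
   control-retained genes form the disease-specific signature.
4. **Enrichment** — a GSEA-style running-sum score sr(p) over the signed
   gene statistic, with empirical p-values from uniformly re-sampled
   same-size gene sets, NES normalization by the same-sign permutation
   mean, and Benjamini–Hochberg FDR per result batch.
5. **Classification** — an architecture zoo (two dense nets, two 1-D
   convolutional nets, and the paper-style recurrent network LSTM→BN→LSTM→
   BN→dense-2), 10-fold cross-validated Adam/binary-cross-entropy training,
   the five monitored metrics (accuracy, AUC, precision, recall, F1),
   per-tissue gene-list feature filters, and cross-tissue transfer (a
   train-tissue × test-tissue AUC matrix with training AUC on the diagonal).

A **synthetic cohort generator** with planted ground truth (tissue
signatures, signed case/control differential genes, pathway sets built to
overlap them) stands in for the access-controlled cohort data, so every
stage is testable end to end against a recoverable truth. The neural
components run on a small NumPy core with manual backpropagation (verified
against numerical gradients in the test suite); no GPU or deep-learning
framework is required.

## Worked example

`examples/` contains one narrative script per capability. The full pipeline
(`examples/06_full_pipeline.py`: 3 tissues, 150 individuals, 5 VAE repeats)
prints:

```
per-tissue held-out AUC:
filter    List-unsupervised  no-filter
tissue
tissue01              0.960      0.594
tissue02              0.880      0.709
tissue03              0.877      0.749

top enrichment rows:
  tissue          pathway     pval     padj       ES
tissue03 planted_tissue03 0.003497 0.031469 0.809452
tissue01 planted_tissue01 0.003968 0.035714 0.728632
tissue02 planted_tissue02 0.010753 0.062500 0.635925
```

Reading this: restricting each tissue's classifier to the genes the
unsupervised arm prioritized (*List-unsupervised*) raises held-out AUC on
every tissue, and each tissue's planted pathway floats to the top of its
enrichment table with a positive running-sum score — the planted
case/control program was recovered from the decoder weights alone.

There is also a thin CLI over the same pipeline:

```bash
tivae run --seed 7 --outdir out/          # or simulate / embed / enrich / ...
```

Each subcommand runs the pipeline up to that stage, resuming from cached
stage outputs keyed by the configuration hash.

## Layout

| module | role |
| --- | --- |
| `tivae.synthetic` | cohort generator, planted truth, pathway sets, dataset IO |
| `tivae.preprocessing` | scaling, stacking, stratified splits, decline labels |
| `tivae.vae` | VAE model, training, repeated per-class embedding |
| `tivae.matching` | single-feature SVM latent-unit → tissue association |
| `tivae.prioritization` | decoder-weight ranking, aggregation, signatures |
| `tivae.enrichment` | running-sum ES, empirical p-values, NES, BH-FDR |
| `tivae.classification` | architecture zoo, metrics, filters, cross-tissue AUC |
| `tivae.pipeline` | config, orchestration, caching, manifests |
| `tivae.nn` | NumPy neural core (dense/conv/LSTM/batch-norm/Adam) |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
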