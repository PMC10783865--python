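# Methods

## Overview

`tcrbind` predicts whether a T-cell receptor (TCR, represented by its CDR3β
loop) recognises a peptide–MHC class I complex (pMHC). The approach is
transfer learning in three stages:

1. **TCR encoder** — a BERT-style bidirectional transformer over CDR3β
   sequences (10–30 residues), pretrained by masked language modeling (MLM)
   on an unlabeled repertoire.
2. **pMHC encoder** — the same stack plus segment embeddings over
   `[START] + 34-residue MHC pseudo-sequence + epitope (8–15 residues)`,
   pretrained jointly on selective MLM (SMLM; masking applied only to
   records where epitope–MHC binding occurs) and a regression of the pooled
   START state onto a 0–1 binding label ("NSP" task: binding-affinity
   records transformed by `1 − log IC50 / log 50000`, clamped to [0, 1];
   mass-spectrometry ligandome records as 0/1).
3. **Prediction head** — with both encoders frozen, four bias-free rank-1
   mapping layers compress each embedding matrix (L × D) into a length-L
   vector (`v_len[i] = ⟨row i, w_dim⟩`) and a length-D vector
   (`v_dim[j] = ⟨column j, w_len⟩`); the concatenation feeds an MLP
   (200 → 100 → 50, ReLU, dropout 0.4) ending in a single tanh unit
   f ∈ (−1, 1). Training is Siamese and contrastive: matched positive and
   negative pairs pass through shared weights under

       loss = Relu(1 + f⁻ − f⁺) + 0.2·(f⁻² + f⁺²).

   Negatives re-pair positive pMHCs with TCRs from a healthy background
   repertoire and are redrawn every epoch (1:1 with positives).

   Four head-engineering choices matter at desk scale and are defaults
   (each exposed or documented): frozen features are read from the
   **penultimate** encoder layer — the classic BERT featurization choice,
   since the final layer specialises to the pretraining head; the
   positional mapping weights initialise as a Gaussian bump over the
   CDR3β apex (TCR) and the epitope block (pMHC), a structural prior on
   where contacts live that removes an otherwise seed-dependent collapse
   of contrastive training; the head trains without decoupled weight decay
   (the 0.2·f² term in the loss already pulls scores toward zero); and the
   weights of the best-validation epoch are restored after early stopping.

The deployable score is a **percentile rank**: the candidate's f is ranked
(midrank ties) against the same pMHC paired with n = 1000 background TCRs,
giving a score in [0, 1] that is comparable across pMHCs and invariant
under any strictly monotone transform of f.

## Architecture and schedules

Reference encoder configuration: 4 layers, 256 dimensions, 8 heads,
feed-forward 4×dim (the standard transformer ratio), learned absolute
position embeddings, post-layer-norm blocks, GELU feed-forward, dropout
0.1. A START token is prepended to every sequence and its final hidden
state is the pooled representation; padding uses a dedicated token and is
masked out of attention, so pad content cannot influence true positions
(verified to < 1e-5). Segment ids are 0 = MHC (TCRs use 0 throughout),
1 = epitope, 2 = padding; no separator token is used. The vocabulary has
24 symbols: PAD, START, MASK, UNK plus the 20 canonical amino acids. MLM
corruption is the standard 15% rate with the 80/10/10
mask/random/unchanged split.

Pretraining schedules: AdamW, peak learning rate 5e-4, batch 512, linear
warmup over 4000 steps, learning rate ×0.3 when validation loss fails to
improve for 2 consecutive epochs, early stop after 4 (1% of the corpus
held out for validation, fixed by seed). The prediction head uses lr
0.005, batch 256, early stop after 6, with a 5% epitope-stratified
validation split. "Reducing the learning rate by 0.3" is implemented as
multiply-by-0.3 (scheduler-factor semantics).

At desk scale these schedules need two adaptations, applied uniformly and
stated wherever used: warmup is set to ~10% of the total step budget
(a 4000-step warmup would exceed the whole budget of a small run, freezing
the learning rate near zero), and batch sizes shrink so that small corpora
still yield enough optimizer steps.

The joint pMHC loss weights CE and MSE 1:4 by default (knob
`loss_weights`). Cross-entropy starts near ln 24 ≈ 3.2 while the MSE term
is bounded by 0.25; unit weighting leaves the regression gradient starved
and the binding head at chance on held-out data, while 1:4 brings the two
gradient scales close enough for both to train.

One subtlety is load-bearing: selective masking correlates with the
binding label by construction, so if the regression head saw the corrupted
inputs it could read the label straight from the MASK tokens (this failure
mode is observable: near-zero validation MSE with constant predictions on
clean inputs). SMLM therefore runs on its own forward pass (binder records
only, corrupted), and the NSP regression on an uncorrupted pass over the
whole batch.

The binder flag gating SMLM is: MS label = 1, or BA unit score ≥ 0.4256
(the transform of the conventional 500 nM binder cutoff).

## Attention-based interpretation

Residue importance is the attention a residue *receives*: column sums of
each attention matrix, averaged over all layers and heads, with START and
padding excluded and the result renormalised to sum to 1 ("emitted"
row-sum aggregation is available as an option). Epitope profiles restrict
to segment-1 positions and renormalise.

Two analyses consume profiles:

* **Motif contrast** — given GLIPH2-style cluster annotations (read from a
  table; the clustering algorithm itself is out of scope), attention is
  averaged inside vs outside motif positions per cluster and the paired
  cluster-level means are tested with the two-sided Wilcoxon signed-rank
  test (≥ 2 clusters required; all-zero differences report p = 1).
* **Structural proximity** — from Cα coordinates (representative atom
  configurable) of a TCR chain and an epitope chain, each TCR residue gets
  its mean Euclidean distance to all epitope residues; Spearman ρ between
  attention and distance is computed after per-complex min–max
  normalisation of both vectors (inert for ρ, kept for plotting parity),
  with a two-sided permutation p-value using add-one smoothing,
  p = (1 + #{|ρ_perm| ≥ |ρ|}) / (1 + n_perm). The signed ρ is reported as
  computed; under the geometry used here, planted contacts with high
  attention produce negative ρ (close ⇒ important).

## The synthetic-data generators

Real recognition rules are unknown, so the generators plant known ones:

* **Background repertoire** — CDR3β lengths uniform on [10, 30], residues
  uniform over the 20 amino acids (an optional human-like "CASS" prefix
  bias exists; uniform is the default because it keeps planted signals
  free of compositional confounds).
* **Anchor rules** (pMHC) — each synthetic allele permits 3 residues at
  epitope position 2 and 3 at the C-terminus (the classic MHC-I anchor
  layout); an epitope binds iff both anchors match. Labels are flipped
  with probability η = 0.1; BA records then receive an IC50 drawn
  log-uniformly on the side of 500 nM consistent with the (possibly
  flipped) label.
* **Recognition rule** (pairs) — a fixed table maps 8 epitope central
  3-mers to 2 compatible TCR central 3-mers each. Positives carry a
  compatible 3-mer at the TCR's central position except an η = 0.1
  fraction. Held-out epitopes are string-disjoint from training but share
  the table's keys, so generalisation to unseen epitopes is measurable.
  3-mer granularity keeps the rule learnable by a small transformer yet
  non-trivial; η keeps the Bayes ceiling below 1.
* **Rule repertoire** — the pretraining corpus for the pair task plants a
  compatible 3-mer at the central position of 50% of sequences, emulating
  the antigen-experienced clones present in real repertoires. This is what
  makes the transfer step meaningful: MLM on a structureless uniform
  corpus has nothing to learn (its loss floor is ln 20), and embeddings
  from such an encoder do not expose the recognition features — measured
  directly, a frozen-encoder head trained on them stays near chance.
* **Toy complexes** — contact residues are placed within 5 Å of the
  epitope centroid, the rest at 15–25 Å.

What these generators do **not** emulate: V(D)J recombination statistics,
real HLA pseudo-sequences, epitope processing biases, TCR
cross-reactivity, or paired α/β chains. Passing tests therefore
demonstrate that the pipeline recovers planted structure under its own
stated noise model — they say nothing about accuracy on real immunological
data, which would require the full-scale corpora and external benchmarks.

## Numerical choices

* Computation is float32 throughout, on a reverse-mode autodiff engine
  over NumPy written for this package (fused softmax/layer-norm/
  cross-entropy; AdamW with decoupled weight decay 0.01).
* Zero-mask MLM batches define the loss as 0 rather than NaN.
* Youden threshold: maximises TPR − FPR over midpoints of adjacent
  distinct scores, ties broken toward the lower threshold; predictions
  positive when score > threshold.
* AUC-PR is average precision (step-wise summation, no interpolation);
  AUC-ROC uses midrank ties.
* Rank scores use midrank tie handling; the background is drawn without
  replacement (pool must be ≥ n).
* The zero-shot frequency threshold is strict: epitopes with > min_count
  occurrences (default 10) go to training.
* Degenerate inputs fail loudly: single-class metric inputs, empty pools,
  constant correlation vectors, < 2 motif clusters.

## Scaled-down study conditions

The distributed checks run the whole pipeline at reduced size, chosen once
as this package's desk-scale condition: tiny encoders (2 layers, 64 dim,
4 heads, ff 256), a 20k-sequence rule repertoire for 2 MLM epochs
(batch 128), 10k pMHC records (4 alleles) for 3 joint epochs (batch 96),
4000 positive pairs for the contrastive head (batch 256, warmup 100
steps, early stopping within 200 epochs) against an 8000-TCR healthy
pool, evaluated on an epitope-disjoint test set of 500 positives and 500
re-paired negatives (`tcrbind.workflows.run_zero_shot_study`).
Presentation accuracy is reported as AUC against the planted anchor
rule's true labels on held-out epitopes (η is training noise; recovery of
the planted rule is the quantity of interest). Full-scale training — real
repertoires of 10⁸ sequences, millions of binding records — and external
benchmark reproduction are out of scope.

## Known limitations

* The rank-1 mapping layers are an aggressive bottleneck; at desk scale
  the prediction head depends strongly on what the frozen embeddings
  expose, hence on pretraining-corpus structure.
* MLM on short sequences with a 24-symbol alphabet saturates quickly;
  attention profiles from tiny encoders are noisier than full-scale ones.
* The permutation test recomputes Spearman per permutation (O(n_perm ·
  n log n)); fine for per-complex use, slow for thousands of complexes.
* CDR3β-only: no α chain, no V/J gene context.
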