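# tcrbind

Predicting TCR–pMHC recognition — whether a T-cell receptor (via its CDR3β
loop) binds a peptide presented by an MHC class I molecule — is a central
problem for TCR-engineered therapies and neoantigen vaccine design, where
the epitopes of interest are usually *unseen*: absent from every training
database. `tcrbind` implements a transfer-learning pipeline for this
zero-shot setting, exercisable end to end on synthetic data with planted
ground truth, for computational immunologists who want a testable,
desk-scale implementation of the approach.

## The model

Three stages, each a separate module:

1. **TCR encoder** (`tcr_bert`) — a bidirectional transformer (default 4
   layers, 256 dims, 8 heads) over integer-encoded CDR3β sequences,
   pretrained by masked language modeling: 15% of residues are corrupted
   (80% → `MASK`, 10% → random residue, 10% unchanged) and recovered with
   cross-entropy loss.
2. **pMHC encoder** (`pmhc_bert`) — the same stack with segment embeddings
   over `[START] + pseudo-sequence (34 aa) + epitope (8–15 aa)`, trained
   jointly on *selective* MLM (masking only where epitope–MHC binding
   occurs) and regression of the pooled `START` state onto a 0–1 binding
   label: binding-affinity records via s = 1 − log(IC50)/log(50000),
   mass-spectrometry records as 0/1. The regression head doubles as an
   epitope-presentation predictor.
3. **Prediction head** (`binder`) — with both encoders frozen, rank-1
   mapping layers compress each embedding matrix E ∈ R^{L×D} into
   v_len = E·w_dim and v_dim = Eᵀ·w_len; an MLP (200→100→50, dropout 0.4,
   tanh output) scores the concatenation. Training is contrastive over
   (positive, negative) pairs with shared weights:

       loss = Relu(1 + f⁻ − f⁺) + 0.2·(f⁻² + f⁺²)

   where negatives re-pair positive pMHCs with healthy-repertoire TCRs.
   The reported score is a **percentile rank** of f against the same pMHC
   paired with 1000 background TCRs.

Around the core: `benchmark` builds epitope-disjoint (zero-shot) splits and
computes AUC-ROC, AUC-PR, PPV@k and Youden cutoffs with negative
resampling; `interpret` contrasts self-attention between motif and
non-motif residues (Wilcoxon signed-rank over GLIPH2-style clusters) and
correlates attention with residue–epitope distances from structures
(Spearman ρ, permutation test); `synthgen` generates every input with
planted, recoverable ground truth. See `docs/methods.md` for assumptions
and design choices.

## Worked example

The whole study — generate synthetic data with a planted recognition rule,
pretrain both encoders, train the head, evaluate zero-shot — is one call:

```python
from tcrbind.workflows import run_zero_shot_study

r = run_zero_shot_study(seed=1)
print(f"presentation AUC:  {r['presentation_auc']:.3f}")
print(f"zero-shot AUC-ROC: {r['pair_auc_roc']:.3f}")
print(f"zero-shot AUC-PR:  {r['pair_auc_pr']:.3f}")
```

Output (about 4 minutes on one CPU):

```
presentation AUC:  0.934
zero-shot AUC-ROC: 0.801
zero-shot AUC-PR:  0.785
```

The presentation AUC says the pMHC encoder's regression head recovers the
planted per-allele anchor rule on held-out epitopes; the pair AUCs say the
contrastive head, trained only on epitopes disjoint from the test set,
ranks true TCR-pMHC pairs above re-paired background TCRs far above chance
(0.5) under η = 0.1 label noise. Each stage is also callable on its own
(`pretrain_mlm`, `pretrain_pmhc`, `train_binder`, `rank_scores`, ...) on
your own CSV tables via `read_table`.

A command-line interface mirrors the library (`tcrbind synth`,
`pretrain-tcr`, `pretrain-pmhc`, `predict-pmhc`, `train-binder`, `rank`,
`evaluate`); each subcommand is a thin wrapper over the functions above.

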