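"""Segment-aware encoder over pseudo-sequence + epitope pairs.

Same transformer stack as the TCR encoder plus a 3-vector segment embedding
(MHC / epitope / padding) and a regression head on the pooled START state.
Training combines two objectives:

* **SMLM** — masked language modeling applied *selectively* to records where
  epitope–MHC binding occurs (MS hits, or BA records at least as strong as
  the 500 nM cutoff on the unit scale), so the model only learns to
  reconstruct residues in genuinely compatible contexts;
* **NSP** — mean-squared-error regression of the pooled representation onto
  the unit-interval binding label (continuous for BA, 0/1 for MS), through a
  logistic output so predictions stay in [0, 1].

The two losses are summed with configurable weights, 1:4 by default: the
cross-entropy term starts near ln(vocab) ≈ 3.2 while the regression term is
bounded by 0.25, so up-weighting the regression keeps the two gradient
scales comparable. The trained NSP head doubles as a presentation predictor
with no further training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .seq_codec import (PMHCRecord, TokenizedSequence, tokenize_pmhc,
                        apply_mlm_mask, IGNORE_INDEX, PMHC_MAX_LEN,
                        SEG_EPITOPE)
from .tcr_bert import (Encoder, EncoderConfig, TrainSchedule, EmbeddingMatrix,
                       AttentionProfile, _PlateauState, _lr_at, pack_batch,
                       attention_profile)


def default_pmhc_config(**overrides) -> EncoderConfig:
    base = dict(max_len=PMHC_MAX_LEN, use_segments=True)
    base.update(overrides)
    return EncoderConfig(**base)


class PMHCEncoder(Encoder):
    """Encoder with segment embeddings and an NSP regression head."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        config = config or default_pmhc_config()
        if not config.use_segments:
            raise ValueError("pMHC encoder requires use_segments=True")
        super().__init__(config, seed=seed)
        rng = np.random.default_rng(seed + 101)
        d = config.dim
        # pooler-style regression head: tanh dense, then a logistic unit
        self.params.add("nsp_h", nn.normal_init(rng, (d, d), 1 / np.sqrt(d)))
        self.params.add("nsp_h_b", np.zeros(d, dtype=nn.DTYPE))
        self.params.add("nsp_w", nn.normal_init(rng, (d, 1), 1 / np.sqrt(d)))
        self.params.add("nsp_b", np.zeros(1, dtype=nn.DTYPE))

    def nsp_scores(self, hidden: Tensor) -> Tensor:
        """Logistic binding score from the pooled START state, (B,)."""
        pooled = hidden[(np.arange(hidden.shape[0]), 0)]
        h = (pooled @ self.params["nsp_h"] + self.params["nsp_h_b"]).tanh()
        out = h @ self.params["nsp_w"] + self.params["nsp_b"]
        return out.sigmoid().reshape(-1)


@dataclass(frozen=True)
class PMHCBatch:
    """Tokenized labelled epitope–MHC examples ready for the joint loss."""

    toks: list[TokenizedSequence]
    assays: list[str]
    labels: np.ndarray          # unit interval
    binder: np.ndarray          # bool; gates selective masking

    @classmethod
    def from_records(cls, records: list[PMHCRecord],
                     max_len: int = PMHC_MAX_LEN) -> "PMHCBatch":
        return cls(
            toks=[tokenize_pmhc(r.pseudo, r.epitope, max_len) for r in records],
            assays=[r.assay for r in records],
            labels=np.array([r.label for r in records], dtype=np.float64),
            binder=np.array([r.is_binder for r in records], dtype=bool))

    def __len__(self) -> int:
        return len(self.toks)


@dataclass(frozen=True)
class PresentationScore:
    score: float

    def __post_init__(self):
        assert 0.0 <= self.score <= 1.0


def encode_pmhc(encoder: PMHCEncoder,
                tok: TokenizedSequence) -> EmbeddingMatrix:
    """Evaluation-mode contextual embedding of one pMHC input."""
    ids, segments, lengths = pack_batch([tok])
    h = encoder.forward(ids, lengths, segments)
    return EmbeddingMatrix(values=h.data[0], true_len=tok.true_len)


def pmhc_losses(encoder: PMHCEncoder, batch: PMHCBatch,
                rng: np.random.Generator | None = None, train: bool = False,
                mask_rate: float = 0.15, loss_weights: tuple[float, float] =
                (1.0, 4.0)) -> tuple[Tensor, Tensor, Tensor]:
    """Joint (ce_smlm, mse_nsp, total) over a batch.

    The SMLM term corrupts *only binder records* and runs them through
    their own forward pass; a batch with no binder yields ce_smlm = 0. The
    NSP term regresses on a separate, uncorrupted pass over the whole
    batch — masking correlates with the binding label by construction, so
    letting the regression head see corrupted inputs would leak the label
    through the MASK tokens themselves.
    """
    if not len(batch):
        raise ValueError("empty batch")
    rng = np.random.default_rng() if rng is None else rng
    segments = np.stack([t.segments for t in batch.toks])
    lengths = np.array([t.true_len for t in batch.toks])

    binder_idx = np.nonzero(batch.binder)[0]
    if len(binder_idx):
        examples = [apply_mlm_mask(batch.toks[i], rate=mask_rate, rng=rng)
                    for i in binder_idx]
        ids_m = np.stack([ex.input_ids for ex in examples])
        targets = np.stack([ex.target_ids for ex in examples])
        rows, cols = np.nonzero(targets != IGNORE_INDEX)
    else:
        rows = np.empty(0, dtype=int)
    if len(rows):
        hid_m = encoder.forward(ids_m, lengths[binder_idx],
                                segments[binder_idx], train=train, rng=rng)
        ce = nn.cross_entropy(encoder.mlm_logits(hid_m, (rows, cols)),
                              targets[rows, cols])
    else:
        ce = Tensor(0.0)

    ids = np.stack([t.ids for t in batch.toks])
    hidden = encoder.forward(ids, lengths, segments, train=train, rng=rng)
    pred = encoder.nsp_scores(hidden)
    diff = pred - Tensor(batch.labels)
    mse = (diff * diff).mean()
    total = ce * loss_weights[0] + mse * loss_weights[1]
    return ce, mse, total


def pretrain_pmhc(records: list[PMHCRecord],
                  config: EncoderConfig | None = None,
                  schedule: TrainSchedule | None = None,
                  rng: np.random.Generator | None = None,
                  loss_weights: tuple[float, float] = (1.0, 4.0)
                  ) -> tuple[PMHCEncoder, list[dict]]:
    """Joint SMLM + NSP pretraining; schedule semantics as for the TCR model.

    The combined validation loss (same 1% held-out convention) drives the
    plateau decay and early stopping.
    """
    if not records:
        raise ValueError("empty dataset")
    config = config or default_pmhc_config()
    sched = schedule or TrainSchedule()
    rng = np.random.default_rng(sched.seed) if rng is None else rng

    split_rng = np.random.default_rng(sched.seed)
    order = split_rng.permutation(len(records))
    n_val = max(1, int(round(sched.val_fraction * len(records))))
    val = PMHCBatch.from_records([records[i] for i in order[:n_val]],
                                 config.max_len)
    train_recs = [records[i] for i in order[n_val:]] or \
        [records[i] for i in order[:n_val]]
    train = PMHCBatch.from_records(train_recs, config.max_len)

    encoder = PMHCEncoder(config, seed=sched.seed)
    opt = nn.AdamW(encoder.params)
    state = _PlateauState(sched)
    history: list[dict] = []
    best_state, best_val = encoder.params.state(), np.inf
    step = 0
    for epoch in range(sched.max_epochs):
        perm = rng.permutation(len(train))
        losses = []
        for i in range(0, len(perm), sched.batch_size):
            idx = perm[i:i + sched.batch_size]
            sub = PMHCBatch(toks=[train.toks[j] for j in idx],
                            assays=[train.assays[j] for j in idx],
                            labels=train.labels[idx],
                            binder=train.binder[idx])
            encoder.params.zero_grad()
            _, _, total = pmhc_losses(encoder, sub, rng=rng, train=True,
                                      loss_weights=loss_weights)
            total.backward()
            step += 1
            opt.lr = _lr_at(step, state.scale, sched)
            opt.step()
            losses.append(float(total.data))
        val_loss = _validation_loss(encoder, val, sched, loss_weights)
        if val_loss < best_val:
            best_val, best_state = val_loss, encoder.params.state()
        state.update(val_loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "lr": opt.lr,
                        "lr_scale": state.scale})
        if state.stop:
            break
    encoder.params.load_state(best_state)
    return encoder, history


def _validation_loss(encoder: PMHCEncoder, val: PMHCBatch,
                     sched: TrainSchedule, loss_weights,
                     batch_size: int = 256) -> float:
    mrng = np.random.default_rng(sched.seed + 1)
    total, n = 0.0, 0
    for i in range(0, len(val), batch_size):
        sl = slice(i, i + batch_size)
        sub = PMHCBatch(toks=val.toks[sl], assays=val.assays[sl],
                        labels=val.labels[sl], binder=val.binder[sl])
        _, _, t = pmhc_losses(encoder, sub, rng=mrng,
                              loss_weights=loss_weights)
        total += float(t.data) * len(sub)
        n += len(sub)
    return total / n


def predict_presentation(encoder: PMHCEncoder, epitope: str,
                         pseudo: str) -> PresentationScore:
    """Epitope–MHC presentation score from the trained NSP head."""
    return PresentationScore(
        score=float(predict_presentation_batch(encoder, [(epitope, pseudo)])[0]))


def predict_presentation_batch(encoder: PMHCEncoder,
                               pairs: list[tuple[str, str]],
                               batch_size: int = 256) -> np.ndarray:
    """Vectorised presentation scores for (epitope, pseudo) pairs."""
    toks = [tokenize_pmhc(p, e, encoder.config.max_len) for e, p in pairs]
    out = []
    for i in range(0, len(toks), batch_size):
        ids, segments, lengths = pack_batch(toks[i:i + batch_size])
        hidden = encoder.forward(ids, lengths, segments)
        out.append(encoder.nsp_scores(hidden).data)
    return np.concatenate(out)


def epitope_attention_profile(encoder: PMHCEncoder, pseudo: str,
                              epitope: str,
                              mode: str = "received") -> AttentionProfile:
    """Attention importance restricted to epitope (segment-1) positions."""
    tok = tokenize_pmhc(pseudo, epitope, encoder.config.max_len)
    full = attention_profile(encoder, tok, mode=mode)
    seg = tok.segments[1:tok.true_len]       # aligns with full.scores
    sub = full.scores[seg == SEG_EPITOPE]
    return AttentionProfile(scores=sub / sub.sum())
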