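"""BERT-style encoder over CDR3β sequences and its MLM pretraining loop.

The encoder is a stack of post-layer-norm transformer blocks with learned
token and absolute-position embeddings (segment embeddings optional — used
by the pMHC variant). Pretraining is masked language modeling over a TCR
repertoire with the AdamW optimizer, linear learning-rate warmup, a
reduce-on-plateau decay and early stopping on validation loss.

Defaults follow the reference configuration: 4 layers, 256 dimensions,
8 heads; peak learning rate 5e-4, batch 512, 4000 warmup steps, decay
factor 0.3 after 2 non-improving validation epochs, early stop after 4.

Attention profiles summarise how much attention each residue *receives*,
averaged over all layers and heads, with START and padding excluded and the
result renormalised to sum to one — a per-residue importance score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor, ParamStore
from .seq_codec import (VOCAB, TokenizedSequence, MaskedExample, apply_mlm_mask,
                        tokenize_tcr, IGNORE_INDEX, TCR_MAX_LEN)

NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 4
    dim: int = 256
    n_heads: int = 8
    ff_dim: int = 1024          # 4 × dim, the standard transformer ratio
    max_len: int = TCR_MAX_LEN
    dropout: float = 0.1
    vocab_size: int = len(VOCAB)
    use_segments: bool = False  # 3 learned segment vectors (pMHC variant)

    def __post_init__(self):
        if self.dim % self.n_heads != 0:
            raise ValueError(
                f"dim {self.dim} not divisible by n_heads {self.n_heads}")
        if min(self.n_layers, self.dim, self.n_heads, self.ff_dim,
               self.max_len, self.vocab_size) <= 0:
            raise ValueError("all size fields must be positive")


@dataclass(frozen=True)
class TrainSchedule:
    peak_lr: float = 5e-4
    batch_size: int = 512
    warmup_steps: int = 4000
    plateau_factor: float = 0.3
    plateau_patience: int = 2
    max_epochs: int = 100
    early_stop_patience: int = 4
    val_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-token contextual embedding, max_len × dim."""

    values: np.ndarray
    true_len: int


@dataclass(frozen=True)
class AttentionProfile:
    """Non-negative importance per true residue, summing to one."""

    scores: np.ndarray

    def __post_init__(self):
        assert np.all(self.scores >= 0) and abs(self.scores.sum() - 1) < 1e-5


class Encoder:
    """Transformer encoder with an MLM head; parameters in a ParamStore."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        self.params = ParamStore()
        rng = np.random.default_rng(seed)
        c = config
        p = self.params
        p.add("tok_emb", nn.normal_init(rng, (c.vocab_size, c.dim)))
        p.add("pos_emb", nn.normal_init(rng, (c.max_len, c.dim)))
        if c.use_segments:
            p.add("seg_emb", nn.normal_init(rng, (3, c.dim)))
        for layer in range(c.n_layers):
            pre = f"l{layer}."
            for name in ("wq", "wk", "wv", "wo"):
                p.add(pre + name, nn.normal_init(rng, (c.dim, c.dim)))
                p.add(pre + name + "_b", np.zeros(c.dim, dtype=nn.DTYPE))
            p.add(pre + "ln1_g", np.ones(c.dim, dtype=nn.DTYPE))
            p.add(pre + "ln1_b", np.zeros(c.dim, dtype=nn.DTYPE))
            p.add(pre + "ff1", nn.normal_init(rng, (c.dim, c.ff_dim)))
            p.add(pre + "ff1_b", np.zeros(c.ff_dim, dtype=nn.DTYPE))
            p.add(pre + "ff2", nn.normal_init(rng, (c.ff_dim, c.dim)))
            p.add(pre + "ff2_b", np.zeros(c.dim, dtype=nn.DTYPE))
            p.add(pre + "ln2_g", np.ones(c.dim, dtype=nn.DTYPE))
            p.add(pre + "ln2_b", np.zeros(c.dim, dtype=nn.DTYPE))
        p.add("mlm_w", nn.normal_init(rng, (c.dim, c.vocab_size)))
        p.add("mlm_b", np.zeros(c.vocab_size, dtype=nn.DTYPE))

    # -- forward --------------------------------------------------------

    def forward(self, ids: np.ndarray, lengths: np.ndarray,
                segments: np.ndarray | None = None, train: bool = False,
                rng: np.random.Generator | None = None,
                collect_attention: bool = False,
                depth: int | None = None) -> Tensor:
        """Encode a batch; returns hidden states (B, max_len, dim).

        Padding positions (index >= length) are masked out of attention so
        their content cannot influence true positions. When
        `collect_attention` is set, per-layer softmax attention matrices
        (B, heads, L, L) are stored on `self.last_attention`. `depth`
        truncates the stack to its first `depth` layers (None = all) —
        downstream feature extraction conventionally reads the penultimate
        layer, whose representations are less specialised to the
        pretraining head than the final one.
        """
        c, p = self.config, self.params
        depth = c.n_layers if depth is None else depth
        if not 0 <= depth <= c.n_layers:
            raise ValueError(f"depth {depth} outside [0, {c.n_layers}]")
        B, L = ids.shape
        if L != c.max_len:
            raise ValueError(f"sequence length {L} != max_len {c.max_len}")
        positions = np.broadcast_to(np.arange(L), (B, L))
        x = nn.embedding(p["tok_emb"], ids) + nn.embedding(p["pos_emb"],
                                                           positions)
        if c.use_segments:
            if segments is None:
                raise ValueError("segment-aware encoder needs segment ids")
            x = x + nn.embedding(p["seg_emb"], segments)
        key_mask = np.arange(L)[None, :] < lengths[:, None]   # (B, L)
        bias = np.where(key_mask, 0.0, NEG_INF).astype(nn.DTYPE)
        bias = bias[:, None, None, :]                          # (B,1,1,L)
        self.last_attention: list[np.ndarray] = []
        H, dh = c.n_heads, c.dim // c.n_heads
        scale = 1.0 / np.sqrt(dh)
        for layer in range(depth):
            pre = f"l{layer}."
            def proj(name):
                h = x @ p[pre + name] + p[pre + name + "_b"]
                return h.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
            q, k, v = proj("wq"), proj("wk"), proj("wv")
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale
            probs = nn.softmax(scores, bias=bias)
            if collect_attention:
                self.last_attention.append(probs.data.copy())
            probs = nn.dropout(probs, c.dropout, rng, train)
            ctx = (probs @ v).transpose(0, 2, 1, 3).reshape(B, L, c.dim)
            ctx = ctx @ p[pre + "wo"] + p[pre + "wo_b"]
            ctx = nn.dropout(ctx, c.dropout, rng, train)
            x = nn.layer_norm(x + ctx, p[pre + "ln1_g"], p[pre + "ln1_b"])
            h = (x @ p[pre + "ff1"] + p[pre + "ff1_b"]).gelu()
            h = h @ p[pre + "ff2"] + p[pre + "ff2_b"]
            h = nn.dropout(h, c.dropout, rng, train)
            x = nn.layer_norm(x + h, p[pre + "ln2_g"], p[pre + "ln2_b"])
        return x

    def mlm_logits(self, hidden: Tensor, positions) -> Tensor:
        """Project hidden states at (batch_idx, pos_idx) onto the vocabulary."""
        sel = hidden[positions]
        return sel @ self.params["mlm_w"] + self.params["mlm_b"]


def init_encoder(config: EncoderConfig | None = None, seed: int = 0) -> Encoder:
    """Randomly initialise an encoder; bit-reproducible per seed."""
    return Encoder(config or EncoderConfig(), seed=seed)


def pack_batch(toks: list[TokenizedSequence]):
    """Stack tokenized sequences into (ids, segments, lengths) arrays."""
    ids = np.stack([t.ids for t in toks])
    segments = np.stack([t.segments for t in toks])
    lengths = np.array([t.true_len for t in toks])
    return ids, segments, lengths


def encode(encoder: Encoder, tok: TokenizedSequence) -> EmbeddingMatrix:
    """Contextual embedding of one sequence (evaluation mode)."""
    ids, segments, lengths = pack_batch([tok])
    h = encoder.forward(ids, lengths,
                        segments if encoder.config.use_segments else None)
    return EmbeddingMatrix(values=h.data[0], true_len=tok.true_len)


def encode_batch(encoder: Encoder, toks: list[TokenizedSequence],
                 batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode embeddings for many sequences, (N, max_len, dim)."""
    out = []
    for i in range(0, len(toks), batch_size):
        ids, segments, lengths = pack_batch(toks[i:i + batch_size])
        h = encoder.forward(
            ids, lengths, segments if encoder.config.use_segments else None)
        out.append(h.data)
    return np.concatenate(out)


def mlm_loss(encoder: Encoder, batch: list[MaskedExample],
             lengths: np.ndarray, segments: np.ndarray | None = None,
             train: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
    """Mean cross-entropy over masked positions; 0 if nothing is masked."""
    if not batch:
        raise ValueError("empty batch")
    ids = np.stack([ex.input_ids for ex in batch])
    targets = np.stack([ex.target_ids for ex in batch])
    rows, cols = np.nonzero(targets != IGNORE_INDEX)
    if len(rows) == 0:
        return Tensor(0.0)
    hidden = encoder.forward(ids, lengths, segments, train=train, rng=rng)
    logits = encoder.mlm_logits(hidden, (rows, cols))
    return nn.cross_entropy(logits, targets[rows, cols])


def _lr_at(step: int, epoch_scale: float, sched: TrainSchedule) -> float:
    warm = min(1.0, step / sched.warmup_steps) if sched.warmup_steps else 1.0
    return sched.peak_lr * warm * epoch_scale


class _PlateauState:
    """Reduce-on-plateau + early-stop bookkeeping shared by all trainers."""

    def __init__(self, sched: TrainSchedule):
        self.sched = sched
        self.best = np.inf
        self.bad_epochs = 0
        self.scale = 1.0
        self.stop = False

    def update(self, val_loss: float) -> None:
        if val_loss < self.best - 1e-7:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs % self.sched.plateau_patience == 0:
                self.scale *= self.sched.plateau_factor
            if self.bad_epochs >= self.sched.early_stop_patience:
                self.stop = True


def pretrain_mlm(corpus: list[str], config: EncoderConfig | None = None,
                 schedule: TrainSchedule | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Encoder, list[dict]]:
    """Pretrain a TCR encoder by masked language modeling.

    A random `val_fraction` of the corpus (≥ 1 sequence, fixed by
    schedule.seed) is held out; its loss drives the plateau decay and early
    stopping. Returns the trained encoder and a per-epoch history of
    losses and learning rate.
    """
    if not corpus:
        raise ValueError("empty corpus")
    config = config or EncoderConfig()
    sched = schedule or TrainSchedule()
    rng = np.random.default_rng(sched.seed) if rng is None else rng
    toks = [tokenize_tcr(s, config.max_len) for s in corpus]

    split_rng = np.random.default_rng(sched.seed)
    order = split_rng.permutation(len(toks))
    n_val = max(1, int(round(sched.val_fraction * len(toks))))
    val_toks = [toks[i] for i in order[:n_val]]
    train_toks = [toks[i] for i in order[n_val:]] or val_toks

    encoder = Encoder(config, seed=sched.seed)
    opt = nn.AdamW(encoder.params)
    state = _PlateauState(sched)
    history: list[dict] = []
    best_state, best_val = encoder.params.state(), np.inf
    step = 0
    for epoch in range(sched.max_epochs):
        perm = rng.permutation(len(train_toks))
        losses = []
        for i in range(0, len(perm), sched.batch_size):
            chunk = [train_toks[j] for j in perm[i:i + sched.batch_size]]
            examples = [apply_mlm_mask(t, rng=rng) for t in chunk]
            lengths = np.array([t.true_len for t in chunk])
            encoder.params.zero_grad()
            loss = mlm_loss(encoder, examples, lengths, train=True, rng=rng)
            if loss._parents:
                loss.backward()
                step += 1
                opt.lr = _lr_at(step, state.scale, sched)
                opt.step()
            losses.append(float(loss.data))
        val_loss = _validation_mlm_loss(encoder, val_toks, sched)
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


def _validation_mlm_loss(encoder: Encoder, val_toks, sched: TrainSchedule,
                         batch_size: int = 256) -> float:
    # fixed masking rng so epochs are compared on identical corruption
    mrng = np.random.default_rng(sched.seed + 1)
    total, n = 0.0, 0
    for i in range(0, len(val_toks), batch_size):
        chunk = val_toks[i:i + batch_size]
        examples = [apply_mlm_mask(t, rng=mrng) for t in chunk]
        lengths = np.array([t.true_len for t in chunk])
        loss = mlm_loss(encoder, examples, lengths)
        total += float(loss.data) * len(chunk)
        n += len(chunk)
    return total / n


def attention_profile(encoder: Encoder, seq: str | TokenizedSequence,
                      mode: str = "received") -> AttentionProfile:
    """Per-residue attention importance for one sequence.

    ``received`` (default) scores residue j by the attention mass flowing
    *into* it (column sums over true-query rows); ``emitted`` scores
    residue i by summing its outgoing row. Either way the score is averaged
    over all layers and heads, START and padding are excluded, and the
    result is renormalised to sum to one.
    """
    tok = tokenize_tcr(seq, encoder.config.max_len) if isinstance(seq, str) \
        else seq
    ids, segments, lengths = pack_batch([tok])
    encoder.forward(ids, lengths,
                    segments if encoder.config.use_segments else None,
                    collect_attention=True)
    att = np.stack(encoder.last_attention)[:, 0]   # (layers, H, L, L)
    n = tok.true_len
    sub = att[:, :, :n, :n]
    if mode == "received":
        raw = sub.sum(axis=2).mean(axis=(0, 1))    # column sums
    elif mode == "emitted":
        raw = sub.sum(axis=3).mean(axis=(0, 1))    # row sums
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    scores = raw[1:]                                # drop START
    return AttentionProfile(scores=scores / scores.sum())


# -- checkpointing -------------------------------------------------------


def save_checkpoint(encoder: Encoder, path, history: list[dict] | None = None
                    ) -> None:
    """Write weights (.npz) plus a JSON sidecar with config and history."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **encoder.params.state())
    side = {"config": asdict(encoder.config),
            "vocab": list(VOCAB.tokens),
            "history": history or []}
    with open(path.removesuffix(".npz") + ".json", "w") as fh:
        json.dump(side, fh, indent=1)


def load_checkpoint(path) -> tuple[Encoder, list[dict]]:
    path = str(path).removesuffix(".npz")
    with open(path + ".json") as fh:
        side = json.load(fh)
    if tuple(side["vocab"]) != VOCAB.tokens:
        raise ValueError("checkpoint vocabulary differs from current build")
    with np.load(path + ".npz") as npz:
        state = {k: npz[k] for k in npz.files}
    config = EncoderConfig(**side["config"])
    if "nsp_w" in state:   # pMHC checkpoint with regression head
        from .pmhc_bert import PMHCEncoder
        enc: Encoder = PMHCEncoder(config)
    else:
        enc = Encoder(config)
    enc.params.load_state(state)
    return enc, side["history"]
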