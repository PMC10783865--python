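"""TCR-pMHC prediction head over frozen encoder embeddings.

Four bias-free mapping layers compress each modality's embedding matrix
(length L × dim D) into two vectors — a length-L view (each position scored
by a learned weighting over dimensions) and a length-D view (each dimension
scored by a learned weighting over positions). The four vectors are
concatenated and fed to an MLP (200 → 100 → 50 ReLU units, dropout 0.4,
single tanh output), so the pair score f lies in (−1, 1).

Training is contrastive and Siamese: a positive and a negative pair pass
through the same weights and the margin loss

    loss = Relu(1 + f⁻ − f⁺) + 0.2·(f⁻² + f⁺²)

pushes positives above negatives with an L2 pull toward zero. Negatives are
built by re-pairing positive pMHCs with TCRs drawn from a healthy background
repertoire, resampled every epoch. Encoders stay frozen throughout: their
embeddings are computed once and cached, with padding rows zeroed.

The deployable output is a percentile rank score: the candidate's f ranked
(midrank ties) against the same pMHC paired with n background TCRs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor, ParamStore
from .seq_codec import PairRecord, tokenize_tcr, tokenize_pmhc
from .tcr_bert import Encoder, TrainSchedule, EmbeddingMatrix, pack_batch
from .pmhc_bert import PMHCEncoder

MLP_WIDTHS = (200, 100, 50)
MLP_DROPOUT = 0.4


def default_binder_schedule(**overrides) -> TrainSchedule:
    """Contrastive-head schedule: lr 0.005, batch 256, early stop at 6."""
    base = dict(peak_lr=0.005, batch_size=256, warmup_steps=100,
                early_stop_patience=6, val_fraction=0.05)
    base.update(overrides)
    return TrainSchedule(**base)


@dataclass(frozen=True)
class PairScore:
    f: float
    role: str = "candidate"     # "positive" / "negative" during training

    def __post_init__(self):
        assert -1.0 < self.f < 1.0


@dataclass(frozen=True)
class RankScore:
    value: float
    n: int

    def __post_init__(self):
        assert 0.0 <= self.value <= 1.0


class BinderModel:
    """Mapping layers + MLP head bound to a frozen encoder pair."""

    def __init__(self, tcr_encoder: Encoder, pmhc_encoder: PMHCEncoder,
                 seed: int = 0, feature_depth: str = "penultimate"):
        if feature_depth not in ("penultimate", "final"):
            raise ValueError(f"unknown feature_depth {feature_depth!r}")
        self.tcr_encoder = tcr_encoder
        self.pmhc_encoder = pmhc_encoder
        self.feature_depth = feature_depth
        self.params = ParamStore()
        rng = np.random.default_rng(seed)
        lt, dt = tcr_encoder.config.max_len, tcr_encoder.config.dim
        lp, dp = pmhc_encoder.config.max_len, pmhc_encoder.config.dim
        # rank-1 mapping weights, no bias
        self.params.add("tcr_w_dim", nn.normal_init(rng, (dt, 1), 1 / np.sqrt(dt)))
        self.params.add("tcr_w_len", self._positional_init(lt, 11.0, rng))
        self.params.add("pmhc_w_dim", nn.normal_init(rng, (dp, 1), 1 / np.sqrt(dp)))
        self.params.add("pmhc_w_len", self._positional_init(lp, 40.0, rng))
        widths = (lt + dt + lp + dp,) + MLP_WIDTHS
        for i in range(len(MLP_WIDTHS)):
            std = np.sqrt(2.0 / widths[i])
            self.params.add(f"mlp{i}_w", nn.normal_init(rng, widths[i:i + 2], std))
            self.params.add(f"mlp{i}_b", np.zeros(widths[i + 1], dtype=nn.DTYPE))
        self.params.add("out_w", nn.normal_init(
            rng, (MLP_WIDTHS[-1], 1), 1.0 / np.sqrt(MLP_WIDTHS[-1])))
        self.params.add("out_b", np.zeros(1, dtype=nn.DTYPE))
        self._tcr_cache: dict[str, np.ndarray] = {}
        self._pmhc_cache: dict[tuple[str, str], np.ndarray] = {}

    @staticmethod
    def _positional_init(length: int, center: float,
                         rng: np.random.Generator) -> np.ndarray:
        """Gaussian bump over positions, plus noise.

        The position-mapping weights start centred where the contact
        residues live — the CDR3β apex for TCRs, the epitope block for
        pMHC inputs — a structural prior that speeds up and stabilises
        contrastive training without constraining what the weights can
        become.
        """
        i = np.arange(length, dtype=np.float64)
        bump = np.exp(-((i - center) ** 2) / 32.0)
        bump /= np.linalg.norm(bump)
        noise = rng.standard_normal(length) * 0.02
        return (bump + noise).astype(nn.DTYPE)[:, None]

    # -- frozen-embedding caches ----------------------------------------

    def _cache_embeddings(self, encoder, keys, toks, cache, batch_size=256):
        missing = [i for i, k in enumerate(keys) if k not in cache]
        # penultimate-layer features: the final layer is specialised to the
        # pretraining head, the layer below transfers better when frozen
        depth = max(1, encoder.config.n_layers - 1) \
            if self.feature_depth == "penultimate" else None
        for i in range(0, len(missing), batch_size):
            idx = missing[i:i + batch_size]
            ids, segments, lengths = pack_batch([toks[j] for j in idx])
            h = encoder.forward(
                ids, lengths,
                segments if encoder.config.use_segments else None,
                depth=depth).data
            for row, j in enumerate(idx):
                e = h[row].copy()
                e[lengths[row]:] = 0.0      # zero padding rows by contract
                cache[keys[j]] = e

    def tcr_embeddings(self, cdr3bs: list[str]) -> np.ndarray:
        uniq = sorted(set(cdr3bs))
        toks = [tokenize_tcr(s, self.tcr_encoder.config.max_len)
                for s in uniq]
        self._cache_embeddings(self.tcr_encoder, uniq, toks, self._tcr_cache)
        return np.stack([self._tcr_cache[s] for s in cdr3bs])

    def pmhc_embeddings(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """pairs = (epitope, pseudo) tuples."""
        uniq = sorted(set(pairs))
        toks = [tokenize_pmhc(p, e, self.pmhc_encoder.config.max_len)
                for e, p in uniq]
        self._cache_embeddings(self.pmhc_encoder, uniq, toks,
                               self._pmhc_cache)
        return np.stack([self._pmhc_cache[k] for k in pairs])

    # -- forward --------------------------------------------------------

    def _features(self, e_tcr: Tensor, e_pmhc: Tensor) -> Tensor:
        p = self.params
        vt_len = (e_tcr @ p["tcr_w_dim"]).reshape(e_tcr.shape[0], -1)
        vt_dim = (e_tcr.transpose(0, 2, 1) @ p["tcr_w_len"]
                  ).reshape(e_tcr.shape[0], -1)
        vp_len = (e_pmhc @ p["pmhc_w_dim"]).reshape(e_pmhc.shape[0], -1)
        vp_dim = (e_pmhc.transpose(0, 2, 1) @ p["pmhc_w_len"]
                  ).reshape(e_pmhc.shape[0], -1)
        return nn.concat([vt_len, vt_dim, vp_len, vp_dim], axis=-1)

    def forward_scores(self, e_tcr: np.ndarray, e_pmhc: np.ndarray,
                       train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Pair scores f ∈ (−1,1) for matched embedding batches, (B,)."""
        p = self.params
        h = self._features(Tensor(e_tcr), Tensor(e_pmhc))
        for i in range(len(MLP_WIDTHS)):
            h = (h @ p[f"mlp{i}_w"] + p[f"mlp{i}_b"]).relu()
            h = nn.dropout(h, MLP_DROPOUT, rng, train)
        return (h @ p["out_w"] + p["out_b"]).tanh().reshape(-1)

    def score_many(self, records: list[PairRecord],
                   batch_size: int = 512) -> np.ndarray:
        """Evaluation-mode f for many pair records."""
        out = []
        for i in range(0, len(records), batch_size):
            chunk = records[i:i + batch_size]
            e_t = self.tcr_embeddings([r.cdr3b for r in chunk])
            e_p = self.pmhc_embeddings([(r.epitope, r.pseudo) for r in chunk])
            out.append(self.forward_scores(e_t, e_p).data)
        return np.concatenate(out)


def map_embeddings(model: BinderModel, E: EmbeddingMatrix, modality: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Compress one embedding matrix into its (v_len, v_dim) vector pair.

    v_len[i] = ⟨row i of E, w_dim⟩ and v_dim[j] = ⟨column j of E, w_len⟩,
    with padding rows zeroed first; bias-free by construction.
    """
    if modality not in ("tcr", "pmhc"):
        raise ValueError(f"unknown modality {modality!r}")
    vals = E.values.copy()
    vals[E.true_len:] = 0.0
    w_dim = model.params[f"{modality}_w_dim"].data[:, 0]
    w_len = model.params[f"{modality}_w_len"].data[:, 0]
    if vals.shape != (len(w_len), len(w_dim)):
        raise ValueError(
            f"embedding shape {vals.shape} does not match {modality} mapping "
            f"({len(w_len)}, {len(w_dim)})")
    return vals @ w_dim, vals.T @ w_len


def score_pair(model: BinderModel, tcr_tok, pmhc_tok) -> PairScore:
    """Deterministic evaluation-mode score for one TCR-pMHC pair."""
    from .seq_codec import detokenize, detokenize_pmhc
    cdr3b = detokenize(tcr_tok)
    pseudo, epitope = detokenize_pmhc(pmhc_tok)
    rec = PairRecord(cdr3b=cdr3b, epitope=epitope, pseudo=pseudo, label=1)
    return PairScore(f=float(model.score_many([rec])[0]))


def contrast_loss(f_plus, f_minus) -> float:
    """Margin loss Relu(1 + f⁻ − f⁺) + 0.2·(f⁻² + f⁺²)."""
    fp = f_plus.f if isinstance(f_plus, PairScore) else float(f_plus)
    fm = f_minus.f if isinstance(f_minus, PairScore) else float(f_minus)
    return max(0.0, 1.0 + fm - fp) + 0.2 * (fm * fm + fp * fp)


def _contrast_loss_t(f_plus: Tensor, f_minus: Tensor) -> Tensor:
    margin = (1.0 + f_minus - f_plus).relu()
    return (margin + 0.2 * (f_minus * f_minus + f_plus * f_plus)).mean()


def sample_negatives(positives: list[PairRecord], pool: list[str],
                     ratio: float = 1.0,
                     rng: np.random.Generator | None = None,
                     max_tries: int = 50) -> list[PairRecord]:
    """Re-pair positive pMHCs with background TCRs to build negatives.

    Each negative takes its pMHC from the positives' pMHC multiset and its
    TCR uniformly from the healthy pool; draws colliding with a known
    positive pair are resampled.
    """
    if not pool:
        raise ValueError("empty background pool")
    rng = np.random.default_rng() if rng is None else rng
    known = {(r.cdr3b, r.epitope, r.pseudo) for r in positives}
    n = int(round(ratio * len(positives)))
    out: list[PairRecord] = []
    for _ in range(n):
        for _try in range(max_tries):
            pos = positives[rng.integers(len(positives))]
            tcr = pool[rng.integers(len(pool))]
            if (tcr, pos.epitope, pos.pseudo) not in known:
                out.append(PairRecord(cdr3b=tcr, epitope=pos.epitope,
                                      pseudo=pos.pseudo, label=0))
                break
        else:
            raise ValueError("could not draw a non-positive negative")
    return out


def _epitope_stratified_split(positives: list[PairRecord], fraction: float,
                              seed: int) -> tuple[list[PairRecord],
                                                  list[PairRecord]]:
    """Hold out ~fraction of positives, sampling within each epitope."""
    rng = np.random.default_rng(seed)
    by_ep: dict[str, list[int]] = {}
    for i, r in enumerate(positives):
        by_ep.setdefault(r.epitope, []).append(i)
    val_idx: set[int] = set()
    for idx in by_ep.values():
        k = int(round(fraction * len(idx)))
        if k:
            val_idx.update(rng.choice(idx, size=k, replace=False).tolist())
    if not val_idx:   # tiny sets: hold out one pair
        val_idx.add(int(rng.integers(len(positives))))
    train = [r for i, r in enumerate(positives) if i not in val_idx]
    val = [r for i, r in enumerate(positives) if i in val_idx]
    return train, val


def train_binder(pairs: list[PairRecord], pool: list[str],
                 tcr_encoder: Encoder, pmhc_encoder: PMHCEncoder,
                 schedule: TrainSchedule | None = None,
                 rng: np.random.Generator | None = None,
                 negative_ratio: float = 1.0
                 ) -> tuple[BinderModel, list[dict]]:
    """Contrastive Siamese training of the prediction head.

    Only the mapping layers and the MLP receive gradients; encoder weights
    are used purely through cached evaluation-mode embeddings and are
    bit-identical before and after. Negatives are redrawn from the pool
    every epoch; a 5% epitope-stratified positive split (with fixed matched
    negatives) provides the validation loss for plateau decay and early
    stopping.
    """
    positives = [r for r in pairs if r.label == 1]
    if not positives:
        raise ValueError("no positive pairs")
    sched = schedule or default_binder_schedule()
    rng = np.random.default_rng(sched.seed) if rng is None else rng
    model = BinderModel(tcr_encoder, pmhc_encoder, seed=sched.seed)
    # no decoupled weight decay on the head: the contrastive loss already
    # carries an explicit L2 pull (0.2·f²), and decay on top slows it
    opt = nn.AdamW(model.params, weight_decay=0.0)

    train_pos, val_pos = _epitope_stratified_split(
        positives, sched.val_fraction, sched.seed)
    if not train_pos:
        train_pos = val_pos
    val_neg = sample_negatives(val_pos, pool, negative_ratio,
                               np.random.default_rng(sched.seed + 1))

    # warm the caches once, in bulk
    model.tcr_embeddings([r.cdr3b for r in positives] + list(pool))
    model.pmhc_embeddings([(r.epitope, r.pseudo) for r in positives])

    from .tcr_bert import _PlateauState, _lr_at
    state = _PlateauState(sched)
    history: list[dict] = []
    best_state = model.params.state()
    best_val = np.inf
    step = 0
    for epoch in range(sched.max_epochs):
        negatives = sample_negatives(train_pos, pool, negative_ratio, rng)
        perm = rng.permutation(len(train_pos))
        losses = []
        for i in range(0, len(perm), sched.batch_size):
            idx = perm[i:i + sched.batch_size]
            pos = [train_pos[j] for j in idx]
            neg = [negatives[j % len(negatives)] for j in idx]
            e_tp = model.tcr_embeddings([r.cdr3b for r in pos])
            e_pp = model.pmhc_embeddings([(r.epitope, r.pseudo) for r in pos])
            e_tn = model.tcr_embeddings([r.cdr3b for r in neg])
            e_pn = model.pmhc_embeddings([(r.epitope, r.pseudo) for r in neg])
            model.params.zero_grad()
            f_plus = model.forward_scores(e_tp, e_pp, train=True, rng=rng)
            f_minus = model.forward_scores(e_tn, e_pn, train=True, rng=rng)
            loss = _contrast_loss_t(f_plus, f_minus)
            loss.backward()
            step += 1
            opt.lr = _lr_at(step, state.scale, sched)
            opt.step()
            losses.append(float(loss.data))
        val_loss = _binder_validation_loss(model, val_pos, val_neg)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.params.state()
        state.update(val_loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "lr": opt.lr,
                        "lr_scale": state.scale})
        if state.stop:
            break
    model.params.load_state(best_state)   # restore the best-validation epoch
    return model, history


def _binder_validation_loss(model: BinderModel, val_pos, val_neg) -> float:
    fp = model.score_many(val_pos)
    fm = model.score_many([val_neg[i % len(val_neg)]
                           for i in range(len(val_pos))])
    return float(np.mean(np.maximum(0.0, 1.0 + fm - fp)
                         + 0.2 * (fm ** 2 + fp ** 2)))


def rank_score(model: BinderModel, pair: PairRecord, pool: list[str],
               n: int = 1000, rng: np.random.Generator | None = None
               ) -> RankScore:
    """Percentile rank of a candidate against n background TCRs.

    The candidate and n pool TCRs (drawn without replacement) are scored
    against the same pMHC; rank = (#{f_bg < f_cand} + ½·ties) / n.
    """
    return rank_scores(model, [pair], pool, n=n, rng=rng)[0]


def rank_scores(model: BinderModel, pairs: list[PairRecord],
                pool: list[str], n: int = 1000,
                rng: np.random.Generator | None = None) -> list[RankScore]:
    """Percentile ranks for many candidates, sharing one background draw."""
    if len(pool) < n:
        raise ValueError(f"pool size {len(pool)} < background size {n}")
    rng = np.random.default_rng() if rng is None else rng
    background = [pool[i] for i in rng.choice(len(pool), size=n,
                                              replace=False)]
    model.tcr_embeddings(background + [r.cdr3b for r in pairs])
    out = []
    for pair in pairs:
        f_cand = float(model.score_many([pair])[0])
        bg = [replace(pair, cdr3b=t, label=0) for t in background]
        f_bg = model.score_many(bg)
        below = int(np.sum(f_bg < f_cand))
        ties = int(np.sum(f_bg == f_cand))
        out.append(RankScore(value=(below + 0.5 * ties) / n, n=n))
    return out
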