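"""Encoder structure: shapes, masking, determinism, schedules, attention."""

import numpy as np
import pytest

from tcrbind import (EncoderConfig, TrainSchedule, attention_profile, encode,
                     init_encoder, mlm_loss, pretrain_mlm, tokenize_tcr,
                     apply_mlm_mask, save_checkpoint, load_checkpoint)
from tcrbind.seq_codec import VOCAB
from tcrbind.tcr_bert import _PlateauState, _lr_at
from tcrbind.synthgen import gen_tcr_repertoire


def _param_count(c: EncoderConfig, nsp: bool = False) -> int:
    """Closed-form parameter count implied by the config."""
    emb = c.vocab_size * c.dim + c.max_len * c.dim
    if c.use_segments:
        emb += 3 * c.dim
    per_layer = (4 * (c.dim * c.dim + c.dim)        # q, k, v, out proj
                 + 2 * 2 * c.dim                    # two layer norms
                 + c.dim * c.ff_dim + c.ff_dim      # ffn in
                 + c.ff_dim * c.dim + c.dim)        # ffn out
    head = c.dim * c.vocab_size + c.vocab_size
    total = emb + c.n_layers * per_layer + head
    if nsp:
        total += c.dim * c.dim + c.dim + c.dim + 1
    return total


class TestInitEncoder:
    def test_default_config_is_reference_architecture(self):
        c = EncoderConfig()
        assert (c.n_layers, c.dim, c.n_heads) == (4, 256, 8)
        assert c.ff_dim == 4 * c.dim

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(dim=65, n_heads=8)

    def test_same_seed_bit_identical(self, tiny_tcr_config):
        a = init_encoder(tiny_tcr_config, seed=9)
        b = init_encoder(tiny_tcr_config, seed=9)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    @pytest.mark.parametrize("cfg", [
        EncoderConfig(n_layers=2, dim=64, n_heads=4, ff_dim=256),
        EncoderConfig(n_layers=1, dim=32, n_heads=2, ff_dim=64, max_len=16),
    ])
    def test_parameter_count_closed_form(self, cfg):
        assert init_encoder(cfg).params.n_params() == _param_count(cfg)


class TestEncode:
    def test_output_shape(self, tcr_encoder):
        em = encode(tcr_encoder, tokenize_tcr("CASSLGQAYEQYF"))
        assert em.values.shape == (32, 64)
        assert np.all(np.isfinite(em.values))

    def test_eval_mode_deterministic(self, tcr_encoder):
        tok = tokenize_tcr("CASSLGQAYEQYF")
        a, b = encode(tcr_encoder, tok), encode(tcr_encoder, tok)
        assert np.array_equal(a.values, b.values)

    def test_pad_positions_cannot_leak(self, tcr_encoder, rng):
        """True-position embeddings are invariant to pad-content changes."""
        tok = tokenize_tcr("CASSLGQAYEQYF")
        base = encode(tcr_encoder, tok).values[:tok.true_len]
        ids = tok.ids.copy()
        ids[tok.true_len:] = rng.choice(VOCAB.aa_ids, 32 - tok.true_len)
        perturbed = type(tok)(ids=ids, segments=tok.segments,
                              true_len=tok.true_len)
        after = encode(tcr_encoder, perturbed).values[:tok.true_len]
        assert np.max(np.abs(after - base)) < 1e-5


class TestMlmLoss:
    def test_uniform_logits_give_log_vocab(self, tiny_tcr_config):
        enc = init_encoder(tiny_tcr_config, seed=0)
        enc.params["mlm_w"].data[...] = 0.0   # uniform output distribution
        enc.params["mlm_b"].data[...] = 0.0
        toks = [tokenize_tcr("CASSLGQAYEQYF"), tokenize_tcr("CASSIRSSYEQYFF")]
        rng = np.random.default_rng(0)
        batch = [apply_mlm_mask(t, 0.5, rng) for t in toks]
        lengths = np.array([t.true_len for t in toks])
        loss = mlm_loss(enc, batch, lengths)
        assert float(loss.data) == pytest.approx(np.log(24), abs=1e-3)

    def test_zero_masked_positions_yield_zero(self, tcr_encoder):
        toks = [tokenize_tcr("CASSLGQAYEQYF")]
        batch = [apply_mlm_mask(toks[0], 0.0, np.random.default_rng(0))]
        loss = mlm_loss(tcr_encoder, batch, np.array([toks[0].true_len]))
        assert float(loss.data) == 0.0

    def test_loss_non_negative(self, tcr_encoder, rng):
        toks = [tokenize_tcr("CASSLGQAYEQYF")]
        batch = [apply_mlm_mask(toks[0], 0.3, rng)]
        loss = mlm_loss(tcr_encoder, batch, np.array([toks[0].true_len]))
        assert float(loss.data) >= 0.0


class TestSchedule:
    def test_linear_warmup_midpoint(self):
        sched = TrainSchedule(peak_lr=0.0005, warmup_steps=4000)
        assert _lr_at(2000, 1.0, sched) == pytest.approx(0.00025)
        assert _lr_at(4000, 1.0, sched) == pytest.approx(0.0005)
        assert _lr_at(8000, 1.0, sched) == pytest.approx(0.0005)

    def test_plateau_decay_after_two_bad_epochs(self):
        """lr × 0.3 once validation stalls for 2 consecutive epochs."""
        sched = TrainSchedule(plateau_factor=0.3, plateau_patience=2,
                              early_stop_patience=4)
        st = _PlateauState(sched)
        st.update(1.0)
        assert st.scale == 1.0
        st.update(1.1)
        assert st.scale == 1.0
        st.update(1.2)
        assert st.scale == pytest.approx(0.3)
        st.update(1.3)
        assert not st.stop
        st.update(1.4)   # 4th consecutive non-improving epoch
        assert st.stop

    def test_improvement_resets_counters(self):
        st = _PlateauState(TrainSchedule())
        st.update(1.0)
        st.update(1.5)
        st.update(0.5)
        assert st.bad_epochs == 0 and not st.stop

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            TrainSchedule(plateau_factor=1.5)
        with pytest.raises(ValueError):
            TrainSchedule(plateau_patience=0)


class TestPretrain:
    def test_motif_corpus_learns_above_chance(self):
        """Masked motif residues are recovered above the 1/20 chance level."""
        motifs = ["WQDRW", "YHFDY", "MKWPM"]
        seqs, anns = gen_tcr_repertoire(1200, motifs, planted_rate=0.7,
                                        seed=3)
        cfg = EncoderConfig(n_layers=2, dim=32, n_heads=4, ff_dim=64)
        sched = TrainSchedule(batch_size=64, warmup_steps=10, max_epochs=2,
                              seed=3)
        enc, hist = pretrain_mlm(seqs, cfg, sched)
        assert hist[-1]["val_loss"] < hist[0]["val_loss"] + 0.05
        # mask a motif position and check recovery accuracy
        hits = total = 0
        for ann in anns[:150]:
            tok = tokenize_tcr(ann.seq_id)
            pos = ann.positions[len(ann.positions) // 2] + 1   # +1 for START
            ids = tok.ids.copy()
            true_id = ids[pos]
            ids[pos] = VOCAB.mask_id
            lengths = np.array([tok.true_len])
            hidden = enc.forward(ids[None, :], lengths)
            logits = enc.mlm_logits(hidden, (np.array([0]), np.array([pos])))
            hits += int(np.argmax(logits.data[0]) == true_id)
            total += 1
        assert hits / total > 1 / 20

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain_mlm([], EncoderConfig(), TrainSchedule())


class TestAttentionProfile:
    def test_sums_to_one_and_matches_length(self, tcr_encoder):
        prof = attention_profile(tcr_encoder, "CASSLGQAYEQYF")
        assert len(prof.scores) == 13
        assert prof.scores.sum() == pytest.approx(1.0, abs=1e-5)
        assert np.all(prof.scores >= 0)

    def test_uniform_attention_gives_uniform_profile(self):
        """Identical token embeddings ⇒ symmetric attention ⇒ flat profile."""
        cfg = EncoderConfig(n_layers=1, dim=16, n_heads=1, ff_dim=16)
        enc = init_encoder(cfg, seed=0)
        enc.params["tok_emb"].data[...] = 0.05
        enc.params["pos_emb"].data[...] = 0.0
        prof = attention_profile(enc, "CASSLGQAYEQYF")
        assert np.allclose(prof.scores, 1 / 13, atol=1e-6)

    def test_deterministic(self, tcr_encoder):
        a = attention_profile(tcr_encoder, "CASSLGQAYEQYF")
        b = attention_profile(tcr_encoder, "CASSLGQAYEQYF")
        assert np.array_equal(a.scores, b.scores)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tcr_encoder):
        path = tmp_path / "enc"
        save_checkpoint(tcr_encoder, path, [{"epoch": 0, "val_loss": 3.1}])
        enc, hist = load_checkpoint(path)
        assert hist[0]["val_loss"] == 3.1
        for k in tcr_encoder.params:
            assert np.array_equal(enc.params[k].data,
                                  tcr_encoder.params[k].data)
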