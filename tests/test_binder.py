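"""Mapping layers, contrastive loss, negative sampling, rank scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrbind import (BinderModel, PairRecord, contrast_loss, map_embeddings,
                     rank_score, rank_scores, sample_negatives, score_pair,
                     tokenize_pmhc, tokenize_tcr, train_binder,
                     default_binder_schedule)
from tcrbind.tcr_bert import EmbeddingMatrix
from tcrbind.synthgen import gen_background_tcrs, gen_pair_dataset


@pytest.fixture(scope="module")
def model(tcr_encoder, pmhc_encoder):
    return BinderModel(tcr_encoder, pmhc_encoder, seed=7)


def _pair(cdr3b="CASSLGQAYEQYF", epitope="SIINFEKLM", label=1):
    return PairRecord(cdr3b=cdr3b, epitope=epitope, pseudo="A" * 34,
                      label=label)


class TestMapEmbeddings:
    def test_output_shapes(self, model, rng):
        E = EmbeddingMatrix(values=rng.standard_normal((32, 64)), true_len=14)
        v_len, v_dim = map_embeddings(model, E, "tcr")
        assert v_len.shape == (32,) and v_dim.shape == (64,)

    def test_zero_matrix_maps_to_zero(self, model):
        E = EmbeddingMatrix(values=np.zeros((32, 64)), true_len=14)
        v_len, v_dim = map_embeddings(model, E, "tcr")
        assert not v_len.any() and not v_dim.any()

    def test_pad_rows_never_contribute(self, model, rng):
        vals = rng.standard_normal((32, 64))
        a = map_embeddings(model, EmbeddingMatrix(vals, true_len=14), "tcr")
        vals2 = vals.copy()
        vals2[14:] = rng.standard_normal((18, 64)) * 100
        b = map_embeddings(model, EmbeddingMatrix(vals2, true_len=14), "tcr")
        assert np.allclose(a[0], b[0]) and np.allclose(a[1], b[1])

    def test_shape_mismatch_rejected(self, model, rng):
        E = EmbeddingMatrix(values=rng.standard_normal((52, 64)), true_len=44)
        with pytest.raises(ValueError):
            map_embeddings(model, E, "tcr")
        with pytest.raises(ValueError):
            map_embeddings(model, E, "mhc2")


class TestScorePair:
    def test_score_in_open_interval(self, model):
        s = score_pair(model, tokenize_tcr("CASSLGQAYEQYF"),
                       tokenize_pmhc("A" * 34, "SIINFEKLM"))
        assert -1.0 < s.f < 1.0

    def test_eval_mode_deterministic(self, model):
        args = (tokenize_tcr("CASSLGQAYEQYF"),
                tokenize_pmhc("A" * 34, "SIINFEKLM"))
        assert score_pair(model, *args).f == score_pair(model, *args).f


class TestContrastLoss:
    @pytest.mark.parametrize("fp,fm,expected", [
        (0.0, 0.0, 1.0),
        (1.0, -1.0, 0.4),
        (0.9, -0.8, 0.29),
    ])
    def test_known_values(self, fp, fm, expected):
        assert contrast_loss(fp, fm) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=100, deadline=None)
    def test_equal_scores_identity(self, f):
        """contrast_loss(f, f) = 1 + 0.4 f² for any f."""
        assert contrast_loss(f, f) == pytest.approx(1 + 0.4 * f * f,
                                                    rel=1e-9)

    def test_non_negative_everywhere(self, rng):
        for _ in range(200):
            fp, fm = rng.uniform(-1, 1, 2)
            assert contrast_loss(fp, fm) >= 0.0


class TestSampleNegatives:
    def test_ratio_and_pmhc_provenance(self, rng):
        positives = [_pair(epitope=e) for e in
                     ("SIINFEKLM", "GILGFVFTL", "NLVPMVATV")]
        pool = gen_background_tcrs(50, seed=0)
        negs = sample_negatives(positives, pool, ratio=2.0, rng=rng)
        assert len(negs) == 6
        pos_pmhc = {(r.epitope, r.pseudo) for r in positives}
        assert all((n.epitope, n.pseudo) in pos_pmhc for n in negs)
        assert all(n.label == 0 and n.cdr3b in set(pool) for n in negs)

    def test_seeded_determinism(self):
        positives = [_pair()]
        pool = gen_background_tcrs(50, seed=0)
        a = sample_negatives(positives, pool, 3.0, np.random.default_rng(5))
        b = sample_negatives(positives, pool, 3.0, np.random.default_rng(5))
        assert a == b

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives([_pair()], [], 1.0, np.random.default_rng(0))


class TestTrainBinder:
    def test_encoders_frozen_and_loss_improves(self, tcr_encoder,
                                               pmhc_encoder):
        """Encoder weights are bit-identical across binder training."""
        split = gen_pair_dataset(n_pos=150, n_neg=50, seed=2, n_test_pos=50,
                                 n_train_epitopes=6, n_test_epitopes=3)
        pool = gen_background_tcrs(200, seed=3)
        before_t = tcr_encoder.params.state()
        before_p = pmhc_encoder.params.state()
        sched = default_binder_schedule(max_epochs=3, seed=2)
        model, hist = train_binder(split.train_pos, pool, tcr_encoder,
                                   pmhc_encoder, sched)
        for k, v in tcr_encoder.params.items():
            assert np.array_equal(v.data, before_t[k])
        for k, v in pmhc_encoder.params.items():
            assert np.array_equal(v.data, before_p[k])
        assert len(hist) == 3
        assert all(np.isfinite(h["train_loss"]) for h in hist)

    def test_no_positives_rejected(self, tcr_encoder, pmhc_encoder):
        with pytest.raises(ValueError):
            train_binder([_pair(label=0)], ["CASSLGQAYEQYF"], tcr_encoder,
                         pmhc_encoder)

    def test_default_schedule_matches_reference(self):
        s = default_binder_schedule()
        assert s.peak_lr == 0.005
        assert s.batch_size == 256
        assert s.early_stop_patience == 6


class TestRankScore:
    def test_candidate_above_all_background(self, model, monkeypatch):
        pool = gen_background_tcrs(60, seed=1)
        pair = _pair()
        fs = {pair.cdr3b: 0.99}

        def fake_score(records, batch_size=512):
            return np.array([fs.get(r.cdr3b, -0.5) for r in records])
        monkeypatch.setattr(model, "score_many", fake_score)
        rs = rank_score(model, pair, pool, n=50,
                        rng=np.random.default_rng(0))
        assert rs.value == 1.0 and rs.n == 50

    def test_midrank_ties(self, model, monkeypatch):
        pool = gen_background_tcrs(60, seed=1)
        monkeypatch.setattr(model, "score_many",
                            lambda records, batch_size=512:
                            np.zeros(len(records)))
        rs = rank_score(model, _pair(), pool, n=50,
                        rng=np.random.default_rng(0))
        assert rs.value == pytest.approx(0.5)

    def test_monotone_in_f_and_background_shuffle_invariant(self, model,
                                                            monkeypatch):
        pool = gen_background_tcrs(100, seed=4)
        bg_scores = dict(zip(pool, np.linspace(-0.9, 0.9, 100)))

        def make_scorer(cand_f):
            def f(records, batch_size=512):
                return np.array([bg_scores.get(r.cdr3b, cand_f)
                                 for r in records])
            return f
        values = []
        for cand in (-0.95, 0.0, 0.5, 0.95):
            monkeypatch.setattr(model, "score_many", make_scorer(cand))
            values.append(rank_score(model, _pair(), pool, n=100,
                                     rng=np.random.default_rng(0)).value)
        assert values == sorted(values)
        # equivariance under strictly monotone transform of f
        tr = dict(zip(pool, np.tanh(3 * np.linspace(-0.9, 0.9, 100))))

        def transformed(records, batch_size=512):
            return np.array([tr.get(r.cdr3b, np.tanh(3 * 0.5))
                             for r in records])
        monkeypatch.setattr(model, "score_many", transformed)
        rs = rank_score(model, _pair(), pool, n=100,
                        rng=np.random.default_rng(0))
        assert rs.value == pytest.approx(values[2])

    def test_pool_too_small_rejected(self, model):
        with pytest.raises(ValueError):
            rank_score(model, _pair(), ["CASSLGQAYEQYF"] * 5, n=10,
                       rng=np.random.default_rng(0))

    def test_pool_drawn_candidates_are_calibrated(self, model, rng):
        """Ranks of pool members under any fixed scorer are ~ Uniform."""
        from scipy.stats import kstest
        pool = gen_background_tcrs(300, seed=9)
        candidates = [_pair(cdr3b=pool[i]) for i in rng.choice(300, 60,
                                                               replace=False)]
        values = [r.value for r in rank_scores(model, candidates, pool,
                                               n=200, rng=rng)]
        assert kstest(values, "uniform").pvalue > 0.01
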