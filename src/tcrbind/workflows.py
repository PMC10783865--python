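"""End-to-end study workflows at desk-scale conditions.

These functions compose the full pipeline — synthetic data generation,
encoder pretraining, contrastive head training, evaluation — under the
fixed scaled-down study conditions described in docs/methods.md: tiny
encoders (2 × 64 × 4 heads), a 20k-sequence rule repertoire (2 MLM
epochs), 10k pMHC records over 4 alleles (3 joint epochs), 4000 positive
pairs, an 8000-TCR healthy background pool, and an epitope-disjoint test
set of 500 positives + 500 re-paired negatives. Everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tcr_bert import EncoderConfig, TrainSchedule, pretrain_mlm
from .pmhc_bert import default_pmhc_config, pretrain_pmhc, \
    predict_presentation_batch
from .binder import default_binder_schedule, train_binder
from .benchmark import auc_roc, auc_pr
from .synthgen import (default_recognition_rule, gen_background_tcrs,
                       gen_pair_dataset, gen_pmhc_dataset,
                       gen_rule_repertoire)

TINY = dict(n_layers=2, dim=64, n_heads=4, ff_dim=256)


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes for the desk-scale zero-shot recognition study."""

    corpus_size: int = 20_000
    tcr_epochs: int = 2
    tcr_batch: int = 128
    pmhc_alleles: int = 4
    pmhc_per_allele: int = 2_500
    pmhc_epochs: int = 3
    pmhc_batch: int = 96
    n_pos: int = 4_000
    n_test_pos: int = 500
    n_test_neg: int = 500
    pool_size: int = 8_000
    binder_max_epochs: int = 200
    encoder: dict = field(default_factory=lambda: dict(TINY))


def _warmup(n_examples: int, epochs: int, batch: int) -> int:
    """~10% of the total step budget."""
    return max(1, n_examples * epochs // batch // 10)


def run_zero_shot_study(seed: int, config: StudyConfig | None = None) -> dict:
    """Pretrain both encoders, train the head, evaluate zero-shot.

    Returns the held-out presentation AUC (against the planted anchor
    rule's true labels), the epitope-disjoint pair AUC-ROC/AUC-PR of the
    raw scores f, training histories, and the trained models.
    """
    c = config or StudyConfig()
    rule = default_recognition_rule(seed=seed)

    corpus = gen_rule_repertoire(rule, c.corpus_size, seed=seed + 50)
    tcr_sched = TrainSchedule(
        batch_size=c.tcr_batch, max_epochs=c.tcr_epochs,
        warmup_steps=_warmup(c.corpus_size, c.tcr_epochs, c.tcr_batch),
        seed=seed)
    tcr_enc, tcr_hist = pretrain_mlm(corpus, EncoderConfig(**c.encoder),
                                     tcr_sched)

    records, anchor_rules = gen_pmhc_dataset(
        n_alleles=c.pmhc_alleles, per_allele=c.pmhc_per_allele, seed=seed)
    pmhc_sched = TrainSchedule(
        batch_size=c.pmhc_batch, max_epochs=c.pmhc_epochs,
        warmup_steps=_warmup(c.pmhc_alleles * c.pmhc_per_allele,
                             c.pmhc_epochs, c.pmhc_batch),
        seed=seed)
    pmhc_enc, pmhc_hist = pretrain_pmhc(
        records, default_pmhc_config(**c.encoder), pmhc_sched)

    by_allele = {r.allele: r for r in anchor_rules}
    pres_test, _ = gen_pmhc_dataset(
        n_alleles=c.pmhc_alleles, per_allele=200,
        anchor_rules=anchor_rules, seed=seed + 1000)
    pres_scores = predict_presentation_batch(
        pmhc_enc, [(r.epitope, r.pseudo) for r in pres_test])
    pres_labels = np.array(
        [by_allele[r.allele].matches(r.epitope) for r in pres_test], int)

    split = gen_pair_dataset(rule=rule, n_pos=c.n_pos, n_neg=c.n_test_neg,
                             seed=seed, n_test_pos=c.n_test_pos)
    pool = gen_background_tcrs(c.pool_size, seed=seed + 7)
    binder_sched = default_binder_schedule(max_epochs=c.binder_max_epochs,
                                           seed=seed)
    model, binder_hist = train_binder(split.train_pos, pool, tcr_enc,
                                      pmhc_enc, binder_sched)
    f = model.score_many(split.test)
    labels = np.array([r.label for r in split.test])
    return {
        "seed": seed,
        "presentation_auc": auc_roc(pres_scores, pres_labels),
        "pair_auc_roc": auc_roc(f, labels),
        "pair_auc_pr": auc_pr(f, labels),
        "tcr_history": tcr_hist,
        "pmhc_history": pmhc_hist,
        "binder_history": binder_hist,
        "model": model,
        "split": split,
        "pool": pool,
    }
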