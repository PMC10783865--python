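"""Seeded generators for every input the pipeline consumes.

Real TCR-pMHC recognition rules are unknown; these generators plant known
ones so end-to-end behaviour is checkable against ground truth:

* a healthy **background repertoire** — CDR3β strings, lengths uniform on
  [10, 30], residues from a fixed composition (uniform by default, which
  keeps planted signals clean; an optional human-like "CASS" prefix bias is
  available);
* a **motif repertoire** — a chosen fraction of sequences embed a short
  library motif at a recorded position, giving exact GLIPH2-style
  annotations;
* a **pMHC dataset** — per synthetic allele, an anchor rule (permitted
  residues at the second and C-terminal epitope positions, the classic
  MHC-I anchor layout) decides binding; labels are flipped at a noise rate
  η, and records carry BA-like unit scores or MS-like binary labels;
* a **pair dataset** — a recognition rule maps epitope central 3-mers to
  compatible TCR central 3-mers; positives satisfy it (except an η
  fraction), and held-out epitopes are string-disjoint from training while
  sharing the same rule keys, so generalisation is testable;
* a **toy complex** — 3D residue geometry with planted contact residues
  near the epitope and the rest far away.

3-mer granularity keeps the planted rule learnable by a small transformer
yet non-trivial (it requires pairwise TCR×epitope interaction); the default
η = 0.1 keeps the Bayes-optimal AUC below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_codec import CANONICAL_AA, PMHCRecord, PairRecord, ba_to_unit
from .interpret import MotifAnnotation, ResidueGeometry

AA = np.array(list(CANONICAL_AA))


def _random_seq(rng: np.random.Generator, length: int,
                cass_prefix: bool = False) -> str:
    s = "".join(rng.choice(AA, size=length))
    return "CASS" + s[4:] if cass_prefix else s


@dataclass(frozen=True)
class RecognitionRule:
    """Planted TCR↔epitope compatibility on central 3-mers."""

    compat: dict[str, tuple[str, ...]]   # epitope 3-mer → TCR 3-mers
    noise: float = 0.1

    def __post_init__(self):
        if not self.compat:
            raise ValueError("empty compatibility map")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise rate must lie in [0, 0.5)")

    @staticmethod
    def _center(seq: str) -> str:
        mid = len(seq) // 2
        return seq[mid - 1:mid + 2]

    def satisfies(self, cdr3b: str, epitope: str) -> bool:
        """Exact rule feature: central TCR 3-mer compatible with epitope's."""
        key = self._center(epitope)
        return key in self.compat and \
            self._center(cdr3b) in self.compat[key]


@dataclass(frozen=True)
class AnchorRule:
    """Permitted residues at anchor positions of one synthetic allele."""

    allele: str
    pseudo: str
    anchors: dict[int, tuple[str, ...]]   # position (−1 = C-term) → residues
    noise: float = 0.1

    def matches(self, epitope: str) -> bool:
        return all(epitope[pos] in allowed
                   for pos, allowed in self.anchors.items())


def gen_background_tcrs(n: int, seed: int,
                        cass_prefix: bool = False) -> list[str]:
    """Healthy-repertoire stand-in: n CDR3β strings, lengths U[10, 30]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(10, 31, size=n)
    return [_random_seq(rng, int(L), cass_prefix) for L in lengths]


def gen_tcr_repertoire(n: int, motif_library: list[str],
                       planted_rate: float, seed: int
                       ) -> tuple[list[str], list[MotifAnnotation]]:
    """Repertoire in which a fraction of sequences embed a library motif.

    Each planted sequence carries exactly one motif at a uniformly chosen
    offset; annotations record the exact positions, cluster id = motif.
    """
    if any(not 3 <= len(m) <= 5 for m in motif_library):
        raise ValueError("motifs must be 3-5 residues long")
    rng = np.random.default_rng(seed)
    seqs, annotations = [], []
    for _ in range(n):
        L = int(rng.integers(10, 31))
        seq = _random_seq(rng, L)
        if motif_library and rng.random() < planted_rate:
            motif = motif_library[rng.integers(len(motif_library))]
            start = int(rng.integers(0, L - len(motif) + 1))
            seq = seq[:start] + motif + seq[start + len(motif):]
            annotations.append(MotifAnnotation(
                seq_id=seq, positions=tuple(range(start, start + len(motif))),
                cluster=motif))
        seqs.append(seq)
    return seqs, annotations


def default_anchor_rules(n_alleles: int, seed: int,
                         noise: float = 0.1) -> list[AnchorRule]:
    """One anchor rule per synthetic allele: position 2 and the C-terminus."""
    rng = np.random.default_rng(seed)
    rules = []
    for a in range(n_alleles):
        pseudo = _random_seq(rng, 34)
        anchors = {1: tuple(rng.choice(AA, size=3, replace=False)),
                   -1: tuple(rng.choice(AA, size=3, replace=False))}
        rules.append(AnchorRule(allele=f"SYN-{a:02d}", pseudo=pseudo,
                                anchors=anchors, noise=noise))
    return rules


def gen_pmhc_dataset(n_alleles: int, per_allele: int,
                     anchor_rules: list[AnchorRule] | None = None,
                     seed: int = 0, ms_fraction: float = 0.5
                     ) -> tuple[list[PMHCRecord], list[AnchorRule]]:
    """Labelled epitope–MHC records governed by per-allele anchor rules.

    Half of the epitopes are built to match their allele's anchors; labels
    equal the anchor match flipped at the rule's noise rate. BA records get
    unit scores consistent with the (possibly flipped) label, MS records a
    binary label.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    rules = anchor_rules or default_anchor_rules(n_alleles, seed)
    rng = np.random.default_rng(seed + 1)
    records = []
    for rule in rules[:n_alleles]:
        for _ in range(per_allele):
            L = int(rng.integers(8, 12))
            ep = list(_random_seq(rng, L))
            if rng.random() < 0.5:   # construct an anchor-matching binder
                for pos, allowed in rule.anchors.items():
                    ep[pos] = allowed[rng.integers(len(allowed))]
            epitope = "".join(ep)
            binds = rule.matches(epitope)
            label_true = binds != (rng.random() < rule.noise)   # η flip
            if rng.random() < ms_fraction:
                records.append(PMHCRecord(
                    allele=rule.allele, pseudo=rule.pseudo, epitope=epitope,
                    assay="MS", label=float(label_true)))
            else:
                # IC50 drawn on the matching side of the 500 nM cutoff
                if label_true:
                    ic50 = float(10 ** rng.uniform(0, np.log10(500)))
                else:
                    ic50 = float(10 ** rng.uniform(np.log10(500),
                                                   np.log10(50000)))
                records.append(PMHCRecord(
                    allele=rule.allele, pseudo=rule.pseudo, epitope=epitope,
                    assay="BA", label=ba_to_unit(ic50)))
    return records, rules


def default_recognition_rule(n_keys: int = 8, compat_per_key: int = 2,
                             noise: float = 0.1,
                             seed: int = 0) -> RecognitionRule:
    """A random 3-mer compatibility table with disjoint key/value sets."""
    rng = np.random.default_rng(seed)
    kmers: set[str] = set()
    while len(kmers) < n_keys * (1 + compat_per_key):
        kmers.add(_random_seq(rng, 3))
    kmers = sorted(kmers)
    rng.shuffle(kmers)
    keys = kmers[:n_keys]
    rest = kmers[n_keys:]
    compat = {k: tuple(rest[i * compat_per_key:(i + 1) * compat_per_key])
              for i, k in enumerate(keys)}
    return RecognitionRule(compat=compat, noise=noise)


def gen_rule_repertoire(rule: RecognitionRule, n: int,
                        planted_rate: float = 0.5,
                        seed: int = 0) -> list[str]:
    """Repertoire containing antigen-experienced clones under `rule`.

    A `planted_rate` fraction of sequences carry one of the rule's
    compatible TCR 3-mers at their central position, mimicking the
    epitope-specific clones present in real repertoires; the rest are
    background. This is the corpus that makes encoder pretraining
    transferable: masked-token prediction learns the recurrent central
    3-mers, and the frozen embeddings then expose them to the prediction
    head.
    """
    rng = np.random.default_rng(seed)
    tris = [t for v in rule.compat.values() for t in v]
    out = []
    for _ in range(n):
        L = int(rng.integers(10, 31))
        seq = _random_seq(rng, L)
        if rng.random() < planted_rate:
            mid = L // 2
            tri = tris[rng.integers(len(tris))]
            seq = seq[:mid - 1] + tri + seq[mid + 2:]
        out.append(seq)
    return out


@dataclass(frozen=True)
class PairSplit:
    """Training positives plus an epitope-disjoint labelled eval set."""

    train_pos: list[PairRecord]
    test: list[PairRecord]
    rule: RecognitionRule
    train_epitopes: tuple[str, ...]
    test_epitopes: tuple[str, ...]


def _gen_epitope(rng, key: str, alleles) -> tuple[str, str]:
    L = int(rng.integers(8, 12))
    mid = L // 2
    ep = _random_seq(rng, L)
    ep = ep[:mid - 1] + key + ep[mid + 2:]
    allele = alleles[rng.integers(len(alleles))]
    return ep, allele.pseudo


def _gen_positive(rng, rule: RecognitionRule, epitope: str,
                  pseudo: str) -> PairRecord:
    L = int(rng.integers(10, 31))
    mid = L // 2
    tcr = _random_seq(rng, L)
    if rng.random() >= rule.noise:    # an η fraction stays rule-violating
        options = rule.compat[rule._center(epitope)]
        tri = options[rng.integers(len(options))]
        tcr = tcr[:mid - 1] + tri + tcr[mid + 2:]
    return PairRecord(cdr3b=tcr, epitope=epitope, pseudo=pseudo, label=1)


def gen_pair_dataset(rule: RecognitionRule | None = None,
                     n_pos: int = 4000, n_neg: int = 1000, seed: int = 0,
                     n_test_pos: int = 500, n_train_epitopes: int = 24,
                     n_test_epitopes: int = 12, n_alleles: int = 4,
                     pool: list[str] | None = None) -> PairSplit:
    """Planted-rule pair data with a zero-shot evaluation split.

    Training and test epitopes are disjoint as strings but share the rule's
    central 3-mer keys, so a model that learns the rule generalises. The
    test set holds `n_test_pos` positives and `n_neg` re-paired background
    negatives.
    """
    rule = rule or default_recognition_rule(seed=seed)
    rng = np.random.default_rng(seed + 2)
    alleles = default_anchor_rules(n_alleles, seed + 3)
    keys = sorted(rule.compat)

    epitopes: dict[str, str] = {}
    while len(epitopes) < n_train_epitopes + n_test_epitopes:
        ep, pseudo = _gen_epitope(rng, keys[len(epitopes) % len(keys)],
                                  alleles)
        epitopes.setdefault(ep, pseudo)
    items = list(epitopes.items())
    train_eps, test_eps = items[:n_train_epitopes], items[n_train_epitopes:]

    train_pos = [_gen_positive(rng, rule, *train_eps[rng.integers(
        len(train_eps))]) for _ in range(n_pos)]
    test_pos = [_gen_positive(rng, rule, *test_eps[rng.integers(
        len(test_eps))]) for _ in range(n_test_pos)]

    bg = pool if pool is not None else gen_background_tcrs(
        max(n_neg, 1000), seed + 4)
    test_neg = []
    for _ in range(n_neg):
        ep, pseudo = test_eps[rng.integers(len(test_eps))]
        test_neg.append(PairRecord(cdr3b=bg[rng.integers(len(bg))],
                                   epitope=ep, pseudo=pseudo, label=0))
    split = PairSplit(train_pos=train_pos, test=test_pos + test_neg,
                      rule=rule,
                      train_epitopes=tuple(e for e, _ in train_eps),
                      test_epitopes=tuple(e for e, _ in test_eps))
    assert not (set(split.train_epitopes) & set(split.test_epitopes))
    return split


def gen_toy_complex(n_tcr_res: int, contact_set: set[int] | frozenset[int],
                    seed: int = 0, n_epitope_res: int = 9
                    ) -> tuple[ResidueGeometry, frozenset[int]]:
    """3D geometry with planted contacts: ≤ 5 Å from the epitope centroid
    for contact residues, ≥ 15 Å for all others."""
    contact_set = frozenset(contact_set)
    if contact_set and max(contact_set) >= n_tcr_res:
        raise ValueError("contact index outside TCR residue range")
    rng = np.random.default_rng(seed)
    epi = rng.uniform(-2.0, 2.0, size=(n_epitope_res, 3))
    centroid = epi.mean(axis=0)
    tcr = np.zeros((n_tcr_res, 3))
    for i in range(n_tcr_res):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(0.5, 4.5) if i in contact_set \
            else rng.uniform(15.0, 25.0)
        tcr[i] = centroid + radius * direction
    return ResidueGeometry(tcr_coords=tcr, epitope_coords=epi), contact_set


def gen_contact_attention(n_res: int, contact_set: frozenset[int],
                          seed: int = 0, high: float = 3.0,
                          noise: float = 0.3) -> np.ndarray:
    """Planted attention profile: elevated at contacts, noisy elsewhere.

    Returns a normalised non-negative vector summing to one, for pairing
    with `gen_toy_complex` in interpretability checks.
    """
    rng = np.random.default_rng(seed)
    raw = np.abs(1.0 + noise * rng.standard_normal(n_res))
    for i in contact_set:
        raw[i] += high
    return raw / raw.sum()
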