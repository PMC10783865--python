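"""Vocabulary, tokenization, MLM masking, label transforms and tabular I/O.

Every sequence entering an encoder passes through this module: CDR3β chains
(10–30 residues, β-chain CDR3 used as the TCR proxy), MHC-I pseudo-sequences
(the fixed 34 peptide-contacting positions that represent an allele) and
epitopes (8–15 residues). Sequences are integer-encoded with a prepended
START token whose final hidden state serves as the pooled representation,
right-padded to a fixed length, and annotated with segment ids that separate
MHC pseudo-sequence (0), epitope (1) and padding (2); TCR inputs use segment
0 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

PAD, START, MASK, UNK = "<pad>", "<start>", "<mask>", "<unk>"

#: segment codes
SEG_MHC, SEG_EPITOPE, SEG_PAD = 0, 1, 2

#: sentinel for unmasked positions in MLM targets
IGNORE_INDEX = -100

TCR_MAX_LEN = 32     # START + 30 residues + 1 spare
PMHC_MAX_LEN = 52    # START + 34 pseudo + 15 epitope + 2 spare
PSEUDO_LEN = 34
TCR_LEN_RANGE = (10, 30)
EPITOPE_LEN_RANGE = (8, 15)

#: 500 nM, the conventional IC50 binder cutoff, on the unit scale
BA_BINDER_CUTOFF = 1.0 - math.log(500.0) / math.log(50000.0)


class SequenceError(ValueError):
    """Invalid residue or sequence length."""


class SchemaError(ValueError):
    """Malformed tabular input."""


@dataclass(frozen=True)
class Vocabulary:
    """Fixed 24-symbol vocabulary: PAD/START/MASK/UNK + 20 canonical AAs."""

    tokens: tuple[str, ...]
    id_of: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, symbol: str) -> int:
        try:
            return self.id_of[symbol]
        except KeyError:
            raise SequenceError(f"unknown symbol {symbol!r}") from None

    def encode_seq(self, seq: str) -> list[int]:
        return [self.encode(c) for c in seq]

    @property
    def pad_id(self) -> int:
        return self.id_of[PAD]

    @property
    def start_id(self) -> int:
        return self.id_of[START]

    @property
    def mask_id(self) -> int:
        return self.id_of[MASK]

    @property
    def aa_ids(self) -> np.ndarray:
        return np.array([self.id_of[a] for a in CANONICAL_AA])


def build_vocab() -> Vocabulary:
    """Build the fixed amino-acid vocabulary (deterministic ordering)."""
    tokens = (PAD, START, MASK, UNK) + tuple(CANONICAL_AA)
    return Vocabulary(tokens=tokens,
                      id_of={t: i for i, t in enumerate(tokens)})


VOCAB = build_vocab()


@dataclass(frozen=True)
class TokenizedSequence:
    """Integer-encoded sequence with segment and padding annotations."""

    ids: np.ndarray        # (max_len,) int64
    segments: np.ndarray   # (max_len,) int64, values in {0, 1, 2}
    true_len: int          # count of non-pad tokens, START included

    @property
    def max_len(self) -> int:
        return len(self.ids)

    def residue_positions(self) -> np.ndarray:
        """Indices of true residues (START and padding excluded)."""
        return np.arange(1, self.true_len)


@dataclass(frozen=True)
class MaskedExample:
    """An MLM training example: corrupted input plus recovery targets."""

    input_ids: np.ndarray
    target_ids: np.ndarray   # original id at masked positions, IGNORE_INDEX elsewhere
    mask_positions: np.ndarray


@dataclass(frozen=True)
class PMHCRecord:
    allele: str
    pseudo: str
    epitope: str
    assay: str         # "BA" or "MS"
    label: float       # unit-interval (BA, post-transform) or {0,1} (MS)

    @property
    def is_binder(self) -> bool:
        """Binding call used to gate selective masking."""
        if self.assay == "MS":
            return self.label >= 0.5
        return self.label >= BA_BINDER_CUTOFF


@dataclass(frozen=True)
class PairRecord:
    cdr3b: str
    epitope: str
    pseudo: str
    label: int         # 1 positive, 0 negative


def _check_residues(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(CANONICAL_AA)
    if bad:
        raise SequenceError(
            f"{what} contains non-canonical residues {sorted(bad)}: {seq!r}")
    return seq


def tokenize_tcr(seq: str, max_len: int = TCR_MAX_LEN) -> TokenizedSequence:
    """Tokenize a CDR3β sequence as [START, residues..., PAD...]."""
    seq = _check_residues(seq, "CDR3b")
    lo, hi = TCR_LEN_RANGE
    if not lo <= len(seq) <= hi:
        raise SequenceError(
            f"CDR3b length {len(seq)} outside [{lo}, {hi}]: {seq!r}")
    n = len(seq) + 1
    ids = np.full(max_len, VOCAB.pad_id, dtype=np.int64)
    ids[0] = VOCAB.start_id
    ids[1:n] = VOCAB.encode_seq(seq)
    segments = np.full(max_len, SEG_PAD, dtype=np.int64)
    segments[:n] = SEG_MHC
    return TokenizedSequence(ids=ids, segments=segments, true_len=n)


def tokenize_pmhc(pseudo: str, epitope: str,
                  max_len: int = PMHC_MAX_LEN) -> TokenizedSequence:
    """Tokenize [START, pseudo-sequence..., epitope..., PAD...].

    Segments mark START + pseudo as 0, epitope as 1, padding as 2; no
    separator token is inserted — segment embeddings alone carry the
    boundary.
    """
    pseudo = _check_residues(pseudo, "pseudo-sequence")
    epitope = _check_residues(epitope, "epitope")
    if len(pseudo) != PSEUDO_LEN:
        raise SequenceError(
            f"pseudo-sequence length {len(pseudo)} != {PSEUDO_LEN}")
    lo, hi = EPITOPE_LEN_RANGE
    if not lo <= len(epitope) <= hi:
        raise SequenceError(
            f"epitope length {len(epitope)} outside [{lo}, {hi}]: {epitope!r}")
    n = 1 + len(pseudo) + len(epitope)
    ids = np.full(max_len, VOCAB.pad_id, dtype=np.int64)
    ids[0] = VOCAB.start_id
    ids[1:1 + len(pseudo)] = VOCAB.encode_seq(pseudo)
    ids[1 + len(pseudo):n] = VOCAB.encode_seq(epitope)
    segments = np.full(max_len, SEG_PAD, dtype=np.int64)
    segments[:1 + len(pseudo)] = SEG_MHC
    segments[1 + len(pseudo):n] = SEG_EPITOPE
    return TokenizedSequence(ids=ids, segments=segments, true_len=n)


def detokenize(tok: TokenizedSequence) -> str:
    """Recover the residue string (START and padding dropped)."""
    return "".join(VOCAB.tokens[i] for i in tok.ids[1:tok.true_len])


def detokenize_pmhc(tok: TokenizedSequence) -> tuple[str, str]:
    """Recover (pseudo, epitope) using the segment annotation."""
    full = detokenize(tok)
    n_pseudo = int(np.sum(tok.segments[1:tok.true_len] == SEG_MHC))
    return full[:n_pseudo], full[n_pseudo:]


def apply_mlm_mask(tok: TokenizedSequence, rate: float = 0.15,
                   rng: np.random.Generator | None = None) -> MaskedExample:
    """Corrupt a tokenized sequence for masked-language-model training.

    Each true residue position (never START or padding) is selected
    independently with probability `rate`; a selected position becomes the
    MASK token with probability 0.8, a random canonical amino acid with 0.1,
    and stays unchanged with 0.1 — the standard BERT corruption scheme.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mask rate {rate} outside [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    positions = tok.residue_positions()
    chosen = positions[rng.random(len(positions)) < rate]
    input_ids = tok.ids.copy()
    target_ids = np.full_like(tok.ids, IGNORE_INDEX)
    if len(chosen):
        target_ids[chosen] = tok.ids[chosen]
        u = rng.random(len(chosen))
        input_ids[chosen[u < 0.8]] = VOCAB.mask_id
        rand_sel = chosen[(u >= 0.8) & (u < 0.9)]
        if len(rand_sel):
            input_ids[rand_sel] = rng.choice(VOCAB.aa_ids, size=len(rand_sel))
    return MaskedExample(input_ids=input_ids, target_ids=target_ids,
                         mask_positions=chosen)


def ba_to_unit(ic50):
    """Map an IC50 binding affinity (nM) onto the unit interval.

    score = clamp(1 − log(ic50)/log(50000), 0, 1) — the MHCflurry-style
    transform: 1 nM → 1.0, 50 µM (or weaker) → 0.0, strictly decreasing in
    between. Accepts scalars or arrays.
    """
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive")
    score = np.clip(1.0 - np.log(arr) / np.log(50000.0), 0.0, 1.0)
    return float(score) if np.isscalar(ic50) else score


# -- tabular I/O ---------------------------------------------------------

_SCHEMAS = {
    "tcr_corpus": ("cdr3b",),
    "pmhc": ("allele", "pseudo", "epitope", "assay", "label"),
    "pairs": ("cdr3b", "epitope", "pseudo", "label"),
}


def read_table(path, schema: str):
    """Read and validate a delimited table of sequence records.

    Schemas: ``tcr_corpus`` → list of CDR3β strings; ``pmhc`` → list of
    PMHCRecord; ``pairs`` → list of PairRecord. Sequences are upper-cased;
    the first malformed row aborts with its 1-based data row number.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = set(_SCHEMAS[schema]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(_parse_row(row, schema))
        except (SequenceError, ValueError) as exc:
            raise SchemaError(f"{path} row {row_no}: {exc}") from exc
    return out


def _parse_row(row, schema: str):
    if schema == "tcr_corpus":
        seq = _check_residues(row.cdr3b, "cdr3b")
        tokenize_tcr(seq)   # length/residue validation
        return seq
    if schema == "pmhc":
        assay = row.assay.upper()
        if assay not in ("BA", "MS"):
            raise ValueError(f"invalid assay kind {row.assay!r}")
        label = float(row.label)
        if not 0.0 <= label <= 1.0:
            raise ValueError(f"label {label} outside [0, 1]")
        rec = PMHCRecord(allele=row.allele,
                         pseudo=_check_residues(row.pseudo, "pseudo"),
                         epitope=_check_residues(row.epitope, "epitope"),
                         assay=assay, label=label)
        tokenize_pmhc(rec.pseudo, rec.epitope)
        return rec
    rec = PairRecord(cdr3b=_check_residues(row.cdr3b, "cdr3b"),
                     epitope=_check_residues(row.epitope, "epitope"),
                     pseudo=_check_residues(row.pseudo, "pseudo"),
                     label=int(row.label))
    if rec.label not in (0, 1):
        raise ValueError(f"label must be 0/1, got {rec.label}")
    tokenize_tcr(rec.cdr3b)
    tokenize_pmhc(rec.pseudo, rec.epitope)
    return rec


def read_epitope_fasta(path) -> list[str]:
    """Read raw epitopes from a FASTA file (headers discarded)."""
    from Bio import SeqIO
    return [_check_residues(str(r.seq), "epitope")
            for r in SeqIO.parse(str(path), "fasta")]


def write_table(records, path) -> None:
    """Write records back out as CSV with the matching schema columns."""
    if not records:
        raise ValueError("nothing to write")
    first = records[0]
    if isinstance(first, PMHCRecord):
        cols = _SCHEMAS["pmhc"]
    elif isinstance(first, PairRecord):
        cols = _SCHEMAS["pairs"]
    else:
        pd.DataFrame({"cdr3b": list(records)}).to_csv(path, index=False)
        return
    pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records]
                 ).to_csv(path, index=False)
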