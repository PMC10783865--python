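"""Residue-importance analytics for trained encoders.

Two lines of evidence connect self-attention to biology:

* **Motif contrast** — TCRs cluster into specificity groups sharing short
  sequence motifs (GLIPH2-style annotations, consumed as a table, never
  computed here). If attention marks functional residues, positions inside
  a motif should receive more attention than positions outside it. Per
  cluster we average attention over motif and non-motif residues and test
  the paired cluster-level means with the Wilcoxon signed-rank test.

* **Structural proximity** — in a resolved TCR-pMHC complex each TCR
  residue has an average distance to the epitope. The Spearman correlation
  between attention and (min-max normalised) distance, with a two-sided
  permutation null, asks whether attention tracks spatial closeness. The
  signed rho is reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wilcoxon

from .tcr_bert import AttentionProfile


@dataclass(frozen=True)
class MotifAnnotation:
    seq_id: str
    positions: tuple[int, ...]   # 0-based residue indices inside the motif
    cluster: str
    confidence: float = 1.0


@dataclass(frozen=True)
class ResidueGeometry:
    """Representative-atom coordinates (Å) for a TCR and an epitope chain."""

    tcr_coords: np.ndarray       # (n_tcr, 3)
    epitope_coords: np.ndarray   # (n_epi, 3)

    def __post_init__(self):
        assert np.all(np.isfinite(self.tcr_coords))
        assert np.all(np.isfinite(self.epitope_coords))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class MotifContrastResult:
    cluster_motif_means: dict[str, float]
    cluster_nonmotif_means: dict[str, float]
    p: float

    @property
    def paired_differences(self) -> np.ndarray:
        return np.array([self.cluster_motif_means[c]
                         - self.cluster_nonmotif_means[c]
                         for c in sorted(self.cluster_motif_means)])


def motif_attention_contrast(profiles: dict[str, AttentionProfile],
                             annotations: list[MotifAnnotation]
                             ) -> MotifContrastResult:
    """Compare attention inside vs outside annotated motifs, per cluster.

    For every cluster, attention scores are pooled over member sequences'
    motif and non-motif residues and averaged; the paired cluster-level
    means feed a two-sided Wilcoxon signed-rank test. Requires ≥ 2 clusters
    and a profile for every annotated sequence.
    """
    by_cluster: dict[str, tuple[list[float], list[float]]] = {}
    for ann in annotations:
        if ann.seq_id not in profiles:
            raise KeyError(f"no attention profile for sequence {ann.seq_id!r}")
        scores = profiles[ann.seq_id].scores
        if max(ann.positions) >= len(scores) or min(ann.positions) < 0:
            raise ValueError(
                f"motif positions {ann.positions} outside sequence "
                f"{ann.seq_id!r} of length {len(scores)}")
        inside = np.zeros(len(scores), dtype=bool)
        inside[list(ann.positions)] = True
        mot, non = by_cluster.setdefault(ann.cluster, ([], []))
        mot.extend(scores[inside])
        non.extend(scores[~inside])
    if len(by_cluster) < 2:
        raise ValueError(
            "paired Wilcoxon test needs >= 2 motif clusters, got "
            f"{len(by_cluster)}")
    motif_means = {c: float(np.mean(m)) for c, (m, _) in by_cluster.items()}
    non_means = {c: float(np.mean(n)) for c, (_, n) in by_cluster.items()}
    diffs = np.array([motif_means[c] - non_means[c] for c in by_cluster])
    if np.allclose(diffs, 0.0):
        p = 1.0   # degenerate: no signal anywhere
    else:
        p = float(wilcoxon(diffs, alternative="two-sided").pvalue)
    return MotifContrastResult(cluster_motif_means=motif_means,
                               cluster_nonmotif_means=non_means, p=p)


def residue_avg_distance(geom: ResidueGeometry) -> np.ndarray:
    """Mean Euclidean distance from each TCR residue to all epitope residues."""
    if not len(geom.tcr_coords) or not len(geom.epitope_coords):
        raise ValueError("both chains must be non-empty")
    diff = geom.tcr_coords[:, None, :] - geom.epitope_coords[None, :, :]
    return np.linalg.norm(diff, axis=-1).mean(axis=1)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant vector has no rank order")
    return (x - lo) / (hi - lo)


def attention_distance_correlation(profile, distances, n_perm: int = 10_000,
                                   rng: np.random.Generator | None = None
                                   ) -> CorrelationResult:
    """Spearman rho between attention and distance with a permutation null.

    Both vectors are min-max normalised first (inert for rho, kept for
    plotting parity); p = (1 + #{|rho_perm| ≥ |rho|}) / (1 + n_perm),
    two-sided with add-one smoothing.
    """
    att = np.asarray(profile.scores if isinstance(profile, AttentionProfile)
                     else profile, float)
    dist = np.asarray(distances, float)
    if att.shape != dist.shape:
        raise ValueError(f"length mismatch: {att.shape} vs {dist.shape}")
    n = len(att)
    if n < 3:
        raise ValueError("need at least 3 residues")
    att, dist = _minmax(att), _minmax(dist)
    rng = np.random.default_rng() if rng is None else rng
    rho = float(spearmanr(att, dist).statistic)
    count = 0
    for _ in range(n_perm):
        perm_rho = spearmanr(att, rng.permutation(dist)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    return CorrelationResult(rho=rho, p=(1 + count) / (1 + n_perm), n=n)


# -- external-format readers ---------------------------------------------


def read_motif_table(path) -> list[MotifAnnotation]:
    """Read GLIPH2-style cluster annotations: sequence, cluster, motif, start.

    `start` is the 0-based offset of the motif within the sequence; an
    optional `confidence` column is carried through. The motif substring is
    verified against the sequence.
    """
    df = pd.read_csv(path, dtype={"sequence": str, "cluster": str,
                                  "motif": str})
    out = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        seq, motif = row.sequence.upper(), row.motif.upper()
        if seq[start:start + len(motif)] != motif:
            raise ValueError(
                f"motif {motif!r} not found at offset {start} of {seq!r}")
        out.append(MotifAnnotation(
            seq_id=seq, positions=tuple(range(start, start + len(motif))),
            cluster=str(row.cluster),
            confidence=float(getattr(row, "confidence", 1.0))))
    return out


def read_pdb_geometry(path, tcr_chain: str, epitope_chain: str,
                      atom: str = "CA") -> ResidueGeometry:
    """Extract representative-atom coordinates for two chains of a PDB file."""
    from Bio.PDB import PDBParser
    structure = PDBParser(QUIET=True).get_structure("complex", str(path))
    model = next(structure.get_models())
    coords = {}
    for chain_id in (tcr_chain, epitope_chain):
        if chain_id not in model:
            raise ValueError(f"chain {chain_id!r} absent from {path}")
        xyz = [res[atom].get_coord() for res in model[chain_id]
               if atom in res]
        if not xyz:
            raise ValueError(f"chain {chain_id!r} has no {atom} atoms")
        coords[chain_id] = np.asarray(xyz, float)
    return ResidueGeometry(tcr_coords=coords[tcr_chain],
                           epitope_coords=coords[epitope_chain])
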