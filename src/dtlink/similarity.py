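"""Drug-drug and protein-protein similarity networks.

Drug similarity is the Tanimoto coefficient on 166-bit structural-key
(MACCS) fingerprints; protein similarity is a normalized pairwise
sequence-alignment score.  Both produce a :class:`SimilarityGraph` — a
complete weighted graph with weights in [0, 1] and unit diagonal — which is
what the embedding stage consumes.

Alignment defaults are local (Smith-Waterman) with BLOSUM62, gap open -10
and gap extend -0.5; a gap of length L costs ``open + (L-1) * extend``.
Raw scores are normalized as ``score(a,b) / sqrt(score(a,a) * score(b,b))``
so that self-similarity is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import VALID_RESIDUES, CompoundRecord, ProteinRecord, check_unique_ids

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityGraph",
    "AlignmentScoring",
    "fingerprint_compounds",
    "tanimoto",
    "drug_similarity_matrix",
    "align",
    "sequence_similarity",
    "protein_similarity_matrix",
    "sparsify",
]


@dataclass
class SimilarityGraph:
    """A weighted undirected similarity network over drugs or proteins."""

    node_ids: list[str]
    weights: np.ndarray
    kind: str  # "drug" or "protein"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if self.kind not in ("drug", "protein"):
            raise ValueError(f"kind must be 'drug' or 'protein', got {self.kind!r}")
        check_unique_ids(self.node_ids, f"{self.kind} node")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if self.weights.min() < 0 or self.weights.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        if not np.allclose(np.diag(self.weights), 1.0):
            raise ValueError("diagonal must be 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class AlignmentScoring:
    """Pairwise-alignment scoring scheme.

    ``X`` is treated as a neutral residue: it scores 0 against everything.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {self.mode!r}")

    def make_aligner(self) -> Align.PairwiseAligner:
        mat = substitution_matrices.load(self.matrix_name)
        alphabet = str(mat.alphabet)
        missing = VALID_RESIDUES - set(alphabet)
        if missing:
            raise ValueError(f"{self.matrix_name} does not cover residues {sorted(missing)}")
        mat = substitution_matrices.Array(alphabet=alphabet, dims=2, data=np.array(mat))
        if "X" in alphabet:
            xi = alphabet.index("X")
            mat[xi, :] = 0.0
            mat[:, xi] = 0.0
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = mat
        aligner.mode = self.mode
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


def fingerprint_compounds(compounds: list[CompoundRecord]) -> list[CompoundRecord]:
    """Populate 166-bit structural-key fingerprints from SMILES structures.

    Compounds that already carry a fingerprint pass through unchanged.  Key
    generation uses the RDKit MACCS implementation; its bit 0 is unused by
    the key dictionary and is dropped to give exactly 166 bits.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    out: list[CompoundRecord] = []
    for rec in compounds:
        if rec.fingerprint is not None:
            out.append(rec)
            continue
        mol = Chem.MolFromSmiles(rec.structure) if rec.structure else None
        if mol is None:
            raise ValueError(f"compound {rec.compound_id!r}: unparseable structure {rec.structure!r}")
        bits = MACCSkeys.GenMACCSKeys(mol)
        fp = np.zeros(167, dtype=np.uint8)
        fp[list(bits.GetOnBits())] = 1
        out.append(
            CompoundRecord(rec.compound_id, structure=rec.structure, fingerprint=fp[1:])
        )
    return out


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on binary fingerprints.

    Two all-zero fingerprints are defined as maximally similar (1.0) — both
    are featureless — and the occurrence is logged.
    """
    a = np.asarray(fp_a)
    b = np.asarray(fp_b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        logger.info("tanimoto of two all-zero fingerprints defined as 1.0")
        return 1.0
    return inter / union


def drug_similarity_matrix(compounds: list[CompoundRecord]) -> SimilarityGraph:
    """Pairwise Tanimoto similarity over a compound collection.

    Each unordered pair is computed once, so the matrix is symmetric by
    construction with a unit diagonal.
    """
    ids = [c.compound_id for c in compounds]
    fps = []
    for c in compounds:
        if c.fingerprint is None:
            raise ValueError(f"compound {c.compound_id!r}: fingerprint not populated")
        fps.append(c.fingerprint)
    n = len(ids)
    w = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            w[i, j] = w[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityGraph(node_ids=ids, weights=w, kind="drug")


def _check_sequence(seq: str) -> None:
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"residues outside the amino-acid alphabet: {sorted(bad)}")


def align(seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None) -> float:
    """Optimal pairwise alignment score under the scoring scheme.

    Local mode returns the best-scoring sub-segment score (>= 0); global
    mode the end-to-end score with affine gaps.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignmentScoring()
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    return float(scoring.make_aligner().score(seq_a, seq_b))


def sequence_similarity(seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None) -> float:
    """Alignment score normalized by the geometric mean of the self-scores,
    clamped to [0, 1]."""
    scoring = scoring or AlignmentScoring()
    aligner = scoring.make_aligner()
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    saa = float(aligner.score(seq_a, seq_a))
    sbb = float(aligner.score(seq_b, seq_b))
    if saa <= 0 or sbb <= 0:
        raise ValueError("degenerate sequence: non-positive self-alignment score")
    sab = float(aligner.score(seq_a, seq_b))
    return float(np.clip(sab / np.sqrt(saa * sbb), 0.0, 1.0))


def protein_similarity_matrix(
    proteins: list[ProteinRecord], scoring: AlignmentScoring | None = None
) -> SimilarityGraph:
    """Pairwise normalized alignment similarity over a protein collection."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    scoring = scoring or AlignmentScoring()
    aligner = scoring.make_aligner()
    ids = [p.protein_id for p in proteins]
    seqs = [p.sequence for p in proteins]
    self_scores = np.array([float(aligner.score(s, s)) for s in seqs])
    if (self_scores <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(self_scores <= 0)]
        raise ValueError(f"non-positive self-alignment score for {bad}")
    n = len(ids)
    w = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sab = float(aligner.score(seqs[i], seqs[j]))
            w[i, j] = w[j, i] = float(
                np.clip(sab / np.sqrt(self_scores[i] * self_scores[j]), 0.0, 1.0)
            )
    return SimilarityGraph(node_ids=ids, weights=w, kind="protein")


def sparsify(graph: SimilarityGraph, min_weight: float) -> SimilarityGraph:
    """Zero out off-diagonal weights below ``min_weight`` (opt-in thinning).

    Nodes left with no positive off-diagonal weight are reported in the log.
    """
    if not 0 <= min_weight < 1:
        raise ValueError("min_weight must lie in [0, 1)")
    w = graph.weights.copy()
    off = ~np.eye(len(graph.node_ids), dtype=bool)
    w[off & (w < min_weight)] = 0.0
    isolated = [
        graph.node_ids[i]
        for i in range(len(graph.node_ids))
        if not (w[i][off[i]] > 0).any()
    ]
    if isolated:
        logger.warning("sparsify left %d isolated nodes: %s", len(isolated), isolated[:10])
    return SimilarityGraph(node_ids=list(graph.node_ids), weights=w, kind=graph.kind)
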