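"""Candidate extraction: score unknown pairs, filter, and rank.

The final model scores every unknown (drug, target) pair; repurposing
candidates are the pairs with predicted interaction probability above a
high-confidence cutoff (default 0.99) whose drug is approved for clinical
use (phase 4).  Targets with no phase-4-drug positives are reported as the
cases where repurposing is most valuable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import TrainedLinkModel
from .dataset import build_features
from .embedding import EmbeddingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Prediction",
    "score_unknown_pairs",
    "filter_candidates",
    "targets_without_approved_drugs",
    "read_annotations",
]


@dataclass
class Prediction:
    drug_id: str
    target_id: str
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score) or not 0 <= self.score <= 1:
            raise ValueError(f"score must be a probability, got {self.score}")


def score_unknown_pairs(
    model: TrainedLinkModel,
    unknown_pairs: list[tuple[str, str]],
    drug_embeddings: EmbeddingMatrix,
    protein_embeddings: EmbeddingMatrix,
    batch_size: int = 50_000,
) -> list[Prediction]:
    """Predict a probability for every unknown pair, sorted by descending
    score with (drug_id, target_id) lexicographic tie-break."""
    if not unknown_pairs:
        return []
    scores = np.empty(len(unknown_pairs))
    for lo in range(0, len(unknown_pairs), batch_size):
        chunk = unknown_pairs[lo : lo + batch_size]
        fs = build_features(chunk, drug_embeddings, protein_embeddings)
        scores[lo : lo + len(chunk)] = model.predict_proba(fs.features)
    order = sorted(range(len(unknown_pairs)), key=lambda i: (-scores[i], unknown_pairs[i]))
    return [
        Prediction(unknown_pairs[i][0], unknown_pairs[i][1], float(scores[i])) for i in order
    ]


def read_annotations(path) -> dict[str, int]:
    """Read a drug_id -> max clinical phase TSV (header: drug_id, max_phase)."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str})
    phases = {}
    for _, row in df.iterrows():
        phase = int(row["max_phase"])
        if not 0 <= phase <= 4:
            raise ValueError(f"drug {row['drug_id']!r}: phase {phase} outside 0..4")
        phases[row["drug_id"]] = phase
    return phases


def filter_candidates(
    predictions: list[Prediction],
    annotations: dict[str, int] | None = None,
    min_score: float = 0.99,
    require_phase: int | None = 4,
) -> pd.DataFrame:
    """Keep predictions with score >= min_score and (optionally) an
    approved drug; ranking order is preserved.

    Drugs with no phase annotation are excluded when a phase is required.
    """
    annotations = annotations or {}
    rows = []
    for rank, pred in enumerate(predictions, 1):
        if pred.score < min_score:
            continue
        phase = annotations.get(pred.drug_id)
        if require_phase is not None and phase != require_phase:
            continue
        rows.append(
            {"rank": rank, "drug_id": pred.drug_id, "target_id": pred.target_id,
             "score": pred.score, "drug_phase": phase if phase is not None else -1}
        )
    if not rows and require_phase is not None:
        logger.warning("no candidates passed the score/phase filters")
    return pd.DataFrame(rows, columns=["rank", "drug_id", "target_id", "score", "drug_phase"])


def targets_without_approved_drugs(
    known_table: pd.DataFrame, annotations: dict[str, int]
) -> tuple[list[str], list[str]]:
    """Split targets into (has positives but none with a phase-4 drug,
    has no known positives at all).

    Both groups are prime repurposing territory; the first lacks an
    *approved* drug, the second lacks any known active compound.
    """
    positives = known_table[known_table["label"] == "positive"]
    targets = sorted(set(known_table["target_id"]))
    with_pos = set(positives["target_id"])
    approved = {
        t for d, t in zip(positives["drug_id"], positives["target_id"])
        if annotations.get(d) == 4
    }
    no_approved = sorted(t for t in with_pos if t not in approved)
    no_positives = sorted(t for t in targets if t not in with_pos)
    return no_approved, no_positives
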