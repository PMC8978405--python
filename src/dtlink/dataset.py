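"""Labelled link datasets: activity labelling, negative sampling, feature
construction and cross-validation partitioning.

Labelling follows the activity-curation rules used for ChEMBL-style data:
a pair is *positive* when its pChEMBL activity is at least the threshold
(default 5.5, i.e. ~3 uM), *negative* when flagged inactive, *weak* when it
has a sub-threshold positive activity (excluded from training and from the
unknown set), and *unknown* otherwise.  For benchmark-style data with no
validated negatives, negatives are drawn uniformly from the unknown pairs.

Features for a (drug, target) pair are the drug embedding concatenated with
the protein embedding (2n columns, drug block first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .embedding import EmbeddingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LabelledPairSet",
    "LinkFeatureSet",
    "CVSplit",
    "assign_labels",
    "enumerate_unknown_pairs",
    "sample_negative_pairs",
    "build_features",
    "make_cv_split",
]


@dataclass
class LabelledPairSet:
    """Binary-labelled (drug, target) pairs with negative-class provenance."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    provenance: str  # "validated-negative" or "sampled-unknown-negative"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must align")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in labelled set")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.provenance not in ("validated-negative", "sampled-unknown-negative"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class LinkFeatureSet:
    """Concatenated drug+protein embedding features for labelled pairs."""

    pairs: list[tuple[str, str]]
    features: np.ndarray
    labels: np.ndarray
    provenance: str = "validated-negative"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != len(self.pairs) or len(self.labels) != len(self.pairs):
            raise ValueError("pairs, features and labels must align")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")


@dataclass
class CVSplit:
    """External hold-out indices plus repeats x folds internal partitions.

    ``internal[r]`` is a list of (train_idx, test_idx) pairs; within one
    repeat the test sets partition the internal pool exactly.
    """

    external: np.ndarray
    internal: list[list[tuple[np.ndarray, np.ndarray]]]

    def validate(self, n: int) -> None:
        ext = set(self.external.tolist())
        internal_pool = set(range(n)) - ext
        for r, folds in enumerate(self.internal):
            seen: set[int] = set()
            for train, test in folds:
                tr, te = set(train.tolist()), set(test.tolist())
                if tr & te:
                    raise ValueError(f"repeat {r}: train/test overlap")
                if (tr | te) != internal_pool:
                    raise ValueError(f"repeat {r}: fold does not span the internal pool")
                if te & ext:
                    raise ValueError(f"repeat {r}: external pairs leaked into a fold")
                if te & seen:
                    raise ValueError(f"repeat {r}: fold test sets overlap")
                seen |= te
            if seen != internal_pool:
                raise ValueError(f"repeat {r}: fold test sets do not partition the pool")


def assign_labels(table: pd.DataFrame, activity_threshold: float = 5.5) -> pd.DataFrame:
    """Label interaction records from activity values and inactive flags.

    Precedence: an explicit ``inactive`` flag wins over any activity value
    (conflicts are counted and logged).  Then activity >= threshold is
    positive; 0 < activity < threshold is weak; everything else unknown.
    Idempotent and total.
    """
    acts = table["activity"].to_numpy(float)
    if np.any(acts[~np.isnan(acts)] < 0):
        raise ValueError("negative activity values are not on the pChEMBL scale")
    flags = table["activity_flag"].to_numpy(object)

    inactive = flags == "inactive"
    has_act = ~np.isnan(acts)
    conflicts = int(np.sum(inactive & has_act & (acts >= activity_threshold)))
    if conflicts:
        logger.info(
            "%d records flagged inactive despite activity >= %.2f; flag takes precedence",
            conflicts, activity_threshold,
        )

    labels = np.full(len(table), "unknown", dtype=object)
    labels[has_act & (acts > 0) & (acts < activity_threshold)] = "weak"
    labels[has_act & (acts >= activity_threshold)] = "positive"
    labels[inactive] = "negative"

    out = table.copy()
    out["label"] = labels
    return out


def enumerate_unknown_pairs(
    drug_ids: list[str], target_ids: list[str], known_table: pd.DataFrame
) -> list[tuple[str, str]]:
    """All drug x target pairs with no known (positive, negative or weak)
    interaction — the pool that prediction ranks.

    The count obeys |D| * |T| - |known| when every known pair is in the
    id lists (anything else is an error).
    """
    if not drug_ids or not target_ids:
        raise ValueError("id lists must be non-empty")
    dset, tset = set(drug_ids), set(target_ids)
    known_mask = known_table["label"].isin(["positive", "negative", "weak"])
    known = set(
        zip(known_table.loc[known_mask, "drug_id"], known_table.loc[known_mask, "target_id"])
    )
    stray = [(d, t) for d, t in known if d not in dset or t not in tset]
    if stray:
        raise ValueError(f"known pairs reference ids outside the lists: {stray[:5]}")
    return [(d, t) for d in drug_ids for t in target_ids if (d, t) not in known]


def sample_negative_pairs(
    unknown_pairs: list[tuple[str, str]], n_samples: int, seed: int
) -> LabelledPairSet:
    """Uniform sample (without replacement) of unknown pairs as negatives."""
    if n_samples > len(unknown_pairs):
        raise ValueError(
            f"requested {n_samples} negatives but only {len(unknown_pairs)} unknown pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(unknown_pairs), size=n_samples, replace=False)
    pairs = [unknown_pairs[i] for i in idx]
    return LabelledPairSet(
        pairs=pairs, labels=np.zeros(n_samples, dtype=int),
        provenance="sampled-unknown-negative",
    )


def build_features(
    pairs: list[tuple[str, str]],
    drug_embeddings: EmbeddingMatrix,
    protein_embeddings: EmbeddingMatrix,
    labels=None,
    provenance: str = "validated-negative",
) -> LinkFeatureSet:
    """Concatenate per-pair drug and protein vectors (drug block first)."""
    missing = sorted(
        {d for d, _ in pairs if d not in drug_embeddings}
        | {t for _, t in pairs if t not in protein_embeddings}
    )
    if missing:
        raise ValueError(f"no embedding for ids: {missing[:10]}")
    feats = np.empty((len(pairs), drug_embeddings.dim + protein_embeddings.dim))
    for i, (d, t) in enumerate(pairs):
        feats[i, : drug_embeddings.dim] = drug_embeddings.vector(d)
        feats[i, drug_embeddings.dim :] = protein_embeddings.vector(t)
    if labels is None:
        labels = np.zeros(len(pairs), dtype=int)
    return LinkFeatureSet(pairs=list(pairs), features=feats, labels=labels, provenance=provenance)


def make_cv_split(
    labels,
    external_fraction: float = 0.1,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> CVSplit:
    """Stratified external hold-out plus repeated stratified k-fold CV.

    The external fraction is drawn once; the internal pool is re-partitioned
    into ``folds`` stratified folds for each of ``repeats`` repeats.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} pairs for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    internal_pool, external = train_test_split(
        idx, test_size=external_fraction, stratify=labels,
        random_state=int(rng.integers(0, 2**31)),
    )
    internal_pool = np.sort(internal_pool)

    counts = np.bincount(labels[internal_pool], minlength=2)
    if (counts < folds).any():
        raise ValueError(
            f"a class has fewer members ({counts.min()}) than folds ({folds}); "
            "use fewer folds"
        )

    internal: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31))
        )
        folds_r = [
            (internal_pool[tr], internal_pool[te])
            for tr, te in skf.split(internal_pool, labels[internal_pool])
        ]
        internal.append(folds_r)
    split = CVSplit(external=np.sort(external), internal=internal)
    split.validate(n)
    return split
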