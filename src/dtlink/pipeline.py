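"""End-to-end orchestration: similarity -> embedding -> dataset -> CV.

This is the programmatic equivalent of running the CLI subcommands in
sequence, returning every intermediate artifact so callers (tests, the
examples, the acceptance script) can inspect any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, CVReport, TrainedLinkModel, run_cv
from .config import PipelineConfig, child_seed
from .dataset import (
    CVSplit,
    LinkFeatureSet,
    assign_labels,
    build_features,
    enumerate_unknown_pairs,
    make_cv_split,
    sample_negative_pairs,
)
from .embedding import EmbeddingMatrix, SkipGramConfig, WalkConfig, embed_graph
from .records import CompoundRecord, ProteinRecord
from .similarity import (
    SimilarityGraph,
    drug_similarity_matrix,
    fingerprint_compounds,
    protein_similarity_matrix,
)
from .simulate import FixtureSpec, gen_compounds, gen_interactions, gen_proteins

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "build_link_dataset", "run_pipeline", "run_fixture_pipeline"]


@dataclass
class PipelineResult:
    dds: SimilarityGraph
    pps: SimilarityGraph
    drug_embeddings: EmbeddingMatrix
    protein_embeddings: EmbeddingMatrix
    features: LinkFeatureSet
    split: CVSplit
    report: CVReport
    final_model: TrainedLinkModel
    labelled_table: pd.DataFrame
    unknown_pairs: list[tuple[str, str]]


def build_link_dataset(
    labelled_table: pd.DataFrame,
    drug_embeddings: EmbeddingMatrix,
    protein_embeddings: EmbeddingMatrix,
    drug_ids: list[str],
    target_ids: list[str],
    balance_negatives: bool = False,
    seed: int = 0,
) -> tuple[LinkFeatureSet, list[tuple[str, str]]]:
    """Assemble the binary training set and the unknown (experimental) pool.

    With validated negatives present they form the negative class
    (optionally subsampled to a 1:1 ratio); without any, negatives are drawn
    uniformly from the unknown pairs at a 1:1 ratio, and the selection
    metric downstream becomes recall-weighted accordingly.
    """
    pos_mask = labelled_table["label"] == "positive"
    neg_mask = labelled_table["label"] == "negative"
    positives = list(zip(labelled_table.loc[pos_mask, "drug_id"],
                         labelled_table.loc[pos_mask, "target_id"]))
    negatives = list(zip(labelled_table.loc[neg_mask, "drug_id"],
                         labelled_table.loc[neg_mask, "target_id"]))
    if not positives:
        raise ValueError("no positive pairs after labelling")
    unknown = enumerate_unknown_pairs(drug_ids, target_ids, labelled_table)

    if negatives:
        provenance = "validated-negative"
        if balance_negatives and len(negatives) > len(positives):
            rng = np.random.default_rng(child_seed(seed, "balance-negatives"))
            idx = rng.choice(len(negatives), size=len(positives), replace=False)
            negatives = [negatives[i] for i in sorted(idx)]
    else:
        provenance = "sampled-unknown-negative"
        sampled = sample_negative_pairs(
            unknown, len(positives), child_seed(seed, "negative-sampling")
        )
        negatives = sampled.pairs
        logger.info("sampled %d unknown pairs as negatives", len(negatives))

    pairs = positives + negatives
    labels = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])
    features = build_features(pairs, drug_embeddings, protein_embeddings, labels, provenance)
    return features, unknown


def run_pipeline(
    compounds: list[CompoundRecord],
    proteins: list[ProteinRecord],
    interactions: pd.DataFrame,
    config: PipelineConfig | None = None,
    balance_negatives: bool = False,
) -> PipelineResult:
    """Run every stage on in-memory inputs under one root seed."""
    config = config or PipelineConfig()
    seed = config.seed

    compounds = fingerprint_compounds(compounds)
    dds = drug_similarity_matrix(compounds)
    pps = protein_similarity_matrix(proteins)

    walk_cfg = WalkConfig(
        p=config.p, q=config.q, walks_per_node=config.walks_per_node,
        walk_length=config.walk_length,
    )
    sg_cfg = SkipGramConfig(
        dim=config.embedding_dim, window=config.window,
        negatives=config.negatives_per_positive, epochs=config.epochs,
        learning_rate=config.learning_rate,
    )
    drug_emb = embed_graph(dds, walk_cfg, sg_cfg, seed=seed)
    prot_emb = embed_graph(pps, walk_cfg, sg_cfg, seed=seed)

    labelled = assign_labels(interactions, config.activity_threshold)
    features, unknown = build_link_dataset(
        labelled, drug_emb, prot_emb,
        [c.compound_id for c in compounds], [p.protein_id for p in proteins],
        balance_negatives=balance_negatives, seed=seed,
    )

    split = make_cv_split(
        features.labels, config.external_fraction, config.folds, config.repeats,
        seed=child_seed(seed, "cv-split"),
    )
    spec = ClassifierSpec(
        max_depth=config.max_depth, subsample=config.subsample,
        min_child_weight=config.min_child_weight, gamma=config.gamma,
    )
    report, final_model = run_cv(features, split, spec, seed=child_seed(seed, "run-cv"))
    return PipelineResult(
        dds=dds, pps=pps, drug_embeddings=drug_emb, protein_embeddings=prot_emb,
        features=features, split=split, report=report, final_model=final_model,
        labelled_table=labelled, unknown_pairs=unknown,
    )


def run_fixture_pipeline(
    fixture: FixtureSpec | None = None,
    config: PipelineConfig | None = None,
    balance_negatives: bool = True,
) -> PipelineResult:
    """Generate the synthetic fixture and run the full pipeline on it.

    The fixture seed follows the pipeline config seed unless a fixture spec
    is passed explicitly.
    """
    config = config or PipelineConfig()
    if fixture is None:
        fixture = FixtureSpec(seed=child_seed(config.seed, "fixture"))
    compounds, drug_truth = gen_compounds(fixture)
    proteins, prot_truth = gen_proteins(fixture)
    interactions = gen_interactions(fixture, compounds, proteins, drug_truth, prot_truth)
    return run_pipeline(
        compounds, proteins, interactions, config, balance_negatives=balance_negatives
    )
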