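"""Synthetic fixture generation with planted, recoverable structure.

The generator emulates the statistical structure the link-prediction method
assumes — similar drugs tend to hit similar targets: drugs fall into
fingerprint clusters (a random 166-bit prototype per cluster, members get
independent bit flips), proteins fall into sequence families (a random
ancestor per family, members get per-site substitutions), and interactions
follow a cluster x family block probability matrix with independent label
noise.  Positives carry a synthesized pChEMBL activity in [5.5, 10);
negatives carry an inactive flag, so the labelling rules are exercised
end to end.

Every generator is deterministic under the spec seed and returns its ground
truth (cluster/family assignments) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import child_rng
from .records import AMINO_ACIDS, FINGERPRINT_LENGTH, CompoundRecord, ProteinRecord, make_interaction_table

__all__ = ["FixtureSpec", "gen_compounds", "gen_proteins", "gen_interactions", "write_fixtures"]

_AA = sorted(AMINO_ACIDS)


def default_block_matrix(n_clusters: int, n_families: int, p_in: float = 0.9, p_out: float = 0.05):
    """Identity-like block matrix: p_in where cluster index == family index
    (mod the smaller count), p_out elsewhere."""
    m = np.full((n_clusters, n_families), p_out)
    for c in range(n_clusters):
        m[c, c % n_families] = p_in
    return m


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic benchmark.

    Defaults are the end-to-end fixture conditions: 60 drugs in 4 clusters,
    50 proteins in 3 families, 5% fingerprint bit flips, 5% sequence
    mutation, in-block interaction probability 0.9 vs 0.05 out of block, and
    2% label noise.
    """

    n_drugs: int = 60
    n_proteins: int = 50
    n_drug_clusters: int = 4
    n_protein_families: int = 3
    fingerprint_flip_prob: float = 0.05
    sequence_length: int = 120
    mutation_rate: float = 0.05
    block_interaction_matrix: np.ndarray | None = None
    label_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fingerprint_flip_prob < 0.5:
            raise ValueError("fingerprint_flip_prob must lie in [0, 0.5)")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in [0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 1 <= self.n_drug_clusters <= self.n_drugs:
            raise ValueError("n_drug_clusters must lie in [1, n_drugs]")
        if not 1 <= self.n_protein_families <= self.n_proteins:
            raise ValueError("n_protein_families must lie in [1, n_proteins]")
        if self.block_interaction_matrix is None:
            self.block_interaction_matrix = default_block_matrix(
                self.n_drug_clusters, self.n_protein_families
            )
        self.block_interaction_matrix = np.asarray(self.block_interaction_matrix, float)
        if self.block_interaction_matrix.shape != (self.n_drug_clusters, self.n_protein_families):
            raise ValueError("block_interaction_matrix shape must be clusters x families")
        if (self.block_interaction_matrix < 0).any() or (self.block_interaction_matrix > 1).any():
            raise ValueError("block probabilities must lie in [0, 1]")


def gen_compounds(spec: FixtureSpec) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Clustered fingerprints; returns (records, drug_id -> cluster)."""
    rng = child_rng(spec.seed, "gen-compounds")
    prototypes = rng.integers(0, 2, size=(spec.n_drug_clusters, FINGERPRINT_LENGTH))
    clusters = np.sort(np.arange(spec.n_drugs) % spec.n_drug_clusters)
    records, truth = [], {}
    for i in range(spec.n_drugs):
        c = int(clusters[i])
        flips = rng.random(FINGERPRINT_LENGTH) < spec.fingerprint_flip_prob
        fp = np.where(flips, 1 - prototypes[c], prototypes[c]).astype(np.uint8)
        cid = f"D{i:04d}"
        records.append(CompoundRecord(compound_id=cid, fingerprint=fp))
        truth[cid] = c
    return records, truth


def gen_proteins(spec: FixtureSpec) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Mutated sequence families; returns (records, protein_id -> family)."""
    rng = child_rng(spec.seed, "gen-proteins")
    aa = np.array(_AA)
    ancestors = rng.integers(0, len(aa), size=(spec.n_protein_families, spec.sequence_length))
    families = np.sort(np.arange(spec.n_proteins) % spec.n_protein_families)
    records, truth = [], {}
    for i in range(spec.n_proteins):
        f = int(families[i])
        seq = ancestors[f].copy()
        mutate = rng.random(spec.sequence_length) < spec.mutation_rate
        # substitution to a uniformly random *different* residue
        for pos in np.flatnonzero(mutate):
            choices = [k for k in range(len(aa)) if k != seq[pos]]
            seq[pos] = choices[int(rng.integers(0, len(choices)))]
        pid = f"P{i:04d}"
        records.append(ProteinRecord(protein_id=pid, sequence="".join(aa[seq])))
        truth[pid] = f
    return records, truth


def gen_interactions(
    spec: FixtureSpec,
    compounds: list[CompoundRecord],
    proteins: list[ProteinRecord],
    drug_clusters: dict[str, int],
    protein_families: dict[str, int],
) -> pd.DataFrame:
    """Planted block-structured interaction table over all pairs.

    Pair (d, t) is truly interacting with probability
    ``block[cluster(d), family(t)]``; the observed label is then flipped
    with probability ``label_noise``.  Positives get an activity drawn
    uniformly from [5.5, 10); negatives get an inactive flag and no
    activity, so downstream labelling has to use both routes.
    """
    rng = child_rng(spec.seed, "gen-interactions")
    drug_ids, target_ids, acts, flags = [], [], [], []
    for c in compounds:
        for p in proteins:
            prob = spec.block_interaction_matrix[
                drug_clusters[c.compound_id], protein_families[p.protein_id]
            ]
            positive = rng.random() < prob
            if rng.random() < spec.label_noise:
                positive = not positive
            drug_ids.append(c.compound_id)
            target_ids.append(p.protein_id)
            if positive:
                acts.append(5.5 + 4.5 * rng.random())
                flags.append("active")
            else:
                acts.append(np.nan)
                flags.append("inactive")
    return make_interaction_table(drug_ids, target_ids, acts, flags)


def write_fixtures(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Generate and write fp.tsv, proteins.fasta, dti.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    compounds, drug_truth = gen_compounds(spec)
    proteins, prot_truth = gen_proteins(spec)
    table = gen_interactions(spec, compounds, proteins, drug_truth, prot_truth)

    fp_path = out / "fp.tsv"
    with open(fp_path, "w") as fh:
        for c in compounds:
            fh.write(c.compound_id + "\t" + "\t".join(map(str, c.fingerprint)) + "\n")
    fa_path = out / "proteins.fasta"
    with open(fa_path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    dti_path = out / "dti.tsv"
    table.drop(columns=["label"]).to_csv(dti_path, sep="\t", index=False)
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("id\tkind\tgroup\n")
        for cid, c in drug_truth.items():
            fh.write(f"{cid}\tdrug\t{c}\n")
        for pid, f in prot_truth.items():
            fh.write(f"{pid}\tprotein\t{f}\n")
    return {"fingerprints": fp_path, "proteins": fa_path, "interactions": dti_path, "truth": truth_path}
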