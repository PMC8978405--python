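"""Readers and writers for the pipeline's on-disk formats.

Everything id-keyed travels as TSV: fingerprint tables, similarity matrices
(ids in the first row and column), interaction edge lists (headered),
embedding tables (node id followed by the vector), and prediction tables.
Compound structures come in as SMILES lists (``id<TAB>smiles``) or SDF;
proteins as FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    FINGERPRINT_LENGTH,
    CompoundRecord,
    ProteinRecord,
    check_unique_ids,
    make_interaction_table,
    validate_interaction_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_compounds",
    "read_proteins",
    "read_interactions",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_embeddings",
    "write_embeddings",
    "write_interactions",
]


def _read_smiles_tsv(path: Path, permissive: bool) -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    failures: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected id<TAB>smiles, got {line!r}")
            cid, smiles = parts[0], parts[1]
            if not smiles:
                failures.append(cid)
                continue
            records.append(CompoundRecord(compound_id=cid, structure=smiles))
    if failures:
        msg = f"{len(failures)} compounds with empty structure: {failures[:10]}"
        if permissive:
            logger.warning(msg)
        else:
            raise ValueError(msg)
    return records


def _read_sdf(path: Path, permissive: bool) -> list[CompoundRecord]:
    from rdkit import Chem

    records: list[CompoundRecord] = []
    failures: list[int] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            failures.append(idx)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{idx}"
        records.append(CompoundRecord(compound_id=cid, structure=Chem.MolToSmiles(mol)))
    if failures:
        msg = f"{len(failures)} unparsable SDF entries at indices {failures[:10]}"
        if permissive:
            logger.warning(msg)
        else:
            raise ValueError(msg)
    return records


def _read_fingerprint_tsv(path: Path) -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            cid, bits = parts[0], parts[1:]
            if len(bits) != FINGERPRINT_LENGTH:
                raise ValueError(
                    f"{path}: row {lineno}: {len(bits)} fingerprint columns, "
                    f"expected {FINGERPRINT_LENGTH}"
                )
            fp = np.array([int(b) for b in bits], dtype=np.uint8)
            records.append(CompoundRecord(compound_id=cid, fingerprint=fp))
    return records


def read_compounds(path, format: str = "smiles-tsv", permissive: bool = False) -> list[CompoundRecord]:
    """Read compounds from ``smiles-tsv``, ``sdf`` or ``fingerprint-tsv``.

    Input order is preserved and ids must be unique.  Unparsable entries are
    a hard error unless ``permissive`` is set, in which case they are dropped
    with a warning.
    """
    path = Path(path)
    if format == "smiles-tsv":
        records = _read_smiles_tsv(path, permissive)
    elif format == "sdf":
        records = _read_sdf(path, permissive)
    elif format == "fingerprint-tsv":
        records = _read_fingerprint_tsv(path)
    else:
        raise ValueError(f"unknown compound format: {format!r}")
    if not records:
        logger.warning("no compounds read from %s", path)
    check_unique_ids([r.compound_id for r in records], "compound")
    return records


def read_proteins(path) -> list[ProteinRecord]:
    """Read proteins from FASTA; the header token before whitespace is the id."""
    records = [
        ProteinRecord(protein_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("no proteins read from %s", path)
    check_unique_ids([r.protein_id for r in records], "protein")
    return records


def read_interactions(path, duplicates: str = "error") -> pd.DataFrame:
    """Read an interaction edge list.

    The TSV must have a header with ``drug_id`` and ``target_id`` plus either
    a ``label`` column or an ``activity`` column (optionally with an
    ``activity_flag`` column).  When only activity data is present the label
    is left ``unknown`` — labelling is a separate, explicit step.

    ``duplicates='median'`` reduces repeated (drug, target) measurements to
    their median activity (flag ``inactive`` only if every measurement is
    inactive); the default raises on duplicates.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_id", "target_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "label" not in df.columns and "activity" not in df.columns:
        raise ValueError(f"{path}: needs a 'label' or an 'activity' column")

    known = {"drug_id", "target_id", "label", "activity", "activity_flag"}
    extra = set(df.columns) - known
    if extra:
        raise ValueError(f"{path}: unrecognized columns {sorted(extra)}")

    n = len(df)
    activity = df["activity"].to_numpy(float) if "activity" in df.columns else np.full(n, np.nan)
    if "activity_flag" in df.columns:
        flags = df["activity_flag"].fillna("none").astype(str).tolist()
    else:
        flags = ["none"] * n
    if "label" in df.columns:
        remap = {"1": "positive", "0": "negative", "1.0": "positive", "0.0": "negative"}
        labels = [remap.get(str(v), str(v)) for v in df["label"]]
    else:
        labels = ["unknown"] * n

    table = make_interaction_table(
        df["drug_id"].astype(str), df["target_id"].astype(str), activity, flags, labels
    ) if duplicates == "error" else pd.DataFrame(
        {
            "drug_id": df["drug_id"].astype(str),
            "target_id": df["target_id"].astype(str),
            "activity": activity,
            "activity_flag": flags,
            "label": labels,
        }
    )

    if duplicates == "median":
        dup_mask = table.duplicated(subset=["drug_id", "target_id"], keep=False)
        if dup_mask.any():
            logger.info("median-reducing %d duplicated measurements", int(dup_mask.sum()))

            def _reduce(g: pd.DataFrame) -> pd.Series:
                return pd.Series(
                    {
                        "activity": g["activity"].median(),
                        "activity_flag": "inactive"
                        if (g["activity_flag"] == "inactive").all()
                        else ("active" if (g["activity_flag"] == "active").any() else "none"),
                        "label": g["label"].iloc[0],
                    }
                )

            table = (
                table.groupby(["drug_id", "target_id"], sort=False)
                .apply(_reduce, include_groups=False)
                .reset_index()
            )
        validate_interaction_table(table)
    elif duplicates != "error":
        raise ValueError(f"unknown duplicate policy: {duplicates!r}")
    return table.reset_index(drop=True)


def write_interactions(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_similarity_matrix(path, tolerance: float = 1e-8):
    """Read a square id-labelled similarity matrix.

    Returns ``(ids, matrix)``.  The matrix must be square with matching row
    and column ids, entries in [0, 1] and symmetric up to ``tolerance``; it
    is symmetrized as (M + M.T)/2 and the diagonal forced to exactly 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if ids != cols:
        raise ValueError(f"{path}: row ids and column ids differ (non-square or reordered)")
    m = df.to_numpy(float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is {m.shape}, not square")
    lo, hi = m.min(), m.max()
    if lo < -tolerance or hi > 1 + tolerance:
        i, j = np.unravel_index(np.argmax(np.abs(m - 0.5)), m.shape)
        raise ValueError(
            f"{path}: entry {m[i, j]} at ({ids[i]}, {ids[j]}) outside [0, 1]"
        )
    asym = np.abs(m - m.T).max()
    if asym > tolerance:
        raise ValueError(f"{path}: asymmetry {asym} exceeds tolerance {tolerance}")
    m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return ids, m


def write_similarity_matrix(ids, matrix, path, decimals: int | None = 6) -> None:
    """Write an id-labelled square matrix as TSV (default 6 decimal places;
    ``decimals=None`` writes full float precision)."""
    df = pd.DataFrame(np.asarray(matrix, float), index=list(ids), columns=list(ids))
    fmt = None if decimals is None else f"%.{decimals}f"
    df.to_csv(path, sep="\t", float_format=fmt)


def read_embeddings(path):
    """Read an embedding table (node id, then the vector). Returns (ids, matrix)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    ids = df[0].tolist()
    check_unique_ids(ids, "embedding node")
    return ids, df.iloc[:, 1:].to_numpy(float)


def write_embeddings(ids, vectors, path) -> None:
    vectors = np.asarray(vectors, float)
    with open(path, "w") as fh:
        for nid, vec in zip(ids, vectors):
            fh.write(nid + "\t" + "\t".join(f"{x:.17g}" for x in vec) + "\n")
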