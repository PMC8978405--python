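"""Domain record types: compounds, proteins, and interaction tables.

An interaction table is an ordinary :class:`pandas.DataFrame` with columns
``drug_id``, ``target_id``, ``activity`` (pChEMBL scale, NaN when absent),
``activity_flag`` (``active`` / ``inactive`` / ``none``) and ``label``
(``positive`` / ``negative`` / ``weak`` / ``unknown``); helpers here build
and validate that schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FINGERPRINT_LENGTH = 166
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

INTERACTION_COLUMNS = ["drug_id", "target_id", "activity", "activity_flag", "label"]
VALID_FLAGS = {"active", "inactive", "none"}
VALID_LABELS = {"positive", "negative", "weak", "unknown"}


@dataclass
class CompoundRecord:
    """A small molecule: an id plus a SMILES structure and/or a 166-bit key set."""

    compound_id: str
    structure: str | None = None
    fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.structure is None and self.fingerprint is None:
            raise ValueError(f"compound {self.compound_id!r}: needs a structure or a fingerprint")
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.uint8)
            if fp.shape != (FINGERPRINT_LENGTH,):
                raise ValueError(
                    f"compound {self.compound_id!r}: fingerprint length "
                    f"{fp.shape} != ({FINGERPRINT_LENGTH},)"
                )
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"compound {self.compound_id!r}: fingerprint entries must be 0/1")
            self.fingerprint = fp


@dataclass
class ProteinRecord:
    """A protein: an id plus an amino-acid sequence (20 letters + X)."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        seq = self.sequence.upper()
        if seq != self.sequence:
            logger.info("protein %s: lowercase residues uppercased", self.protein_id)
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"protein {self.protein_id!r}: invalid residues {sorted(bad)}")
        self.sequence = seq


def check_unique_ids(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def make_interaction_table(
    drug_ids,
    target_ids,
    activity=None,
    activity_flag=None,
    label=None,
) -> pd.DataFrame:
    """Assemble a schema-conforming interaction table from column data."""
    n = len(drug_ids)
    df = pd.DataFrame(
        {
            "drug_id": list(drug_ids),
            "target_id": list(target_ids),
            "activity": np.full(n, np.nan) if activity is None else np.asarray(activity, float),
            "activity_flag": ["none"] * n if activity_flag is None else list(activity_flag),
            "label": ["unknown"] * n if label is None else list(label),
        }
    )
    validate_interaction_table(df)
    return df


def validate_interaction_table(df: pd.DataFrame, allow_duplicates: bool = False) -> None:
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    bad_flags = set(df["activity_flag"]) - VALID_FLAGS
    if bad_flags:
        raise ValueError(f"invalid activity flags: {sorted(bad_flags)}")
    bad_labels = set(df["label"]) - VALID_LABELS
    if bad_labels:
        raise ValueError(f"invalid labels: {sorted(bad_labels)}")
    if not allow_duplicates:
        dup = df.duplicated(subset=["drug_id", "target_id"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (drug, target) pair: ({first['drug_id']!r}, {first['target_id']!r})"
            )
    acts = df["activity"].to_numpy(float)
    if np.any(acts[~np.isnan(acts)] < 0):
        raise ValueError("negative activity values are not on the pChEMBL scale")
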