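"""Dataset I/O, SMILES standardization and cross-validation splitting.

A dataset is a list of :class:`MoleculeRecord` — one compound per CSV row
with an identifier, a SMILES string and a binary hazard label (1 = carries
the hazard statement, 0 = conclusively does not).  Structures are
standardized with RDKit's sanitizing parser; salts and other multi-fragment
SMILES are kept intact because the string-based featurizers handle every
SMILES symbol, including counter-ions and metals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

__all__ = [
    "MoleculeRecord",
    "FoldSplit",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "standardize_smiles",
    "standardize_records",
    "make_folds",
    "folds_to_frame",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: synonyms accepted for the binary label column (case-insensitive)
DEFAULT_LABEL_SYNONYMS = {
    "1": 1, "0": 0,
    "active": 1, "inactive": 0,
    "true": 1, "false": 0,
    "pos": 1, "neg": 0,
}


class DatasetError(ValueError):
    """Raised for malformed dataset files or infeasible split requests."""


@dataclass
class MoleculeRecord:
    """One compound: identifier, raw and standardized SMILES, binary label.

    ``valid`` is True iff standardization succeeded, in which case
    ``smiles_std`` holds the canonical sanitized SMILES.
    """

    id: str
    smiles_raw: str
    label: int
    smiles_std: str | None = None
    valid: bool = False

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DatasetError(f"label must be 0 or 1, got {self.label!r}")
        if self.valid != (self.smiles_std is not None):
            raise DatasetError("valid must be True iff smiles_std is present")


@dataclass(frozen=True)
class FoldSplit:
    """Index lists for one cross-validation fold.

    ``train_idx`` is the proper training set (base classifier), ``cal_idx``
    the conformal calibration set carved out of the fold's training portion,
    ``test_idx`` the held-out fold.  The three lists are disjoint and
    together cover the dataset.
    """

    fold_index: int
    train_idx: np.ndarray
    cal_idx: np.ndarray
    test_idx: np.ndarray


def read_dataset(
    path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    label_col: str = "label",
    delimiter: str = ",",
    label_synonyms: dict[str, int] | None = None,
) -> list[MoleculeRecord]:
    """Read a labelled SMILES dataset from CSV, in file order.

    The label column must parse to {0, 1}; the mapping accepts the
    synonyms in ``label_synonyms`` (default: active/inactive, true/false,
    pos/neg, 1/0, case-insensitive).  A missing column raises
    :class:`DatasetError`; an unparseable label raises with the offending
    row number (1-based, excluding the header).
    """
    synonyms = dict(DEFAULT_LABEL_SYNONYMS if label_synonyms is None else label_synonyms)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in (id_col, smiles_col, label_col):
        if col not in df.columns:
            raise DatasetError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    records: list[MoleculeRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        raw_label = str(getattr(row, label_col)).strip().lower()
        if raw_label not in synonyms:
            raise DatasetError(
                f"row {row_number}: cannot parse label {getattr(row, label_col)!r} "
                f"as binary (accepted: {sorted(synonyms)})"
            )
        records.append(
            MoleculeRecord(
                id=str(getattr(row, id_col)),
                smiles_raw=str(getattr(row, smiles_col)),
                label=synonyms[raw_label],
            )
        )
    return records


def write_dataset(records: Sequence[MoleculeRecord], path) -> None:
    """Write records back to CSV with ``smiles_std`` and ``valid`` columns."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles_raw for r in records],
            "label": [r.label for r in records],
            "smiles_std": [r.smiles_std if r.valid else "" for r in records],
            "valid": [int(r.valid) for r in records],
        }
    ).to_csv(path, index=False)


def standardize_smiles(smiles_raw: str) -> str | None:
    """Canonicalize a SMILES string with the sanitizing parser.

    Returns the canonical SMILES, or ``None`` for unparseable input (no
    exception is raised; invalid structures are flagged and excluded
    downstream).  Multi-fragment SMILES (salts, counter-ions, metals) are
    retained intact.  Idempotent: standardizing the output returns itself.
    """
    mol = Chem.MolFromSmiles(smiles_raw, sanitize=True)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def standardize_records(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Standardize every record; invalid structures are flagged, not dropped.

    The number of invalid structures is logged.  Downstream featurization
    works on the ``valid`` records only.
    """
    out = []
    n_invalid = 0
    for rec in records:
        std = standardize_smiles(rec.smiles_raw)
        if std is None:
            n_invalid += 1
            out.append(replace(rec, smiles_std=None, valid=False))
        else:
            out.append(replace(rec, smiles_std=std, valid=True))
    if n_invalid:
        logger.warning("standardization: %d of %d SMILES invalid (flagged, kept)",
                       n_invalid, len(records))
    return out


def make_folds(
    n_records: int,
    k: int = 10,
    cal_frac: float = 0.2,
    seed: int | None = None,
    shuffle: bool = True,
    stratify_cal: bool = False,
    labels: Sequence[int] | None = None,
) -> list[FoldSplit]:
    """Build k-fold cross-validation splits with a calibration carve-out.

    Each fold's test set is one of k contiguous blocks of a (by default
    shuffled) index permutation; ``cal_frac`` of the remaining training
    portion is then drawn at random as the conformal calibration set, so
    ``|cal| = round(cal_frac * (n - |test|))``.  With ``shuffle=False`` the
    fold blocks follow file order (the plain unshuffled k-fold).

    ``stratify_cal=True`` draws the calibration set per label stratum
    (requires ``labels``); off by default.
    """
    if k < 2:
        raise DatasetError(f"need at least 2 folds, got k={k}")
    if n_records < k:
        raise DatasetError(f"cannot make {k} folds from {n_records} records")
    if not 0.0 < cal_frac < 1.0:
        raise DatasetError(f"cal_frac must be in (0, 1), got {cal_frac}")
    if stratify_cal and labels is None:
        raise DatasetError("stratify_cal=True requires labels")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records) if shuffle else np.arange(n_records)
    blocks = np.array_split(order, k)

    folds = []
    for fold_index, test_idx in enumerate(blocks):
        pool = np.concatenate([b for j, b in enumerate(blocks) if j != fold_index])
        n_cal = int(round(cal_frac * pool.size))
        if stratify_cal:
            y = np.asarray(labels)[pool]
            cal_parts = []
            for cls in np.unique(y):
                members = pool[y == cls]
                n_c = int(round(cal_frac * members.size))
                cal_parts.append(rng.choice(members, size=n_c, replace=False))
            cal_idx = np.concatenate(cal_parts)
        else:
            cal_idx = rng.choice(pool, size=n_cal, replace=False)
        cal_set = set(cal_idx.tolist())
        train_idx = np.array([i for i in pool if i not in cal_set], dtype=int)
        folds.append(
            FoldSplit(
                fold_index=fold_index,
                train_idx=np.sort(train_idx),
                cal_idx=np.sort(cal_idx.astype(int)),
                test_idx=np.sort(test_idx.astype(int)),
            )
        )
    return folds


def folds_to_frame(folds: Sequence[FoldSplit], ids: Sequence[str]) -> pd.DataFrame:
    """Tabulate fold assignments as (id, fold, role) rows."""
    rows = []
    for fs in folds:
        for role, idx in (("train", fs.train_idx), ("cal", fs.cal_idx), ("test", fs.test_idx)):
            for i in idx:
                rows.append((ids[i], fs.fold_index, role))
    return pd.DataFrame(rows, columns=["id", "fold", "role"])
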