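"""Reading, writing, canonicalizing, deduplicating and splitting logP datasets.

A dataset is an ordered list of :class:`MoleculeRecord`, each carrying a SMILES
string, a log10 toluene/water partition coefficient, and a fidelity tag
(``"LF"`` for cheap computed labels, ``"HF"`` for experimental measurements).
Labels are stored on the log10 scale exactly as given; no unit conversion
happens at I/O time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit parse warnings are reported via our own counters

FIDELITIES = ("LF", "HF")


class DataError(ValueError):
    """Raised on contract violations in dataset I/O."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with its label and provenance."""

    smiles: str
    logp: float
    fidelity: str
    canonical_smiles: str = ""
    source: str = ""
    name: Optional[str] = None

    def __post_init__(self):
        if self.fidelity not in FIDELITIES:
            raise DataError(f"fidelity must be one of {FIDELITIES}, got {self.fidelity!r}")
        if not math.isfinite(self.logp):
            raise DataError(f"non-finite logP for {self.smiles!r}")


@dataclass
class FidelityDataset:
    """Ordered collection of records of one (or mixed) fidelity tiers."""

    records: list[MoleculeRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return FidelityDataset(self.records[idx], label=self.label)
        return self.records[idx]

    @property
    def smiles(self) -> list[str]:
        return [r.canonical_smiles or r.smiles for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.logp for r in self.records], dtype=np.float64)

    def subset(self, indices: Iterable[int], label: str = "") -> "FidelityDataset":
        return FidelityDataset([self.records[i] for i in indices], label=label or self.label)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions plus the shuffling seed."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise DataError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DataError("split fractions must sum to 1")


@dataclass
class ReadReport:
    n_read: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str, str]] = field(default_factory=list)  # (row, smiles, reason)


@dataclass
class DedupReport:
    removed: list[tuple[Optional[str], Optional[str], str]] = field(default_factory=list)
    # (kept_name, removed_name, canonical_smiles)

    def __len__(self) -> int:
        return len(self.removed)


def canonicalize(smiles: str) -> str:
    """Canonical isomeric SMILES; two spellings of one molecule map to one string.

    Aromaticity is perceived and stereochemistry retained.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def read_dataset(
    path,
    fidelity: str,
    smiles_col: str = "smiles",
    label_col: str = "logp",
    name_col: Optional[str] = "name",
    label: str = "",
) -> tuple[FidelityDataset, ReadReport]:
    """Read a CSV of SMILES + labels, dropping rows that fail to parse.

    Rows with unparseable SMILES or non-finite labels are dropped and counted
    in the returned :class:`ReadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in (smiles_col, label_col):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r} in {path}")
    report = ReadReport(n_read=len(df))
    records: list[MoleculeRecord] = []
    has_name = name_col is not None and name_col in df.columns
    for i, row in df.iterrows():
        smi = str(row[smiles_col])
        try:
            val = float(row[label_col])
        except (TypeError, ValueError):
            val = float("nan")
        if not math.isfinite(val):
            report.rejected.append((int(i), smi, "non-finite label"))
            continue
        try:
            canon = canonicalize(smi)
        except DataError:
            report.rejected.append((int(i), smi, "unparseable SMILES"))
            continue
        records.append(
            MoleculeRecord(
                smiles=smi,
                logp=val,
                fidelity=fidelity,
                canonical_smiles=canon,
                source=str(path),
                name=str(row[name_col]) if has_name and not pd.isna(row[name_col]) else None,
            )
        )
    if not records:
        raise DataError(f"empty dataset after filtering: {path}")
    report.n_kept = len(records)
    return FidelityDataset(records, label=label or path.stem), report


def ensure_canonical(ds: FidelityDataset) -> FidelityDataset:
    """Fill in missing canonical_smiles fields (no-op for already-canonical records)."""
    out = []
    for r in ds.records:
        if not r.canonical_smiles:
            r = replace(r, canonical_smiles=canonicalize(r.smiles))
        out.append(r)
    return FidelityDataset(out, label=ds.label)


def deduplicate(ds: FidelityDataset) -> tuple[FidelityDataset, DedupReport]:
    """Drop repeat occurrences of a molecule within one fidelity tier.

    The first occurrence is kept. Dedup is keyed on (fidelity, canonical
    SMILES): the same molecule may legitimately appear in both LF and HF tiers
    (multi-target learning depends on that).
    """
    ds = ensure_canonical(ds)
    seen: dict[tuple[str, str], MoleculeRecord] = {}
    kept: list[MoleculeRecord] = []
    report = DedupReport()
    for r in ds.records:
        key = (r.fidelity, r.canonical_smiles)
        if key in seen:
            report.removed.append((seen[key].name, r.name, r.canonical_smiles))
        else:
            seen[key] = r
            kept.append(r)
    return FidelityDataset(kept, label=ds.label), report


def random_split(
    ds: FidelityDataset, spec: SplitSpec
) -> tuple[FidelityDataset, FidelityDataset, FidelityDataset]:
    """Disjoint, exhaustive train/val/test partition by a seeded permutation.

    Sizes are floor(n*f_train), floor(n*f_val), remainder to test; the same
    seed always yields the same membership.
    """
    n = len(ds)
    if n < 3:
        raise DataError(f"dataset of size {n} too small for a 3-way split")
    f_tr, f_va, _ = spec.fractions
    n_tr = int(math.floor(n * f_tr))
    n_va = int(math.floor(n * f_va))
    if n_tr == 0 or n_va == 0 or n - n_tr - n_va == 0:
        raise DataError(f"dataset of size {n} yields an empty split for fractions {spec.fractions}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    tr = ds.subset(perm[:n_tr], label=f"{ds.label}/train")
    va = ds.subset(perm[n_tr : n_tr + n_va], label=f"{ds.label}/val")
    te = ds.subset(perm[n_tr + n_va :], label=f"{ds.label}/test")
    return tr, va, te


def write_predictions(
    path,
    smiles: Sequence[str],
    predictions: np.ndarray,
    head_names: Optional[Sequence[str]] = None,
) -> None:
    """Write a prediction table: one row per molecule, one column per head."""
    preds = np.atleast_2d(np.asarray(predictions, dtype=np.float64))
    if preds.shape[0] == 1 and len(smiles) > 1:
        preds = preds.T
    if len(smiles) == 0:
        raise DataError("no predictions to write")
    if preds.shape[0] != len(smiles):
        raise DataError("predictions and smiles length mismatch")
    if head_names is None:
        head_names = ["logp_pred"] if preds.shape[1] == 1 else [
            f"logp_pred_{i}" for i in range(preds.shape[1])
        ]
    df = pd.DataFrame({"canonical_smiles": list(smiles)})
    for j, name in enumerate(head_names):
        df[name] = preds[:, j]
    df.to_csv(path, index=False, float_format="%.12g")


def read_predictions(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    return pd.read_csv(path)


def write_dataset(path, ds: FidelityDataset) -> None:
    """Write a dataset as a standard CSV (smiles, logp, canonical_smiles[, name])."""
    ds = ensure_canonical(ds)
    df = pd.DataFrame(
        {
            "smiles": [r.smiles for r in ds.records],
            "logp": [r.logp for r in ds.records],
            "canonical_smiles": [r.canonical_smiles for r in ds.records],
        }
    )
    if any(r.name for r in ds.records):
        df["name"] = [r.name or "" for r in ds.records]
    df.to_csv(path, index=False, float_format="%.12g")
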