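"""Metrics, stratified error analyses and the fingerprint regression baseline.

Besides overall RMSE / R², predictions are stratified two ways that matter
for partitioning behaviour: by molar-mass bin (100 g/mol bands — heavier
molecules are harder) and by chemical class assigned through SMARTS
substructure matching. The class table below is an explicit convention of
this package: patterns are tried most-specific-first (an aminophenol must not
be swallowed by the phenol or aniline pattern), and molecules matching no
pattern fall into ``"other"``. Class-level results are convention-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.ensemble import RandomForestRegressor

from .data_io import DataError, FidelityDataset, ensure_canonical
from .featurization import molar_mass

MASS_BIN_EDGES = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0, float("inf"))
MASS_BIN_LABELS = ("0-100", "100-200", "200-300", "300-400", "400-500", "500+")

# Priority-ordered (most specific first) SMARTS table; a class may carry
# several patterns (e.g. the three aminophenol substitution patterns).
CHEMICAL_CLASS_SMARTS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("aminophenol", (
        "[OX2H]c1ccccc1[NX3;H2,H1]",
        "[OX2H]c1cccc(c1)[NX3;H2,H1]",
        "[OX2H]c1ccc(cc1)[NX3;H2,H1]",
    )),
    ("benzoic acid", ("[OX2H1][CX3](=O)c1ccccc1",)),
    ("sulfonamide", ("[SX4](=O)(=O)[NX3]",)),
    ("ureide", ("[NX3][CX3](=O)[NX3]",)),
    ("amide", ("[NX3][CX3](=O)[#6]",)),
    ("quinoline", ("c1ccc2ncccc2c1",)),
    ("phenol", ("[OX2H]c1ccccc1",)),
    ("aniline", ("[NX3;H2,H1;!$(NC=O)]c1ccccc1",)),
    ("pyridine derivative", ("c1ccncc1",)),
    ("ketone", ("[#6][CX3](=O)[#6]",)),
    ("alcohol", ("[OX2H][CX4]",)),
    ("ether", ("[OD2]([#6])[#6]",)),
    ("alkyl halide", ("[CX4][F,Cl,Br,I]",)),
    ("benzene derivative", ("c1ccccc1",)),
    ("cycloalkane", ("[CX4;R]",)),
)

_COMPILED = [
    (name, tuple(Chem.MolFromSmarts(p) for p in pats))
    for name, pats in CHEMICAL_CLASS_SMARTS
]


@dataclass
class EvalReport:
    n: int
    rmse: float
    r2: float
    within_one_log: float
    per_mass_bin: dict[str, tuple[int, float, float]] = field(default_factory=dict)
    per_class: dict[str, tuple[int, float, float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse": self.rmse,
            "r2": self.r2,
            "within_one_log": self.within_one_log,
            "per_mass_bin": {k: list(v) for k, v in self.per_mass_bin.items()},
            "per_class": {k: list(v) for k, v in self.per_class.items()},
        }


def rmse(truth: Sequence[float], pred: Sequence[float]) -> float:
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape:
        raise DataError("rmse: length mismatch")
    if t.size == 0:
        raise DataError("rmse: empty input")
    return float(np.sqrt(np.mean((t - p) ** 2)))


def r_squared(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape:
        raise DataError("r_squared: length mismatch")
    if t.size < 2:
        raise DataError("r_squared: need at least two points")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("r_squared: constant truth")
    return 1.0 - float(np.sum((t - p) ** 2)) / ss_tot


def mass_bin(mass: float) -> str:
    """Left-closed 100 g/mol bins; mass exactly 200 lands in 200-300."""
    for lo, hi, lab in zip(MASS_BIN_EDGES[:-1], MASS_BIN_EDGES[1:], MASS_BIN_LABELS):
        if lo <= mass < hi:
            return lab
    return MASS_BIN_LABELS[-1]


def bin_by_molar_mass(ds: FidelityDataset) -> dict[str, FidelityDataset]:
    out = {lab: [] for lab in MASS_BIN_LABELS}
    for r in ds.records:
        out[mass_bin(molar_mass(r.smiles))].append(r)
    return {lab: FidelityDataset(recs, label=lab) for lab, recs in out.items()}


def classify_chemical_class(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES: {smiles!r}")
    for name, pats in _COMPILED:
        if any(mol.HasSubstructMatch(p) for p in pats):
            return name
    return "other"


def evaluate(
    truth: FidelityDataset, predictions: Sequence[float]
) -> tuple[EvalReport, pd.DataFrame]:
    """Full report plus a parity table (truth, pred, mass bin, class)."""
    pred = np.asarray(predictions, dtype=np.float64).ravel()
    if pred.size != len(truth):
        raise DataError("one prediction per truth molecule required")
    t = truth.labels
    err = np.abs(pred - t)
    masses = np.array([molar_mass(r.smiles) for r in truth.records])
    bins = [mass_bin(m) for m in masses]
    classes = [classify_chemical_class(r.smiles) for r in truth.records]
    parity = pd.DataFrame(
        {
            "canonical_smiles": ensure_canonical(truth).smiles,
            "truth": t,
            "pred": pred,
            "abs_error": err,
            "molar_mass": masses,
            "mass_bin": bins,
            "chemical_class": classes,
        }
    )
    per_bin = {}
    for lab in MASS_BIN_LABELS:
        sel = parity["mass_bin"] == lab
        if sel.any():
            sub = parity[sel]
            per_bin[lab] = (
                int(sel.sum()),
                rmse(sub["truth"], sub["pred"]),
                float(sub["abs_error"].mean()),
            )
        else:
            per_bin[lab] = (0, float("nan"), float("nan"))
    per_class = {}
    for lab in sorted(set(classes)):
        sub = parity[parity["chemical_class"] == lab]["abs_error"]
        per_class[lab] = (
            len(sub),
            float(sub.median()),
            float(sub.quantile(0.25)),
            float(sub.quantile(0.75)),
        )
    report = EvalReport(
        n=len(truth),
        rmse=rmse(t, pred),
        r2=r_squared(t, pred),
        within_one_log=float(np.mean(err <= 1.0)),  # closed +/- 1 margin
        per_mass_bin=per_bin,
        per_class=per_class,
    )
    return report, parity


# ---------------------------------------------------------------------------
# fingerprint baseline


def _morgan_fps(smiles: Sequence[str], radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    X = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DataError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        X[i] = np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")
    return X


def fingerprint_baseline(
    train: FidelityDataset,
    test: FidelityDataset,
    seed: int = 0,
    n_estimators: int = 500,
) -> np.ndarray:
    """Random forest on ECFP4 (Morgan radius-2, 2048-bit) fingerprints.

    The train set may mix fidelity tiers; when a molecule carries both an LF
    and an HF label, the experimental (HF) value is retained. ``max_features``
    is set to sqrt — the usual choice for high-dimensional binary
    fingerprints.
    """
    if len(train) == 0 or len(test) == 0:
        raise DataError("nonempty train and test sets required")
    train = ensure_canonical(train)
    labels: dict[str, tuple[float, str]] = {}
    for r in train.records:
        prev = labels.get(r.canonical_smiles)
        if prev is None or (prev[1] == "LF" and r.fidelity == "HF"):
            labels[r.canonical_smiles] = (r.logp, r.fidelity)
    smiles = list(labels)
    y = np.array([labels[s][0] for s in smiles])
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(_morgan_fps(smiles), y)
    return forest.predict(_morgan_fps(ensure_canonical(test).smiles))
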