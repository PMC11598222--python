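"""Molecular featurization, feature selection, and fold-isolated scaling.

Three feature families are supported:

* ``ecfp4`` — 2048-bit extended-connectivity fingerprints of diameter 4
  (Morgan radius 2), the substrate for atom-level contribution maps;
* ``maccs`` — 167-position MACCS structural keys (index 0 unused);
* ``rdkit2d`` — the full RDKit 2D physicochemical descriptor block, the
  continuous-descriptor feature set (min–max scaled per training fold).

Selection (variance filter, recursive feature elimination) and min–max
scaling are fitted on training rows only and serialized as plain state
objects so that cross-validation stays leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier

FEATURE_KINDS = ("ecfp4", "maccs", "rdkit2d")
FINGERPRINT_KINDS = ("ecfp4", "maccs")

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class FeatureMatrix:
    """Compounds × features numeric matrix with named columns and SMILES keys."""

    kind: str
    values: np.ndarray
    feature_names: list
    row_keys: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_keys):
            raise ValueError("values must be 2-D with one row per key")

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.kind,
            self.values[idx],
            list(self.feature_names),
            [self.row_keys[i] for i in idx],
        )


@dataclass
class SelectionState:
    """Retained feature indices (into the original matrix) after filtering."""

    indices: np.ndarray
    method: str  # "variance" | "rfe" | "composed"
    threshold: Optional[float] = None
    target_count: Optional[int] = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx.min() < 0):
            raise ValueError("indices must be sorted, unique and non-negative")
        self.indices = idx

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if self.indices.size and self.indices.max() >= matrix.shape[1]:
            raise ValueError("selection indices exceed matrix width")
        return matrix[:, self.indices]

    def compose(self, inner: "SelectionState") -> "SelectionState":
        """Selection equivalent to applying ``self`` then ``inner``."""
        return SelectionState(self.indices[inner.indices], "composed")

    def to_dict(self) -> dict:
        return {
            "indices": self.indices.tolist(),
            "method": self.method,
            "threshold": self.threshold,
            "target_count": self.target_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionState":
        return cls(np.asarray(d["indices"]), d["method"], d.get("threshold"), d.get("target_count"))


@dataclass
class ScalerState:
    """Per-feature min/max learned from one training fold.

    Maps training values into [0, 1]; external rows are transformed with the
    same affine map and may fall outside [0, 1] (no clipping).  A constant
    training feature maps to 0 everywhere.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise ValueError("max must be >= min per feature")

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(np.asarray(d["minimum"]), np.asarray(d["maximum"]))


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def _mol(std_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(std_smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {std_smiles!r}")
    return mol


def ecfp4(std_smiles: str) -> np.ndarray:
    """2048-bit ECFP4 (Morgan radius-2) fingerprint of a standardized SMILES."""
    return np.asarray(_MORGAN.GetFingerprintAsNumPy(_mol(std_smiles)), dtype=np.uint8)


#: Morgan radius-2 / 2048-bit fingerprint — identical to ECFP4 and used under
#: that name for chemical-space analysis.
morgan2 = ecfp4


def maccs(std_smiles: str) -> np.ndarray:
    """167-position MACCS structural keys (bit 0 unused by convention)."""
    bv = MACCSkeys.GenMACCSKeys(_mol(std_smiles))
    arr = np.zeros(167, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(std_smiles_list: list, kind: str = "ecfp4") -> FeatureMatrix:
    if kind not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    fn = ecfp4 if kind == "ecfp4" else maccs
    rows = np.array([fn(s) for s in std_smiles_list], dtype=float)
    names = [f"{kind}_{i}" for i in range(rows.shape[1])]
    return FeatureMatrix(kind, rows, names, list(std_smiles_list))


def descriptor_block(std_smiles_list: list) -> tuple:
    """RDKit 2D descriptor matrix for a list of standardized structures.

    Descriptors that come out non-finite for any compound are dropped, and a
    compound for which every descriptor fails is excluded; both are recorded.

    Returns ``(FeatureMatrix, log)`` where log lists
    ``(std_smiles, "excluded", reason)`` entries for failed compounds.
    """
    if not std_smiles_list:
        raise ValueError("empty structure list")
    names = [n for n, _ in Descriptors.descList]
    rows, keys, log = [], [], []
    for smi in std_smiles_list:
        mol = _mol(smi)
        vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan, silent=True)
        row = np.array([vals[n] for n in names], dtype=float)
        if not np.any(np.isfinite(row)):
            log.append((smi, "excluded", "descriptor_failure"))
            continue
        rows.append(row)
        keys.append(smi)
    if not rows:
        raise ValueError("all compounds failed descriptor calculation")
    matrix = np.array(rows)
    finite_cols = np.all(np.isfinite(matrix), axis=0)
    matrix = matrix[:, finite_cols]
    names = [n for n, keep in zip(names, finite_cols) if keep]
    return FeatureMatrix("rdkit2d", matrix, names, keys), log


def featurize(std_smiles_list: list, kind: str) -> FeatureMatrix:
    """Dispatch to the requested feature family."""
    if kind in FINGERPRINT_KINDS:
        return fingerprint_matrix(std_smiles_list, kind)
    if kind == "rdkit2d":
        fm, log = descriptor_block(std_smiles_list)
        if log:
            raise ValueError(f"{len(log)} compounds failed descriptor calculation")
        return fm
    raise ValueError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def variance_filter(matrix: np.ndarray, threshold: float = 0.01) -> SelectionState:
    """Retain features whose variance (ddof=0) exceeds ``threshold``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    variances = np.var(matrix, axis=0)
    idx = np.flatnonzero(variances > threshold)
    if idx.size == 0:
        raise ValueError("no informative features after variance filter")
    return SelectionState(idx, "variance", threshold=threshold)


def rfe_select(
    matrix: np.ndarray,
    labels,
    n_target: int,
    seed: int = 0,
    step_fraction: float = 0.1,
) -> SelectionState:
    """Recursive feature elimination driven by forest impurity importance.

    Each round a small random forest ranks the surviving features and the
    lowest-importance 10% (of the remaining set, at least one) is dropped,
    until exactly ``n_target`` features remain.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target > matrix.shape[1]:
        raise ValueError(
            f"n_target={n_target} exceeds feature count {matrix.shape[1]}"
        )
    surviving = np.arange(matrix.shape[1])
    while surviving.size > n_target:
        forest = RandomForestClassifier(n_estimators=50, random_state=seed, n_jobs=1)
        forest.fit(matrix[:, surviving], labels)
        importances = forest.feature_importances_
        n_drop = min(
            surviving.size - n_target, max(1, int(step_fraction * surviving.size))
        )
        # ties broken by feature order: stable argsort on (importance, index)
        order = np.argsort(importances, kind="stable")
        surviving = np.delete(surviving, order[:n_drop])
    return SelectionState(np.sort(surviving), "rfe", target_count=n_target)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def fit_minmax(train_matrix: np.ndarray) -> ScalerState:
    """Learn per-feature min/max from training rows only."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.size == 0:
        raise ValueError("empty training matrix")
    return ScalerState(train_matrix.min(axis=0), train_matrix.max(axis=0))


def apply_minmax(state: ScalerState, matrix: np.ndarray) -> np.ndarray:
    """Affine [0, 1] map learned at fit time; no clipping of external rows."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != state.minimum.shape[0]:
        raise ValueError(
            f"feature count mismatch: {matrix.shape[1]} vs {state.minimum.shape[0]}"
        )
    span = state.maximum - state.minimum
    span = np.where(span == 0, 1.0, span)
    return (matrix - state.minimum) / span
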