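"""Readers, writers, and model-bundle persistence.

Compound tables arrive as UTF-8 comma-separated CSV (columns ``casrn``,
``smiles``, one column per weight-of-evidence scheme, optional
``dsa``/``dsa05``/``dsa01``) or as SDF V2000 with properties of the same
names.  Model bundles persist as a directory: ``meta.json`` (config, seeds,
threshold, digests), ``selection.json``, ``scaler.json``, ``ad.json`` and a
joblib blob for the fitted predictor, with a SHA-256 digest check on load.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem

from . import applicability, calibration, features
from .curation import ENDPOINTS, SCHEMES, CompoundRecord, CuratedDataset, standardize_structure
from .modeling import ModelBundle

BUNDLE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Compound tables
# ---------------------------------------------------------------------------


def _float_or_none(v):
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def read_compounds(path, fmt: str = None) -> tuple:
    """Read a compound table from CSV or SDF.

    Returns ``(records, skipped)``; malformed rows (no structure) are
    skipped and counted, never fatal.  A CSV without a ``smiles`` column is
    an error.
    """
    path = Path(path)
    fmt = fmt or ("sdf" if path.suffix.lower() == ".sdf" else "csv")
    records, skipped = [], []
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        if "smiles" not in df.columns:
            raise ValueError(f"{path}: missing required 'smiles' column")
        scheme_cols = {s: s.lower() for s in SCHEMES if s.lower() in df.columns}
        for i, row in df.iterrows():
            smi = row.get("smiles")
            if not isinstance(smi, str) or not smi.strip():
                skipped.append((i, "empty_smiles"))
                continue
            records.append(
                CompoundRecord(
                    casrn=str(row.get("casrn", f"row-{i}")),
                    raw_smiles=smi.strip(),
                    outcomes={s: row.get(c) for s, c in scheme_cols.items()},
                    dsa=_float_or_none(row.get("dsa")),
                    dsa05=_float_or_none(row.get("dsa05")),
                    dsa01=_float_or_none(row.get("dsa01")),
                )
            )
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped.append((i, "unreadable_molecule"))
                continue
            props = mol.GetPropsAsDict()
            props = {str(k).lower(): v for k, v in props.items()}
            records.append(
                CompoundRecord(
                    casrn=str(props.get("casrn", f"mol-{i}")),
                    raw_smiles=Chem.MolToSmiles(mol),
                    outcomes={
                        s: props.get(s.lower()) for s in SCHEMES if s.lower() in props
                    },
                    dsa=_float_or_none(props.get("dsa")),
                    dsa05=_float_or_none(props.get("dsa05")),
                    dsa01=_float_or_none(props.get("dsa01")),
                )
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return records, skipped


def write_compounds_csv(records: list, path) -> None:
    rows = []
    for r in records:
        row = {"casrn": r.casrn, "smiles": r.raw_smiles}
        row.update({s.lower(): r.outcomes.get(s) for s in SCHEMES})
        row.update({"dsa": r.dsa, "dsa05": r.dsa05, "dsa01": r.dsa01})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_compounds_sdf(records: list, path) -> None:
    writer = Chem.SDWriter(str(path))
    for r in records:
        mol = Chem.MolFromSmiles(r.raw_smiles)
        if mol is None:
            continue
        mol.SetProp("casrn", r.casrn)
        for s in SCHEMES:
            if r.outcomes.get(s) is not None:
                mol.SetProp(s.lower(), str(r.outcomes[s]))
        for name in ENDPOINTS:
            v = r.endpoint_value(name)
            if v is not None:
                mol.SetProp(name.lower(), repr(v))
        writer.write(mol)
    writer.close()


def write_curated(dataset: CuratedDataset, out_csv, log_csv=None) -> None:
    """Curated CSV (std_smiles, label) plus the drop-log CSV."""
    pd.DataFrame(dataset.items, columns=["std_smiles", "label"]).to_csv(
        out_csv, index=False
    )
    if log_csv is not None:
        pd.DataFrame(dataset.log, columns=["casrn", "action", "reason"]).to_csv(
            log_csv, index=False
        )


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------


def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist a fitted bundle as a directory of JSON state + predictor blob."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.predictor, path / "predictor.joblib")
    digest = hashlib.sha256((path / "predictor.joblib").read_bytes()).hexdigest()
    (path / "selection.json").write_text(json.dumps(bundle.selection.to_dict()))
    (path / "scaler.json").write_text(
        json.dumps(bundle.scaler.to_dict() if bundle.scaler else None)
    )
    (path / "ad.json").write_text(json.dumps(bundle.ad.to_dict()))
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "algorithm": bundle.algorithm,
        "hyperparameters": bundle.hyperparameters,
        "feature_kind": bundle.feature_kind,
        "pt": bundle.pt,
        "metadata": bundle.metadata,
        "predictor_digest": digest,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_bundle(path) -> ModelBundle:
    """Load a bundle; verifies the format version and the predictor digest."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {meta['format_version']} != "
            f"supported version {BUNDLE_FORMAT_VERSION}"
        )
    blob = (path / "predictor.joblib").read_bytes()
    if hashlib.sha256(blob).hexdigest() != meta["predictor_digest"]:
        raise ValueError("predictor blob digest mismatch: bundle corrupted")
    scaler_d = json.loads((path / "scaler.json").read_text())
    return ModelBundle(
        algorithm=meta["algorithm"],
        hyperparameters=meta["hyperparameters"],
        predictor=joblib.load(path / "predictor.joblib"),
        feature_kind=meta["feature_kind"],
        selection=features.SelectionState.from_dict(
            json.loads((path / "selection.json").read_text())
        ),
        scaler=features.ScalerState.from_dict(scaler_d) if scaler_d else None,
        pt=meta["pt"],
        ad=applicability.ADState.from_dict(json.loads((path / "ad.json").read_text())),
        metadata=meta["metadata"],
    )


# ---------------------------------------------------------------------------
# Batch prediction
# ---------------------------------------------------------------------------


def predict_batch(bundle: ModelBundle, smiles_list: list) -> pd.DataFrame:
    """Score a list of raw SMILES with one bundle.

    Per row: standardized structure, positive-class probability, calibrated
    call, AD distance and in-domain flag.  Unparsable or rejected entries
    get ``status`` set and never abort the batch.
    """
    rows = []
    parsed = []
    for smi in smiles_list:
        out = standardize_structure(smi)
        if not out.ok:
            rows.append(
                {
                    "smiles": smi,
                    "std_smiles": None,
                    "status": f"error:{out.reason.value}",
                    "prob": np.nan,
                    "call": None,
                    "ad_distance": np.nan,
                    "in_ad": False,
                }
            )
        else:
            rows.append({"smiles": smi, "std_smiles": out.std_smiles, "status": "ok"})
            parsed.append((len(rows) - 1, out.std_smiles))
    if parsed:
        idx, std = zip(*parsed)
        X = features.featurize(list(std), bundle.feature_kind).values
        Xm = bundle.transform(X)
        dists = applicability.ad_distances(bundle.ad, Xm)
        task = bundle.metadata.get("task", "binary")
        if task == "binary":
            probs = bundle.positive_prob(X)
            calls = calibration.apply_threshold(probs, bundle.pt)
        else:
            proba = bundle.prob_matrix(X)
            probs = proba.max(axis=1)
            calls = bundle.predictor.classes_[np.argmax(proba, axis=1)]
        for j, i in enumerate(idx):
            rows[i].update(
                {
                    "prob": float(probs[j]),
                    "call": int(calls[j]),
                    "ad_distance": float(dists[j]),
                    "in_ad": bool(dists[j] <= bundle.ad.cutoff),
                }
            )
    return pd.DataFrame(rows)
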