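"""Chemical standardization and biological curation of compound/outcome tables.

Raw entries from human patch-test compilations arrive as (CASRN, SMILES,
per-scheme outcome) rows, frequently as salts, solvates, mixtures, or exact
duplicates with concordant or conflicting outcomes.  This module turns such
tables into QSAR-ready datasets:

* structures are standardized (counterions stripped, charges neutralized,
  chemotypes normalized, canonical SMILES emitted) and mixtures, inorganics
  and very large organics are rejected;
* duplicate structures are collapsed when their outcomes agree and removed
  when they disagree;
* binary (sensitizer vs. non-sensitizer), multiclass (NC / weak 1B /
  strong 1A) and continuous (log10 dose-per-skin-area) datasets are
  assembled per weight-of-evidence scheme, with every dropped record logged.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

SCHEMES = ("MLLP", "MSPE", "WoE", "WES")
ENDPOINTS = ("DSA", "DSA05", "DSA01")

#: Outcome labels carrying no usable information.
UNINFORMATIVE = {"unavailable", "missing", "", None}

#: Heavy-atom cap above which an organic structure is considered a
#: polymer/macromolecule and rejected (configurable per call).
DEFAULT_MAX_HEAVY_ATOMS = 100

#: Canonical SMILES of organic fragments treated as counterions/solvates and
#: stripped when they accompany a larger parent fragment.  Carbon-free
#: fragments (chloride, sodium, sulfate, water, ...) are always strippable.
ORGANIC_COUNTERIONS = {
    Chem.CanonSmiles(s)
    for s in (
        "CC(=O)O", "CC(=O)[O-]",            # acetate
        "C(=O)O", "C(=O)[O-]",              # formate
        "OC(=O)C(=O)O",                      # oxalate
        "OC(=O)C(F)(F)F",                    # trifluoroacetate
        "CS(=O)(=O)O", "CS(=O)(=O)[O-]",    # mesylate
        "Cc1ccc(S(=O)(=O)O)cc1",             # tosylate
        "OC(=O)C(O)C(O)C(=O)O",              # tartrate
        "OC(=O)CC(O)(CC(=O)O)C(=O)O",        # citrate
    )
}


class RejectReason(str, Enum):
    MIXTURE = "mixture"
    INORGANIC = "inorganic"
    LARGE_ORGANIC = "large_organic"
    UNPARSABLE = "unparsable"


@dataclass
class StandardizationOutcome:
    """Result of standardizing one raw SMILES: either a canonical structure
    or a rejection reason, never both."""

    status: str  # "ok" | "rejected"
    std_smiles: Optional[str] = None
    reason: Optional[RejectReason] = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class CompoundRecord:
    """One raw table entry: registry number, structure, per-scheme outcomes
    and optional continuous dose-per-skin-area values (µg/cm²)."""

    casrn: str
    raw_smiles: str
    outcomes: dict = field(default_factory=dict)
    dsa: Optional[float] = None
    dsa05: Optional[float] = None
    dsa01: Optional[float] = None
    std_smiles: Optional[str] = None

    def endpoint_value(self, endpoint: str) -> Optional[float]:
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
        return {"DSA": self.dsa, "DSA05": self.dsa05, "DSA01": self.dsa01}[endpoint]


@dataclass
class CuratedDataset:
    """Deduplicated labeled structures for one task × scheme (or endpoint),
    plus a provenance log of every dropped record."""

    task: str  # "binary" | "multiclass" | "continuous"
    scheme: str  # scheme name or endpoint name
    items: list  # list[(std_smiles, label-or-value)]
    log: list = field(default_factory=list)  # list[(casrn, action, reason)]

    @property
    def smiles(self) -> list:
        return [s for s, _ in self.items]

    @property
    def labels(self) -> list:
        return [y for _, y in self.items]

    def class_counts(self) -> dict:
        counts: dict = {}
        for _, y in self.items:
            counts[y] = counts.get(y, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Structure standardization
# ---------------------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()


def _is_counterion(frag: Chem.Mol) -> bool:
    if not any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
        return True
    return Chem.MolToSmiles(frag) in ORGANIC_COUNTERIONS


def standardize_structure(
    raw_smiles: str, max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS
) -> StandardizationOutcome:
    """Standardize one raw SMILES into a QSAR-ready canonical structure.

    Multi-fragment inputs keep a single parent fragment only when every other
    fragment is a recognized counterion or solvate; two substantial organic
    fragments are a mixture.  The parent is normalized and neutralized
    (quaternary nitrogens stay charged), must contain carbon, and must not
    exceed ``max_heavy_atoms`` heavy atoms.  Idempotent on its own output.
    Unparsable input is a rejection, never an exception.
    """
    if not raw_smiles or not raw_smiles.strip():
        return StandardizationOutcome("rejected", reason=RejectReason.UNPARSABLE)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return StandardizationOutcome("rejected", reason=RejectReason.UNPARSABLE)

    frags = list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))
    if len(frags) == 1:
        parent = frags[0]
    else:
        parents = [f for f in frags if not _is_counterion(f)]
        if len(parents) > 1:
            return StandardizationOutcome("rejected", reason=RejectReason.MIXTURE)
        if len(parents) == 1:
            parent = parents[0]
        else:
            # pure salt/solvate cluster: keep the largest organic fragment
            organics = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
            if not organics:
                return StandardizationOutcome("rejected", reason=RejectReason.INORGANIC)
            parent = max(organics, key=lambda f: f.GetNumHeavyAtoms())
    try:
        parent = rdMolStandardize.Cleanup(parent)
        parent = _UNCHARGER.uncharge(parent)
        Chem.SanitizeMol(parent)
    except Exception:
        return StandardizationOutcome("rejected", reason=RejectReason.UNPARSABLE)

    if not any(a.GetAtomicNum() == 6 for a in parent.GetAtoms()):
        return StandardizationOutcome("rejected", reason=RejectReason.INORGANIC)
    if parent.GetNumHeavyAtoms() > max_heavy_atoms:
        return StandardizationOutcome("rejected", reason=RejectReason.LARGE_ORGANIC)
    return StandardizationOutcome("ok", std_smiles=Chem.MolToSmiles(parent))


def standardize_records(
    records: list, max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS
) -> tuple:
    """Standardize a batch of records.

    Returns ``(kept, log)`` where ``kept`` records carry ``std_smiles`` and
    ``log`` lists ``(casrn, "rejected", reason)`` for the rest.
    """
    kept, log = [], []
    for rec in records:
        out = standardize_structure(rec.raw_smiles, max_heavy_atoms=max_heavy_atoms)
        if out.ok:
            kept.append(
                CompoundRecord(
                    casrn=rec.casrn,
                    raw_smiles=rec.raw_smiles,
                    outcomes=dict(rec.outcomes),
                    dsa=rec.dsa,
                    dsa05=rec.dsa05,
                    dsa01=rec.dsa01,
                    std_smiles=out.std_smiles,
                )
            )
        else:
            log.append((rec.casrn, "rejected", out.reason.value))
    return kept, log


# ---------------------------------------------------------------------------
# Duplicate resolution
# ---------------------------------------------------------------------------

_HAZARD_MAP = {"NC": 0, "1A": 1, "1B": 1, "sensitizer": 1}
_POTENCY_MAP = {"NC": 0, "1B": 1, "1A": 2}


def _informative(outcome) -> bool:
    return outcome not in UNINFORMATIVE


def resolve_duplicates(records: list, scheme: str, level: str = "hazard") -> tuple:
    """Collapse duplicate structures; remove structures with conflicting outcomes.

    Concordance is judged at ``level``: ``"hazard"`` treats 1A and 1B as the
    same (both sensitizers), which is the binary-task rule; ``"potency"``
    distinguishes them for the multiclass task.  Groups whose informative
    outcomes disagree are removed entirely and logged as discordant.

    Returns ``(records, log)`` with unique ``std_smiles`` in the output.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if level not in ("hazard", "potency"):
        raise ValueError(f"level must be 'hazard' or 'potency', got {level!r}")
    cls_map = _HAZARD_MAP if level == "hazard" else _POTENCY_MAP

    groups: dict = {}
    for rec in records:
        if rec.std_smiles is None:
            raise ValueError(f"record {rec.casrn} is not standardized")
        groups.setdefault(rec.std_smiles, []).append(rec)

    kept, log = [], []
    # deterministic order regardless of input permutation
    for smi in sorted(groups):
        grp = sorted(groups[smi], key=lambda r: r.casrn)
        outs = [r.outcomes.get(scheme) for r in grp]
        classes = {cls_map[o] for o in outs if _informative(o) and o in cls_map}
        if len(classes) > 1:
            for r in grp:
                log.append((r.casrn, "removed", "discordant"))
            continue
        representative = next(
            (r for r in grp if _informative(r.outcomes.get(scheme))), grp[0]
        )
        kept.append(representative)
        for r in grp:
            if r is not representative:
                log.append((r.casrn, "merged", "concordant_duplicate"))
    return kept, log


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def assemble_binary(records: list, scheme: str) -> CuratedDataset:
    """Binary hazard dataset: sensitizer/1A/1B → 1, NC → 0; uninformative
    outcomes dropped and logged.  Raises on an empty result."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    items, log = [], []
    for rec in sorted(records, key=lambda r: r.std_smiles):
        out = rec.outcomes.get(scheme)
        if not _informative(out) or out not in _HAZARD_MAP:
            log.append((rec.casrn, "dropped", "no_outcome"))
            continue
        items.append((rec.std_smiles, _HAZARD_MAP[out]))
    if not items:
        raise ValueError(f"empty dataset for scheme {scheme!r}")
    return CuratedDataset("binary", scheme, items, log)


def assemble_multiclass(records: list, scheme: str) -> CuratedDataset:
    """Three-class potency dataset: NC → 0, 1B (weak) → 1, 1A (strong) → 2.

    A bare hazard-only "sensitizer" outcome carries no potency and is
    dropped like a missing outcome.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    items, log = [], []
    for rec in sorted(records, key=lambda r: r.std_smiles):
        out = rec.outcomes.get(scheme)
        if not _informative(out) or out not in _POTENCY_MAP:
            log.append((rec.casrn, "dropped", "no_outcome"))
            continue
        items.append((rec.std_smiles, _POTENCY_MAP[out]))
    if not items:
        raise ValueError(f"empty dataset for scheme {scheme!r}")
    return CuratedDataset("multiclass", scheme, items, log)


def assemble_continuous(records: list, endpoint: str) -> CuratedDataset:
    """Continuous log-dose dataset for one endpoint (DSA, DSA05, DSA01).

    Multiple entries for a structure are reduced to their median dose before
    the base-10 log transform; records without a positive dose are dropped
    and logged.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    values: dict = {}
    log = []
    for rec in records:
        if rec.std_smiles is None:
            raise ValueError(f"record {rec.casrn} is not standardized")
        v = rec.endpoint_value(endpoint)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            log.append((rec.casrn, "dropped", "missing_value"))
            continue
        if v <= 0:
            log.append((rec.casrn, "dropped", "nonpositive_dose"))
            continue
        values.setdefault(rec.std_smiles, []).append(float(v))
    items = [
        (smi, math.log10(statistics.median(vs))) for smi, vs in sorted(values.items())
    ]
    if not items:
        raise ValueError(f"empty dataset for endpoint {endpoint!r}")
    return CuratedDataset("continuous", endpoint, items, log)
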