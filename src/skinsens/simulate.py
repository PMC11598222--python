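"""Synthetic compound/outcome generator emulating human patch-test data.

The generator enumerates a scaffold × substituent chemical space (benzenes,
pyridines, cyclohexanes, alkyl chains) in which skin-sensitization potency
is driven by structural alerts: an aldehyde marks strong sensitizers (the
canonical direct-acting electrophile of the sensitization adverse-outcome
pathway), while sulfonamide and 1,2-diol moieties mark weak sensitizers.
On top of the clean structures it injects the pathologies real tables have —
salt forms, two-fragment mixtures, exact duplicate entries with concordant
or deliberately discordant outcomes, label noise, scheme-wise "unavailable"
outcomes, and per-class log-normal dose-per-skin-area values with replicate
entries of inflated spread.

Defaults reproduce the study conditions of the modeled data: sensitizers
outnumber non-sensitizers ~3:1 in the binary task and weak sensitizers are
~3× as abundant as either other class in the multiclass task.  Every
injection is recorded in a ground-truth ledger so curation can be reconciled
count-for-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .curation import SCHEMES, CompoundRecord


@dataclass
class AlertRule:
    """A substructure pattern and the potency class it confers."""

    name: str
    smarts: str
    effect: str  # "strong" | "weak"
    probability: float = 1.0

    def __post_init__(self):
        if self.effect not in ("strong", "weak"):
            raise ValueError("effect must be 'strong' or 'weak'")
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        self._pattern = Chem.MolFromSmarts(self.smarts)
        if self._pattern is None:
            raise ValueError(f"unparsable SMARTS {self.smarts!r}")

    def matches(self, mol: Chem.Mol) -> bool:
        return mol.HasSubstructMatch(self._pattern)


DEFAULT_ALERTS = (
    AlertRule("aldehyde", "[CX3H1](=O)[#6]", "strong"),
    AlertRule("sulfonamide", "[#16X4](=[OX1])(=[OX1])[NX3]", "weak"),
    AlertRule("1,2-diol", "[OX2H][CX4][CX4][OX2H]", "weak"),
)


@dataclass
class SyntheticConfig:
    """Generator conditions.

    ``binary_ratio`` is the sensitizer:non-sensitizer target (≈3:1), and
    ``weak_to_strong`` splits sensitizers (weak ≈ 3× strong), matching the
    class structure of the patch-test compilations.  Dose parameters are
    log10 µg/cm² per class — lower dose means higher potency, so strong <
    weak < NC.
    """

    n: int = 400
    seed: int = 0
    binary_ratio: float = 3.0
    weak_to_strong: float = 3.0
    duplicate_fraction: float = 0.05
    salt_fraction: float = 0.05
    mixture_fraction: float = 0.03
    label_noise: float = 0.05
    discordance_rate: float = 0.5
    unavailable_rate: float = 0.03
    dose_log_means: dict = field(
        default_factory=lambda: {2: 0.5, 1: 2.0, 0: 3.5}
    )
    dose_log_sd: float = 0.4
    replicate_fraction: float = 0.3
    replicate_spread_factor: float = 3.0

    def __post_init__(self):
        if self.n < 20:
            raise ValueError("n must be >= 20")
        for name in (
            "duplicate_fraction",
            "salt_fraction",
            "mixture_fraction",
            "label_noise",
            "discordance_rate",
            "unavailable_rate",
            "replicate_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


# --------------------------------------------------------------------------
# Chemical space enumeration
# --------------------------------------------------------------------------

_INERT_SUBS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "CO",
    "N", "NC", "Cl", "F", "Br", "C#N", "[N+](=O)[O-]", "C(F)(F)F",
)
_ALERT_SUBS = (
    "C=O", "CC=O",                      # aldehydes (strong)
    "S(N)(=O)=O", "CS(N)(=O)=O",        # sulfonamides (weak)
    "C(O)CO", "CC(O)CO",                # 1,2-diols (weak)
)
_ALL_SUBS = _INERT_SUBS + _ALERT_SUBS

_MONO_TEMPLATES = ("c1ccc({x})cc1", "c1cc({x})ccn1", "C1CCC({x})CC1")
_DI_TEMPLATES = (
    "c1ccc({x})c({y})c1",
    "c1cc({x})cc({y})c1",
    "c1cc({x})ccc1{y}",
)
_CHAINS = ("CC", "CCC", "CCCC", "CCCCC", "CCCCCC")


def enumerate_space() -> list:
    """All valid canonical structures of the scaffold × substituent space."""
    raw = []
    for t in _MONO_TEMPLATES:
        raw += [t.format(x=x) for x in _ALL_SUBS]
    for t in _DI_TEMPLATES:
        raw += [t.format(x=x, y=y) for x in _ALL_SUBS for y in _ALL_SUBS]
    raw += [c + x for c in _CHAINS for x in _ALL_SUBS]
    seen, out = set(), []
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            out.append(can)
    return out


def true_class(smiles: str, rules=DEFAULT_ALERTS) -> int:
    """Deterministic potency class from the alert rules (probability 1)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return 0
    if any(r.matches(mol) for r in rules if r.effect == "strong"):
        return 2
    if any(r.matches(mol) for r in rules if r.effect == "weak"):
        return 1
    return 0


# --------------------------------------------------------------------------
# Library generation
# --------------------------------------------------------------------------


def _class_targets(config: SyntheticConfig, n_parents: int) -> dict:
    r, w = config.binary_ratio, config.weak_to_strong
    f_nc = 1.0 / (1.0 + r)
    f_strong = (1.0 - f_nc) / (1.0 + w)
    f_weak = 1.0 - f_nc - f_strong
    n_nc = int(round(f_nc * n_parents))
    n_strong = int(round(f_strong * n_parents))
    return {0: n_nc, 2: n_strong, 1: n_parents - n_nc - n_strong}


def generate_library(config: SyntheticConfig, rules=DEFAULT_ALERTS) -> list:
    """Raw SMILES entries at the configured conditions (see ``simulate`` for
    the entries *plus* the ground-truth ledger)."""
    return simulate_library(config, rules)[0]


def simulate_library(config: SyntheticConfig, rules=DEFAULT_ALERTS) -> tuple:
    """Generate raw entries and the injection ledger.

    Returns ``(smiles_list, truth)`` where truth records each entry's parent
    structure and class, plus which entries are salts, duplicates and
    mixtures.
    """
    rng = np.random.default_rng(config.seed)
    n_dup = int(round(config.duplicate_fraction * config.n))
    n_mix = int(round(config.mixture_fraction * config.n))
    n_parents = config.n - n_dup - n_mix
    if n_parents < 2:
        raise ValueError("n too small for the configured injection fractions")

    space = enumerate_space()
    pools = {0: [], 1: [], 2: []}
    for smi in space:
        pools[true_class(smi, rules)].append(smi)
    targets = _class_targets(config, n_parents)
    for cls, want in targets.items():
        if want > len(pools[cls]):
            raise ValueError(
                f"n exceeds enumerable space: class {cls} needs {want}, "
                f"pool has {len(pools[cls])}"
            )

    parents = []
    for cls in (0, 1, 2):
        chosen = rng.choice(pools[cls], size=targets[cls], replace=False)
        parents += [str(s) for s in chosen]
    parents = [parents[i] for i in rng.permutation(len(parents))]

    entries = list(parents)
    salted = set()
    n_salt = int(round(config.salt_fraction * n_parents))
    for i in rng.choice(n_parents, size=n_salt, replace=False):
        entries[i] = entries[i] + ".Cl"
        salted.add(int(i))

    dup_of = {}
    for _ in range(n_dup):
        src = int(rng.integers(0, n_parents))
        dup_of[len(entries)] = src
        entries.append(entries[src])

    mixtures = []
    for _ in range(n_mix):
        a, b = rng.choice(n_parents, size=2, replace=False)
        mixtures.append(len(entries))
        entries.append(parents[int(a)] + "." + parents[int(b)])

    truth = {
        "n_parents": n_parents,
        "n_duplicates": n_dup,
        "n_mixtures": n_mix,
        "n_salts": n_salt,
        "parents": parents,
        "salted_indices": sorted(salted),
        "duplicate_of": dup_of,
        "mixture_indices": mixtures,
    }
    return entries, truth


# --------------------------------------------------------------------------
# Outcome and dose assignment
# --------------------------------------------------------------------------

_CLASS_LABEL = {0: "NC", 1: "1B", 2: "1A"}


def assign_outcomes(
    smiles_list: list,
    rules=DEFAULT_ALERTS,
    config: Optional[SyntheticConfig] = None,
    truth: Optional[dict] = None,
) -> list:
    """Attach per-scheme outcome labels to raw entries.

    The class comes from the alert rules (strong beats weak beats none),
    with Bernoulli label noise applied once per unique structure so exact
    duplicates stay concordant by default.  Later copies of a duplicated
    structure are flipped to a conflicting class at the discordance rate,
    and individual scheme outcomes are blanked to "unavailable" at the
    configured rate — both to exercise duplicate resolution and assembly
    drops downstream.  When a ``truth`` ledger is passed, expected
    discordant structures are recorded in it.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = []
    base_class: dict = {}
    discordant: set = set()
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if smi not in base_class:
            cls = true_class(smi, rules)
            if mol is not None:
                for r in rules:
                    if r.probability < 1 and r.matches(mol) and rng.random() > r.probability:
                        cls = 0
                        break
            if rng.random() < config.label_noise:
                cls = int(rng.choice([c for c in (0, 1, 2) if c != cls]))
            base_class[smi] = cls
            first = True
        else:
            first = False
        cls = base_class[smi]
        if not first and rng.random() < config.discordance_rate:
            cls = int(rng.choice([c for c in (0, 1, 2) if c != base_class[smi]]))
            discordant.add(smi)
        outcomes = {}
        for scheme in SCHEMES:
            if rng.random() < config.unavailable_rate:
                outcomes[scheme] = "unavailable"
            else:
                outcomes[scheme] = _CLASS_LABEL[cls]
        records.append(
            CompoundRecord(casrn=f"SYN-{i:06d}", raw_smiles=smi, outcomes=outcomes)
        )
    if truth is not None:
        truth["discordant_structures"] = sorted(discordant)
    return records


def assign_doses(records: list, config: Optional[SyntheticConfig] = None) -> list:
    """Draw per-class log-normal dose-per-skin-area values.

    A configurable fraction of compounds is expanded into 2–5 replicate
    entries with spread inflated by ``replicate_spread_factor``, reproducing
    the wide per-compound interquartile ranges of real patch-test doses.
    Returns a new (possibly longer) record list.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out = []
    for rec in records:
        label = next(
            (v for v in rec.outcomes.values() if v in ("NC", "1B", "1A")), "NC"
        )
        cls = {"NC": 0, "1B": 1, "1A": 2}[label]
        mu = config.dose_log_means[cls]
        replicate = rng.random() < config.replicate_fraction
        n_rep = int(rng.integers(2, 6)) if replicate else 1
        sd = config.dose_log_sd * (config.replicate_spread_factor if replicate else 1.0)
        for _ in range(n_rep):
            dsa = 10.0 ** (mu + sd * rng.standard_normal())
            dsa05 = 10.0 ** (mu - 0.2 + sd * rng.standard_normal())
            dsa01 = 10.0 ** (mu - 0.4 + sd * rng.standard_normal())
            out.append(
                CompoundRecord(
                    casrn=rec.casrn,
                    raw_smiles=rec.raw_smiles,
                    outcomes=dict(rec.outcomes),
                    dsa=dsa,
                    dsa05=dsa05,
                    dsa01=dsa01,
                    std_smiles=rec.std_smiles,
                )
            )
    return out


def simulate(config: Optional[SyntheticConfig] = None, rules=DEFAULT_ALERTS) -> tuple:
    """Full synthetic dataset: entries → outcomes → doses.

    Returns ``(records, truth)``; records carry outcomes and dose values,
    truth is the injection ledger for reconciliation tests.
    """
    config = config or SyntheticConfig()
    entries, truth = simulate_library(config, rules)
    records = assign_outcomes(entries, rules, config, truth)
    records = assign_doses(records, config)
    return records, truth
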