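"""Model interpretation: additive feature attributions and atom-level
fragment-contribution maps.

Feature attributions are Shapley values estimated by permutation sampling
against a background of training rows.  For each (background row, random
permutation) pair the marginal contributions telescope exactly to
``f(x) − f(background)``, so the averaged attributions satisfy

    base + Σ_j φ_j = model probability of the explained row

up to floating-point error, for every model family.  Only features where the
explained row differs from the background can carry mass, which keeps the
cost proportional to the number of differing bits rather than the full
fingerprint width.

Atom contribution maps work by fingerprint-bit removal: for each atom, every
on-bit whose circular environment contains that atom is zeroed, and the
atom's weight is the drop in predicted sensitization probability,
``P(full) − P(bits zeroed)``.  Positive weight (green) therefore marks
substructure whose removal lowers the predicted hazard — i.e. a fragment
driving sensitization — and negative weight (purple) the opposite.  Weights
are normalized per molecule by the maximum absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Draw import rdMolDraw2D

from .modeling import ModelBundle

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class AttributionResult:
    """Per-feature Shapley attributions for one explained row (positive
    class); base + sum(values) ≈ the model's probability for the row."""

    values: np.ndarray
    base_value: float
    target_class: int = 1

    @property
    def prediction(self) -> float:
        return float(self.base_value + self.values.sum())


@dataclass
class AtomContributionMap:
    """Per-atom contribution weights in [-1, 1] (normalized by max |w|);
    positive means the atom's fingerprint bits push the prediction toward
    sensitizer."""

    std_smiles: str
    weights: np.ndarray
    raw_weights: np.ndarray
    probability: float


def feature_attributions(
    bundle: ModelBundle,
    feature_rows: np.ndarray,
    n_background: int = 5,
    n_permutations: int = 10,
    seed: int = 0,
) -> list:
    """Permutation-sampling Shapley attributions in the model's own space.

    ``feature_rows`` live in the post-selection (and post-scaling) space the
    predictor consumes, matching the AD reference matrix used as background.
    """
    rows = np.atleast_2d(np.asarray(feature_rows, dtype=float))
    ref = bundle.ad.reference
    if rows.shape[1] != ref.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {rows.shape[1]} vs {ref.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(ref.shape[0], size=min(n_background, ref.shape[0]), replace=False)
    background = ref[bg_idx]

    def prob(matrix: np.ndarray) -> np.ndarray:
        proba = bundle.predictor.predict_proba(matrix)
        col = int(np.flatnonzero(bundle.predictor.classes_ == 1)[0])
        return proba[:, col]

    base = float(prob(background).mean())
    results = []
    for x in rows:
        phi = np.zeros(rows.shape[1])
        for b in background:
            diff = np.flatnonzero(x != b)
            if diff.size == 0:
                continue
            for _ in range(n_permutations):
                order = rng.permutation(diff)
                # walk b -> x one differing feature at a time; batch-predict
                walk = np.tile(b, (diff.size + 1, 1))
                for step, j in enumerate(order, start=1):
                    walk[step:, j] = x[j]
                p = prob(walk)
                phi[order] += p[1:] - p[:-1]
        phi /= background.shape[0] * n_permutations
        results.append(AttributionResult(phi, base))
    return results


def _atom_bit_ownership(mol: Chem.Mol) -> tuple:
    """Map each atom to the set of on-bits whose circular environment
    contains it; the union over atoms is exactly the set of on-bits."""
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = _MORGAN.GetFingerprintAsNumPy(mol, additionalOutput=ao)
    bit_info = ao.GetBitInfoMap()
    atom_bits = [set() for _ in range(mol.GetNumAtoms())]
    for bit, environments in bit_info.items():
        for center, radius in environments:
            if radius == 0:
                atom_bits[center].add(bit)
                continue
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
            atoms = {center}
            for bid in bond_ids:
                bond = mol.GetBondWithIdx(bid)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            for a in atoms:
                atom_bits[a].add(bit)
    return np.asarray(fp, dtype=float), atom_bits


def atom_contributions(bundle: ModelBundle, std_smiles: str) -> AtomContributionMap:
    """Atom-level contribution map via fingerprint-bit removal.

    Requires a fingerprint-based bundle: bit identity must survive feature
    selection, which is why RFE never runs on fingerprints.  Hash-collision
    bits shared between atoms are zeroed for any owning atom.
    """
    if bundle.feature_kind != "ecfp4":
        raise ValueError("contribution maps require fingerprint (ecfp4) models")
    mol = Chem.MolFromSmiles(std_smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {std_smiles!r}")
    full, atom_bits = _atom_bit_ownership(mol)

    variants = [full]
    for bits in atom_bits:
        v = full.copy()
        v[list(bits)] = 0.0
        variants.append(v)
    probs = bundle.positive_prob(np.array(variants))
    p_full = float(probs[0])
    raw = p_full - probs[1:]
    max_abs = np.max(np.abs(raw))
    weights = raw / max_abs if max_abs > 0 else np.zeros_like(raw)
    return AtomContributionMap(std_smiles, weights, raw, p_full)


def render_contribution_map(
    cmap: AtomContributionMap, path: str, size: int = 400
) -> str:
    """Write a 2-D depiction (SVG) with a diverging color scale:
    green = promotes sensitization, purple = protective."""
    mol = Chem.MolFromSmiles(cmap.std_smiles)
    green = np.array([0.30, 0.75, 0.30])
    purple = np.array([0.60, 0.40, 0.75])
    white = np.array([1.0, 1.0, 1.0])
    colors, atoms = {}, []
    for i, w in enumerate(cmap.weights):
        if w == 0:
            continue
        tint = green if w > 0 else purple
        mix = white + abs(float(w)) * (tint - white)
        colors[i] = tuple(mix)
        atoms.append(i)
    drawer = rdMolDraw2D.MolDraw2DSVG(size, size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightAtoms=atoms, highlightAtomColors=colors
    )
    drawer.FinishDrawing()
    with open(path, "w") as fh:
        fh.write(drawer.GetDrawingText())
    return path
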