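"""Euclidean nearest-neighbor applicability domain (AD).

A prediction is considered reliable only when the query compound is close
enough, in the model's own feature space, to the training set.  The cutoff
is the Tropsha-school construction: with d̄ and s the mean and standard
deviation of within-training nearest-neighbor distances,

    D_c = d̄ + Z·s,

where Z (default 0.5) sets the significance level.  A query is in-domain
iff its distance to the nearest training compound is ≤ D_c.  The AD is
fitted per cross-validation fold on the post-selection (and, for continuous
descriptors, post-scaling) training matrix — the exact space the model
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ADState:
    """Reference training matrix plus the fitted distance cutoff."""

    reference: np.ndarray
    d_mean: float
    d_sd: float
    z: float
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.tolist(),
            "d_mean": self.d_mean,
            "d_sd": self.d_sd,
            "z": self.z,
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ADState":
        return cls(np.asarray(d["reference"], dtype=float), d["d_mean"], d["d_sd"], d["z"], d["cutoff"])


def fit_ad(train_features: np.ndarray, z: float = 0.5) -> ADState:
    """Fit the AD on a training feature matrix (needs ≥ 2 rows).

    Each training row's distance to its nearest *other* training row gives
    the within-training 1-NN distance distribution; d̄ and s use ddof=0.
    """
    ref = np.asarray(train_features, dtype=float)
    if ref.ndim != 2 or ref.shape[0] < 2:
        raise ValueError("AD requires a 2-D training matrix with >= 2 rows")
    dist = cdist(ref, ref)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    d_mean = float(nn.mean())
    d_sd = float(nn.std())
    return ADState(ref, d_mean, d_sd, float(z), d_mean + z * d_sd)


def ad_check(state: ADState, feature_row) -> tuple:
    """Distance of one query row to its nearest training compound and the
    in-domain flag (distance ≤ D_c)."""
    row = np.asarray(feature_row, dtype=float).reshape(1, -1)
    if row.shape[1] != state.reference.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {row.shape[1]} vs {state.reference.shape[1]}"
        )
    d = float(cdist(row, state.reference).min())
    return d, d <= state.cutoff


def ad_distances(state: ADState, feature_matrix) -> np.ndarray:
    """Vectorized nearest-training-neighbor distances for many rows."""
    m = np.asarray(feature_matrix, dtype=float)
    if m.shape[1] != state.reference.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {m.shape[1]} vs {state.reference.shape[1]}"
        )
    return cdist(m, state.reference).min(axis=1)


def coverage(state: ADState, feature_matrix) -> float:
    """Percentage of rows inside the applicability domain."""
    m = np.asarray(feature_matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty feature matrix")
    d = ad_distances(state, m)
    return 100.0 * float(np.mean(d <= state.cutoff))
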