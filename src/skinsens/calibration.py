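"""Threshold-moving calibration of binary probability outputs.

Class-imbalanced sensitization data push probability estimates for the
minority class below 0.5, so the default cutoff wastes sensitivity or
specificity.  Instead of resampling, the decision threshold is moved to the
value that maximizes the geometric mean √(SE·SP) on held-out predictions.
Because SE and SP are piecewise constant between observed probabilities, the
scan over observed unique probabilities (plus 0.5) is exact — it dominates
any fixed grid.  Ties break toward the smallest threshold, favoring
sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ThresholdScan:
    """Exhaustive gmean scan: candidate thresholds with their SE/SP/gmean and
    the selected probability threshold (PT)."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    gmeans: np.ndarray
    selected: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "sensitivities": self.sensitivities.tolist(),
            "specificities": self.specificities.tolist(),
            "gmeans": self.gmeans.tolist(),
            "selected": self.selected,
        }


def gmean(se: float, sp: float) -> float:
    """Geometric mean of sensitivity and specificity, √(SE·SP)."""
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("SE and SP must lie in [0, 1]")
    return math.sqrt(se * sp)


def apply_threshold(probabilities, pt: float) -> np.ndarray:
    """Binary calls from positive-class probabilities: 1 iff p >= PT."""
    if not (0 < pt <= 1):
        raise ValueError("PT must lie in (0, 1]")
    return (np.asarray(probabilities, dtype=float) >= pt).astype(int)


def select_threshold(y_true, probabilities) -> ThresholdScan:
    """Pick the probability threshold maximizing √(SE·SP).

    Candidates are the observed unique probabilities plus 0.5; every
    candidate is evaluated with the inclusive rule (positive iff p >= t).
    The smallest *observed* probability attaining the maximal gmean is
    returned (ties break toward the smallest, favoring sensitivity).  The
    calls induced by 0.5 always coincide with those of some observed
    candidate — or call nothing positive — so the selected threshold attains
    the global maximum over the whole candidate set.
    """
    y_true = np.asarray(y_true, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y_true.shape != p.shape:
        raise ValueError("y_true and probabilities must have equal length")
    pos = y_true == 1
    neg = y_true == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to select a threshold")

    candidates = np.unique(np.concatenate([p, [0.5]]))
    observed = np.isin(candidates, p)
    se = np.empty(candidates.size)
    sp = np.empty(candidates.size)
    g = np.empty(candidates.size)
    for i, t in enumerate(candidates):
        calls = p >= t
        se[i] = np.mean(calls[pos])
        sp[i] = np.mean(~calls[neg])
        g[i] = gmean(se[i], sp[i])
    best_g = g[observed].max()
    best = int(np.flatnonzero(observed & (g == best_g))[0])  # smallest observed maximizer
    return ThresholdScan(candidates, se, sp, g, float(candidates[best]))
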