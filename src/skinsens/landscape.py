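"""Activity-landscape roughness (ROGI), 2-D projections, and chemical-space
grouping.

The roughness index quantifies how rugged a structure–activity landscape is:
progressively merge compounds by complete-linkage clustering at increasing
distance thresholds t ∈ [0, 1], coarse-grain the activity to size-weighted
cluster means, and measure how fast the weighted dispersion σ(t) falls from
its full-data value σ(0):

    ROGI = 2 ∫₀¹ (σ(0) − σ(t)) dt

A smooth landscape loses dispersion only at large t (similar compounds have
similar activity, so early merges change little) giving a small score; a
landscape full of activity cliffs collapses dispersion immediately and
scores high.  Activities are min–max normalized first, so the score is
invariant to positive affine transforms and lies in [0, 1].

Projections use metric MDS on the normalized distance matrix; activity
values are interpolated over the 2-D coordinates to draw surface/contour
grids.  Chemical-space grouping embeds Morgan radius-2/2048-bit
fingerprints with UMAP and groups compounds by density (DBSCAN) on the
embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import griddata
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN
from sklearn.manifold import MDS
from sklearn.neighbors import NearestNeighbors

from . import features


@dataclass
class LandscapeResult:
    """Normalized distances, activity vector, ROGI score, 2-D embedding and
    the interpolated activity grid for one continuous dataset."""

    distances: np.ndarray
    activity: np.ndarray
    rogi_score: float
    coordinates: np.ndarray
    grid: np.ndarray


@dataclass
class ChemSpaceGrouping:
    """2-D embedding plus a density-based group label per compound
    (−1 = noise)."""

    smiles: list
    coordinates: np.ndarray
    groups: np.ndarray
    seed: int


def normalized_distances(feature_matrix: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances rescaled to [0, 1] by the maximum."""
    m = np.asarray(feature_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    d = squareform(pdist(m))
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def _weighted_dispersion(values: np.ndarray, weights: np.ndarray) -> float:
    mean = float(np.sum(weights * values))
    return float(np.sqrt(np.sum(weights * (values - mean) ** 2)))


def rogi(distance_matrix: np.ndarray, activity) -> float:
    """Roughness index of an activity landscape (see module docstring).

    The threshold grid is the set of complete-linkage merge heights plus
    {0, 1}; the integral is trapezoidal, following the reference
    construction of the index.  Constant activity scores exactly 0.
    """
    d = np.asarray(distance_matrix, dtype=float)
    y = np.asarray(activity, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != y.size:
        raise ValueError("distance matrix and activity lengths must match")
    if not np.all(np.isfinite(y)):
        raise ValueError("activity must be finite")
    n = y.size
    y = _minmax(y)
    if np.all(y == y[0]):
        return 0.0
    condensed = squareform(d, checks=False)
    if np.all(condensed == condensed[0]) and not np.all(y == y[0]):
        warnings.warn("constant distances with varying activity: maximal roughness")
    link = linkage(condensed, method="complete")
    thresholds = np.unique(np.clip(np.concatenate([[0.0, 1.0], link[:, 2]]), 0.0, 1.0))
    sigma0 = _weighted_dispersion(y, np.full(n, 1.0 / n))
    losses = []
    for t in thresholds:
        clusters = fcluster(link, t, criterion="distance")
        ids = np.unique(clusters)
        means = np.array([y[clusters == c].mean() for c in ids])
        weights = np.array([np.sum(clusters == c) for c in ids], dtype=float) / n
        losses.append(sigma0 - _weighted_dispersion(means, weights))
    return float(2.0 * np.trapezoid(losses, thresholds))


def mds_embed(distance_matrix: np.ndarray, seed: int = 0) -> np.ndarray:
    """Stress-minimizing 2-D metric embedding of a precomputed distance
    matrix; reproducible from the seed."""
    d = np.asarray(distance_matrix, dtype=float)
    mds = MDS(
        n_components=2,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress=False,
        n_init=4,
        max_iter=3000,
        eps=1e-12,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mds.fit_transform(d)


def activity_grid(coordinates: np.ndarray, activity, resolution: int = 50) -> np.ndarray:
    """Linear interpolation of activity over a regular r×r grid spanning the
    coordinate bounding box (NaN outside the convex hull).

    Linear barycentric interpolation passes through the data points and
    never over/undershoots the input range inside the hull.
    """
    coords = np.asarray(coordinates, dtype=float)
    y = np.asarray(activity, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    spread = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-10) < 2:
        raise ValueError("points are collinear; cannot interpolate a surface")
    gx = np.linspace(coords[:, 0].min(), coords[:, 0].max(), resolution)
    gy = np.linspace(coords[:, 1].min(), coords[:, 1].max(), resolution)
    mx, my = np.meshgrid(gx, gy)
    return griddata(coords, y, (mx, my), method="linear")


def landscape_analysis(
    feature_matrix: np.ndarray, activity, seed: int = 0, resolution: int = 50
) -> LandscapeResult:
    """Distances → ROGI → MDS → interpolated grid, in one call."""
    d = normalized_distances(feature_matrix)
    score = rogi(d, activity)
    coords = mds_embed(d, seed=seed)
    grid = activity_grid(coords, activity, resolution=resolution)
    return LandscapeResult(d, np.asarray(activity, dtype=float), score, coords, grid)


def chemspace_grouping(
    smiles_list: list,
    seed: int = 0,
    min_group_size: int = 3,
    variance_threshold: float = 0.01,
) -> ChemSpaceGrouping:
    """Morgan-fingerprint chemical-space map with density-based groups.

    Radius-2/2048-bit fingerprints are variance-filtered, embedded in 2-D
    with UMAP (seeded), and grouped with DBSCAN whose radius comes from a
    k-distance heuristic.  Compounds are canonically sorted internally
    before embedding, so the partition is invariant to input order (group
    labels are reported in the caller's order).
    """
    if len(smiles_list) < 10:
        raise ValueError("too few for embedding (need >= 10 compounds)")
    import umap  # heavy import; deferred

    order = np.argsort(np.asarray(smiles_list, dtype=object))
    sorted_smiles = [smiles_list[i] for i in order]
    fm = features.fingerprint_matrix(sorted_smiles, "ecfp4")
    sel = features.variance_filter(fm.values, threshold=variance_threshold)
    X = sel.apply(fm.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(15, len(sorted_smiles) - 1),
            random_state=seed,
            n_jobs=1,
        )
        emb = reducer.fit_transform(X)
    k = min(min_group_size, len(sorted_smiles) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    kdist = np.sort(nn.kneighbors(emb)[0][:, -1])
    eps = float(np.percentile(kdist, 90)) or 1.0
    groups = DBSCAN(eps=eps, min_samples=min_group_size).fit_predict(emb)

    coords = np.empty_like(emb)
    labels = np.empty(len(smiles_list), dtype=int)
    coords[order] = emb
    labels[order] = groups
    return ChemSpaceGrouping(list(smiles_list), coords, labels, seed)
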