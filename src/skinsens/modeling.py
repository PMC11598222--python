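"""Classifier training, Bayesian hyperparameter search, 5-fold external
cross-validation, and performance metrics for sensitization QSAR models.

Three algorithm families are supported — random forest, gradient boosting
(LightGBM) and RBF-kernel SVM — each emitting class probabilities.  Model
selection uses an in-house Bayesian optimizer: a Gaussian-process surrogate
with expected-improvement acquisition over documented search spaces, where
trial 0 always evaluates the default configuration so the returned setting
can never score below it.

Cross-validation is *external*: each fold fits feature selection, scaling,
the applicability domain and the model on its 80% training split alone, and
scores the held-out 20%.  Out-of-fold probabilities are pooled, the decision
threshold is calibrated on the pool, and metrics are reported over in-domain
compounds together with coverage.

Binary metrics follow the standard confusion-matrix definitions

    SE = TP/(TP+FN)     SP = TN/(TN+FP)     CCR = (SE+SP)/2
    PPV = TP/(TP+FP)    NPV = TN/(TN+FN)

with zero-denominator values reported as undefined (``None``), never as 0.
Multiclass metrics are one-vs-rest per class, macro-averaged over classes
with defined values.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import applicability, calibration, features
from .curation import CuratedDataset

ALGORITHMS = ("random_forest", "lightgbm", "svm")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce one modeling run.

    ``trials`` counts hyperparameter-search evaluations (1 = defaults only);
    ``z`` is the applicability-domain significance parameter; ``rfe`` turns
    recursive feature elimination on for the continuous-descriptor feature
    kind (fingerprint bit identity is always preserved).
    """

    task: str = "binary"
    scheme: str = "WES"
    feature_kind: str = "ecfp4"
    algorithm: str = "random_forest"
    k: int = 5
    trials: int = 1
    seed: int = 0
    z: float = 0.5
    calibrate: bool = True
    undersample: bool = True
    rfe: bool = False
    rfe_target: Optional[int] = None

    def __post_init__(self):
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_kind not in features.FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Folds and balancing
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Assignment of each compound index to exactly one of k folds."""

    assignment: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_fold_plan(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified partition into k folds of near-equal size.

    A class with fewer than k members triggers a warning (from the
    stratifier) and is spread across folds as evenly as possible.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels.size < k:
        raise ValueError("need at least k compounds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((labels.size, 1)), labels)):
        assignment[test_idx] = fold
    return FoldPlan(assignment, k, seed)


def undersample_majority(dataset: CuratedDataset, seed: int = 0) -> CuratedDataset:
    """Randomly shrink the majority class to the size of the second-largest.

    Only the majority class loses members; an already balanced dataset comes
    back unchanged (items identical, order preserved).
    """
    if dataset.task != "multiclass":
        raise ValueError("undersampling applies to multiclass datasets")
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (major, n_major), (_, n_second) = ordered[0], ordered[1]
    if n_major == n_second:
        return dataset
    rng = np.random.default_rng(seed)
    major_pos = [i for i, (_, y) in enumerate(dataset.items) if y == major]
    keep = set(rng.choice(major_pos, size=n_second, replace=False).tolist())
    items, log = [], list(dataset.log)
    for i, item in enumerate(dataset.items):
        if item[1] == major and i not in keep:
            log.append((item[0], "undersampled", "majority_class"))
        else:
            items.append(item)
    return CuratedDataset(dataset.task, dataset.scheme, items, log)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """SE/SP/CCR/PPV/NPV (None where the denominator is zero), optional AUC,
    coverage (%) and probability threshold, plus per-class sub-reports for
    multiclass."""

    se: Optional[float] = None
    sp: Optional[float] = None
    ccr: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    auc: Optional[float] = None
    coverage: Optional[float] = None
    pt: Optional[float] = None
    per_class: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("se", "sp", "ccr", "ppv", "npv", "auc", "coverage", "pt")}
        if self.per_class is not None:
            d["per_class"] = {str(c): r.to_dict() for c, r in self.per_class.items()}
        return d


def confusion_counts(y_true, y_called, positive_class=1) -> ConfusionCounts:
    """Exhaustive TP/TN/FP/FN counts treating ``positive_class`` as positive."""
    y_true = np.asarray(y_true)
    y_called = np.asarray(y_called)
    if y_true.shape != y_called.shape:
        raise ValueError("y_true and y_called must have equal length")
    if positive_class == 1 and set(np.unique(np.concatenate([y_true, y_called]))) - {0, 1}:
        raise ValueError("binary labels must lie in {0, 1}")
    t = y_true == positive_class
    c = y_called == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & c)),
        tn=int(np.sum(~t & ~c)),
        fp=int(np.sum(~t & c)),
        fn=int(np.sum(t & ~c)),
    )


def _safe_div(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def binary_metrics(counts: ConfusionCounts) -> MetricsReport:
    """SE/SP/CCR/PPV/NPV from confusion counts; undefined stays ``None``."""
    se = _safe_div(counts.tp, counts.tp + counts.fn)
    sp = _safe_div(counts.tn, counts.tn + counts.fp)
    ccr = (se + sp) / 2 if se is not None and sp is not None else None
    return MetricsReport(
        se=se,
        sp=sp,
        ccr=ccr,
        ppv=_safe_div(counts.tp, counts.tp + counts.fp),
        npv=_safe_div(counts.tn, counts.tn + counts.fn),
    )


def _macro(values) -> Optional[float]:
    defined = [v for v in values if v is not None]
    return sum(defined) / len(defined) if defined else None


def multiclass_metrics(y_true, y_called) -> MetricsReport:
    """One-vs-rest metrics per class, macro-averaged with equal class weight;
    classes with an undefined value are excluded from that macro average."""
    y_true = np.asarray(y_true)
    y_called = np.asarray(y_called)
    labels = sorted(set(y_true.tolist()) | set(y_called.tolist()))
    if set(labels) - {0, 1, 2}:
        raise ValueError("multiclass labels must lie in {0, 1, 2}")
    per_class = {
        c: binary_metrics(
            ConfusionCounts(
                tp=int(np.sum((y_true == c) & (y_called == c))),
                tn=int(np.sum((y_true != c) & (y_called != c))),
                fp=int(np.sum((y_true != c) & (y_called == c))),
                fn=int(np.sum((y_true == c) & (y_called != c))),
            )
        )
        for c in labels
    }
    se = _macro(r.se for r in per_class.values())
    sp = _macro(r.sp for r in per_class.values())
    return MetricsReport(
        se=se,
        sp=sp,
        ccr=(se + sp) / 2 if se is not None and sp is not None else None,
        ppv=_macro(r.ppv for r in per_class.values()),
        npv=_macro(r.npv for r in per_class.values()),
        per_class=per_class,
    )


def auc_score(y_true, probabilities) -> Optional[float]:
    """Area under the ROC curve; macro one-vs-rest for multiclass.

    Equals the probability that a random positive outranks a random negative
    (ties counted half).  Undefined (``None``) when only one class is present.
    """
    y_true = np.asarray(y_true)
    p = np.asarray(probabilities, dtype=float)
    if np.unique(y_true).size < 2:
        return None
    if p.ndim == 1:
        return float(roc_auc_score(y_true, p))
    return float(roc_auc_score(y_true, p, multi_class="ovr", average="macro"))


def ccr_score(y_true, y_called, task: str = "binary") -> Optional[float]:
    """Correct classification rate — the tuning and headline metric."""
    if task == "binary":
        return binary_metrics(confusion_counts(y_true, y_called)).ccr
    return multiclass_metrics(y_true, y_called).ccr


# ---------------------------------------------------------------------------
# Training and Bayesian hyperparameter search
# ---------------------------------------------------------------------------

#: Search spaces: (low, high, log-scale?, integer?).  Conventional ranges for
#: the three families; the default configuration sits inside every space.
SEARCH_SPACES = {
    "random_forest": {
        "n_estimators": (100, 1000, True, True),
        "max_depth": (3, 30, False, True),
    },
    "lightgbm": {
        "num_leaves": (15, 255, True, True),
        "learning_rate": (1e-3, 0.3, True, False),
        "n_estimators": (100, 1000, True, True),
    },
    "svm": {
        "C": (1e-2, 1e3, True, False),
        "gamma": (1e-4, 10.0, True, False),
    },
}


def default_hyperparameters(algorithm: str, X=None) -> dict:
    """The default configuration evaluated as trial 0 of every search."""
    if algorithm == "random_forest":
        return {"n_estimators": 100, "max_depth": 30}
    if algorithm == "lightgbm":
        return {"num_leaves": 31, "learning_rate": 0.1, "n_estimators": 100}
    if algorithm == "svm":
        gamma = 1.0
        if X is not None:
            X = np.asarray(X, dtype=float)
            var = X.var()
            if var > 0:
                gamma = 1.0 / (X.shape[1] * var)  # sklearn's "scale"
        lo, hi = SEARCH_SPACES["svm"]["gamma"][:2]
        return {"C": 1.0, "gamma": float(np.clip(gamma, lo, hi))}
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train(X, y, algorithm: str, hyperparameters: Optional[dict] = None, seed: int = 0):
    """Fit one classifier; the returned predictor exposes ``predict_proba``
    with rows summing to 1.  Raises on single-class labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have equal row counts")
    if np.unique(y).size < 2:
        raise ValueError("cannot train on a single class")
    hp = dict(hyperparameters or default_hyperparameters(algorithm, X))
    if algorithm == "random_forest":
        model = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    elif algorithm == "lightgbm":
        model = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **hp)
    elif algorithm == "svm":
        model = SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def _params_to_unit(algorithm: str, params: dict) -> np.ndarray:
    x = []
    for name, (lo, hi, log, _is_int) in SEARCH_SPACES[algorithm].items():
        v = params[name]
        if log:
            x.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            x.append((v - lo) / (hi - lo))
    return np.clip(np.asarray(x), 0.0, 1.0)


def _unit_to_params(algorithm: str, x: np.ndarray) -> dict:
    params = {}
    for xi, (name, (lo, hi, log, is_int)) in zip(x, SEARCH_SPACES[algorithm].items()):
        if log:
            v = float(np.exp(np.log(lo) + xi * (np.log(hi) - np.log(lo))))
        else:
            v = float(lo + xi * (hi - lo))
        params[name] = int(round(v)) if is_int else v
    return params


def _inner_cv_ccr(X, y, algorithm, params, task, seed, k_inner=3) -> float:
    """Tuning objective: mean CCR over a stratified inner CV."""
    y = np.asarray(y)
    plan = make_fold_plan(y, k=k_inner, seed=seed)
    scores = []
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        if np.unique(y[tr]).size < 2:
            continue
        model = train(X[tr], y[tr], algorithm, params, seed=seed)
        proba = model.predict_proba(X[te])
        called = model.classes_[np.argmax(proba, axis=1)]
        s = ccr_score(y[te], called, task)
        if s is not None:
            scores.append(s)
    return float(np.mean(scores)) if scores else 0.0


def tune_hyperparameters(
    X, y, algorithm: str, n_trials: int = 20, seed: int = 0, task: str = "binary"
) -> dict:
    """Bayesian hyperparameter search maximizing mean inner-CV CCR.

    Trial 0 evaluates the default configuration; a handful of seeded random
    trials initialize a Gaussian-process surrogate (Matérn 5/2 on the
    unit-cube encoding of the space), after which candidates maximizing
    expected improvement are evaluated.  The best observed configuration is
    returned, so its objective is never below the default's; ties go to the
    earliest trial.
    """
    if algorithm not in SEARCH_SPACES:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    dim = len(SEARCH_SPACES[algorithm])

    observed_x, observed_y, trial_params = [], [], []

    def evaluate(params: dict):
        score = _inner_cv_ccr(X, y, algorithm, params, task, seed)
        observed_x.append(_params_to_unit(algorithm, params))
        observed_y.append(score)
        trial_params.append(params)

    evaluate(default_hyperparameters(algorithm, X))
    n_init = min(4, n_trials - 1)
    for _ in range(n_init):
        evaluate(_unit_to_params(algorithm, rng.random(dim)))

    for _ in range(n_trials - 1 - n_init):
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(dim, 0.3)),
            alpha=1e-4,
            normalize_y=True,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(observed_x), np.array(observed_y))
        candidates = rng.random((256, dim))
        mu, sigma = gp.predict(candidates, return_std=True)
        best = max(observed_y)
        sigma = np.maximum(sigma, 1e-9)
        z = (mu - best) / sigma
        ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
        evaluate(_unit_to_params(algorithm, candidates[int(np.argmax(ei))]))

    return dict(trial_params[int(np.argmax(observed_y))])


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """A fitted predictor with everything needed to score new compounds:
    feature selection, optional scaler, calibrated threshold, applicability
    domain, and run metadata."""

    algorithm: str
    hyperparameters: dict
    predictor: object
    feature_kind: str
    selection: features.SelectionState
    scaler: Optional[features.ScalerState]
    pt: float
    ad: applicability.ADState
    metadata: dict = field(default_factory=dict)

    def transform(self, X_original: np.ndarray) -> np.ndarray:
        """Original feature space → the space the predictor consumes."""
        X = self.selection.apply(np.asarray(X_original, dtype=float))
        if self.scaler is not None:
            X = features.apply_minmax(self.scaler, X)
        return X

    def prob_matrix(self, X_original: np.ndarray) -> np.ndarray:
        return self.predictor.predict_proba(self.transform(X_original))

    def positive_prob(self, X_original: np.ndarray) -> np.ndarray:
        """P(class 1) for binary bundles."""
        proba = self.prob_matrix(X_original)
        col = int(np.flatnonzero(self.predictor.classes_ == 1)[0])
        return proba[:, col]


def _fit_fold_state(X_train, y_train, config: RunConfig):
    """Fit selection (+ optional RFE) and scaler on training rows only."""
    sel = features.variance_filter(X_train, threshold=0.01)
    X_sel = sel.apply(X_train)
    if config.feature_kind == "rdkit2d" and config.rfe:
        target = config.rfe_target or max(1, X_sel.shape[1] // 2)
        rfe = features.rfe_select(X_sel, y_train, target, seed=config.seed)
        sel = sel.compose(rfe)
        X_sel = rfe.apply(X_sel)
    scaler = None
    if config.feature_kind == "rdkit2d":
        scaler = features.fit_minmax(X_sel)
        X_sel = features.apply_minmax(scaler, X_sel)
    return sel, scaler, X_sel


# ---------------------------------------------------------------------------
# 5-fold external cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Pooled and per-fold metrics plus the out-of-fold prediction table."""

    pooled: MetricsReport
    fold_reports: list
    pt: float
    predictions: pd.DataFrame
    config: RunConfig
    fold_plan: FoldPlan


def crossvalidate(dataset: CuratedDataset, config: RunConfig) -> CVReport:
    """External k-fold cross-validation of the full pipeline.

    Per fold everything downstream of featurization — undersampling (for
    multiclass), the variance filter and RFE, min–max scaling, tuning, model
    fitting and the applicability domain — sees the 80% training split only.
    Out-of-fold probabilities are pooled; the probability threshold is
    selected on the pool (binary task with calibration on, else 0.5); and
    headline metrics cover in-domain out-of-fold compounds, with coverage
    the in-domain percentage.
    """
    smiles = dataset.smiles
    y = np.asarray(dataset.labels)
    fm = features.featurize(smiles, config.feature_kind)
    X_all = fm.values
    plan = make_fold_plan(y, k=config.k, seed=config.seed)

    n = len(smiles)
    n_classes = int(np.unique(y).size)
    proba = np.full((n, n_classes), np.nan)
    ad_dist = np.full(n, np.nan)
    in_ad = np.zeros(n, dtype=bool)
    scored = np.zeros(n, dtype=bool)
    class_order = np.sort(np.unique(y))

    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        X_tr, y_tr = X_all[tr], y[tr]
        if config.task == "multiclass" and config.undersample:
            sub = CuratedDataset(
                "multiclass", dataset.scheme, [(smiles[i], int(y[i])) for i in tr]
            )
            sub = undersample_majority(sub, seed=config.seed + fold)
            kept = {s for s, _ in sub.items}
            mask = np.array([smiles[i] in kept for i in tr])
            X_tr, y_tr = X_tr[mask], y_tr[mask]
        if np.unique(y_tr).size < 2:
            warnings.warn(f"fold {fold} skipped: single-class training split")
            continue
        sel, scaler, X_fit = _fit_fold_state(X_tr, y_tr, config)
        hp = default_hyperparameters(config.algorithm, X_fit)
        if config.trials > 1:
            hp = tune_hyperparameters(
                X_fit, y_tr, config.algorithm, config.trials, seed=config.seed, task=config.task
            )
        model = train(X_fit, y_tr, config.algorithm, hp, seed=config.seed)
        ad = applicability.fit_ad(X_fit, z=config.z)

        X_te = sel.apply(X_all[te])
        if scaler is not None:
            X_te = features.apply_minmax(scaler, X_te)
        p = model.predict_proba(X_te)
        for j, cls in enumerate(model.classes_):
            proba[te, int(np.flatnonzero(class_order == cls)[0])] = p[:, j]
        d = applicability.ad_distances(ad, X_te)
        ad_dist[te] = d
        in_ad[te] = d <= ad.cutoff
        scored[te] = True

    if not scored.any():
        raise ValueError("no fold could be scored")

    pos_col = int(np.flatnonzero(class_order == 1)[0]) if 1 in class_order else -1
    if config.task == "binary":
        p_pos = proba[:, pos_col]
        if config.calibrate:
            scan = calibration.select_threshold(y[scored], p_pos[scored])
            pt = scan.selected
        else:
            pt = 0.5
        calls = np.full(n, -1)
        calls[scored] = calibration.apply_threshold(p_pos[scored], pt)
    else:
        pt = 0.5
        calls = np.full(n, -1)
        calls[scored] = class_order[np.nanargmax(proba[scored], axis=1)]

    def _report(mask) -> MetricsReport:
        use = mask & scored & in_ad
        if config.task == "binary":
            rep = binary_metrics(confusion_counts(y[use], calls[use]))
            rep.auc = auc_score(y[use], proba[use, pos_col])
        else:
            rep = multiclass_metrics(y[use], calls[use])
            rep.auc = auc_score(y[use], proba[use])
        rep.coverage = 100.0 * float(np.sum(mask & scored & in_ad)) / max(
            1, int(np.sum(mask & scored))
        )
        rep.pt = pt
        return rep

    pooled = _report(np.ones(n, dtype=bool))
    fold_reports = [_report(plan.assignment == f) for f in range(plan.k)]

    predictions = pd.DataFrame(
        {
            "std_smiles": smiles,
            "fold": plan.assignment,
            "label": y,
            "prob": proba[:, pos_col] if config.task == "binary" else list(proba),
            "call": calls,
            "ad_distance": ad_dist,
            "in_ad": in_ad,
            "scored": scored,
        }
    )
    return CVReport(pooled, fold_reports, pt, predictions, config, plan)


def y_randomize(
    dataset: CuratedDataset, config: RunConfig, rounds: int = 10, seed: int = 0
) -> list:
    """Repeat the full cross-validation on label-shuffled copies.

    Each round draws an independent seed; a model whose real-label CCR does
    not clearly exceed the shuffled distribution owes its score to chance.
    Returns one pooled ``MetricsReport`` per round.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    reports = []
    children = np.random.SeedSequence(seed).spawn(rounds)
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        labels = np.asarray(dataset.labels)
        shuffled = rng.permutation(labels)
        shuffled_ds = CuratedDataset(
            dataset.task,
            dataset.scheme,
            [(s, int(v)) for s, v in zip(dataset.smiles, shuffled)],
        )
        cfg = replace(config, seed=sub_seed)
        reports.append(crossvalidate(shuffled_ds, cfg).pooled)
    return reports


# ---------------------------------------------------------------------------
# Final model fitting
# ---------------------------------------------------------------------------


def fit_bundle(dataset: CuratedDataset, config: RunConfig) -> tuple:
    """Cross-validate for the threshold, then refit on the full dataset.

    Returns ``(ModelBundle, CVReport)``; the bundle's PT comes from the
    pooled out-of-fold calibration and its AD from the full training matrix.
    """
    report = crossvalidate(dataset, config)
    smiles = dataset.smiles
    y = np.asarray(dataset.labels)
    X_all = features.featurize(smiles, config.feature_kind).values
    if config.task == "multiclass" and config.undersample:
        sub = undersample_majority(dataset, seed=config.seed)
        keep = {s for s, _ in sub.items}
        mask = np.array([s in keep for s in smiles])
        X_all_fit, y_fit = X_all[mask], y[mask]
    else:
        X_all_fit, y_fit = X_all, y
    sel, scaler, X_fit = _fit_fold_state(X_all_fit, y_fit, config)
    hp = default_hyperparameters(config.algorithm, X_fit)
    if config.trials > 1:
        hp = tune_hyperparameters(
            X_fit, y_fit, config.algorithm, config.trials, seed=config.seed, task=config.task
        )
    model = train(X_fit, y_fit, config.algorithm, hp, seed=config.seed)
    ad = applicability.fit_ad(X_fit, z=config.z)
    digest = hashlib.sha256("\n".join(smiles).encode()).hexdigest()
    bundle = ModelBundle(
        algorithm=config.algorithm,
        hyperparameters=hp,
        predictor=model,
        feature_kind=config.feature_kind,
        selection=sel,
        scaler=scaler,
        pt=report.pt,
        ad=ad,
        metadata={
            "task": config.task,
            "scheme": dataset.scheme,
            "feature_kind": config.feature_kind,
            "seed": config.seed,
            "config": config.to_dict(),
            "training_digest": digest,
        },
    )
    return bundle, report
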