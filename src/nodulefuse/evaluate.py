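"""Classification, ROC/AUC, repeated-split aggregation, and t tests.

The evaluation protocol mirrors the five-experiment grid:

1. biomarkers only (logistic regression + random forest),
2. images only (3D CNN scores + random forest on 64-dim deep features),
3. deep features + tiled biomarkers (length 128),
4. deep features + tiled radiomics (length 127),
5. deep features + both (length 130),

each under fully supervised (distribution A) and semi-supervised
(distribution B) modes, repeated over fresh seeded 80:20 splits (default
1000 repeats for experiment 1, 30 for experiments 2-5).  Repeats share
split seeds across compared models/modes (paired design), which strictly
reduces comparison variance.  Model AUC samples are compared with a
two-tailed Student's (pooled-variance) t test at alpha = 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cnn import ArchitectureSpec, MaligNet, TrainConfig, build_model, normalize_boxes
from .cnn import train as train_cnn
from .data import (
    LabeledDataset,
    NoduleRecord,
    SplitPair,
    biomarker_matrix,
    build_distribution_A,
    split,
)
from .exceptions import ConfigurationError, TrainingError
from .fusion import fuse_cohort
from .pseudolabel import DEFAULT_K, build_distribution_B
from .radiomics import radiomics_matrix

logger = logging.getLogger(__name__)

ALPHA = 0.05
FPR_GRID = np.linspace(0.0, 1.0, 101)

#: default repeat counts per experiment
DEFAULT_REPEATS = {1: 1000, 2: 30, 3: 30, 4: 30, 5: 30}

#: experiment id -> fusion recipe for the random-forest-on-features model
EXPERIMENT_RECIPES = {2: "image_only", 3: "image+biomarker",
                      4: "image+radiomic", 5: "image+both"}


def derive_seed(*keys: int) -> int:
    """Stable child seed (< 2**31) from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if (np.diff(self.fpr) < -1e-12).any() or (np.diff(self.tpr) < -1e-12).any():
            raise ValueError("fpr/tpr must be monotone non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and
                self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve over all distinct score thresholds + trapezoidal AUC.

    The trapezoidal AUC over the full threshold sweep equals the pairwise
    concordance statistic (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thr, fpr, tpr, float(np.trapezoid(tpr, fpr)))


def average_roc(curves: list[ROCCurve]) -> ROCCurve:
    """Vertical averaging on a fixed 101-point FPR grid.

    Each curve's tpr is linearly interpolated onto the grid, the grid
    values are averaged, and the AUC is recomputed on the averaged curve.
    """
    if not curves:
        raise ValueError("cannot average zero ROC curves")
    grid_tprs = [np.interp(FPR_GRID, c.fpr, c.tpr) for c in curves]
    mean_tpr = np.mean(grid_tprs, axis=0)
    # pin the threshold-sweep endpoints so the averaged curve is a valid ROC
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ROCCurve(
        np.array([]), FPR_GRID, mean_tpr, float(np.trapezoid(mean_tpr, FPR_GRID))
    )


# ---------------------------------------------------------------------------
# Student's t test
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    alpha: float = ALPHA
    significant: bool = False

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < self.alpha)


def t_test(auc_a: np.ndarray, auc_b: np.ndarray, alpha: float = ALPHA) -> TTestResult:
    """Two-tailed Student's (pooled-variance) two-sample t test."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each AUC sample needs length >= 2")
    df = len(a) + len(b) - 2
    pooled_var = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, alpha)
        warnings.warn(
            "degenerate t test: zero within-group variance with unequal means",
            stacklevel=2,
        )
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TTestResult(float(t), df, 0.0, alpha)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), df, float(p), alpha)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class Scorer:
    """A fitted classifier exposing class-1 probabilities."""

    def __init__(self, clf, kind: str):
        self._clf = clf
        self.kind = kind

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(np.asarray(features, dtype=float))[:, 1]


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "random_forest",
    seed: int = 0,
    n_trees: int = 100,
) -> Scorer:
    """Fit a logistic-regression or random-forest probability scorer."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise TrainingError("cannot fit a classifier on single-class labels")
    if kind == "logistic":
        clf = LogisticRegression(max_iter=2000)
    elif kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    else:
        raise ConfigurationError(f"unknown classifier kind {kind!r}")
    clf.fit(features, labels)
    return Scorer(clf, kind)


# ---------------------------------------------------------------------------
# The repeated-split experiment harness
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-model outcome of one experiment under one supervision mode."""

    experiment_id: int
    supervision: str
    model_name: str
    auc_samples: np.ndarray
    mean_auc: float
    mean_roc: ROCCurve

    def __post_init__(self) -> None:
        self.auc_samples = np.asarray(self.auc_samples, dtype=float)
        if self.supervision not in ("full", "semi"):
            raise ValueError("supervision must be 'full' or 'semi'")


def _split_for_mode(
    records: list[NoduleRecord], supervision: str, seed: int,
    ratio: float, best_k: int,
) -> SplitPair:
    if supervision == "full":
        return split(build_distribution_A(records), ratio, seed)
    if supervision == "semi":
        return build_distribution_B(records, k=best_k, seed=seed, ratio=ratio)
    raise ConfigurationError(f"unknown supervision mode {supervision!r}")


def run_experiment(
    cohort: list[NoduleRecord],
    experiment_id: int,
    supervision: str = "full",
    n_repeats: int | None = None,
    seed: int = 0,
    ratio: float = 0.8,
    best_k: int = DEFAULT_K,
    rf_trees: int = 100,
    arch: ArchitectureSpec | None = None,
    train_config: TrainConfig | None = None,
    cnn_mode: str = "per_repeat",
    shared_cnn: MaligNet | None = None,
    shared_features: np.ndarray | None = None,
    shared_scores: np.ndarray | None = None,
) -> dict[str, ExperimentResult]:
    """Run one experiment, one supervision mode, over repeated splits.

    Returns a dict keyed by model name ("logistic"/"random_forest" for
    experiment 1; "cnn"/"cnn_rf" for experiment 2; "cnn_rf" for 3-5).

    ``cnn_mode``: "per_repeat" retrains the CNN inside every repeat (the
    reference protocol); "shared" trains it once on a pretrain split (or
    accepts a caller-supplied ``shared_cnn``) and reuses its features
    across repeats — the scaled-down protocol for desk-size runs.
    ``shared_features``/``shared_scores`` (aligned with ``cohort``) skip
    even the shared extraction, for callers comparing several experiments
    on one frozen CNN.
    """
    if experiment_id not in (1, 2, 3, 4, 5):
        raise ConfigurationError(f"experiment_id must be 1..5, got {experiment_id}")
    if cnn_mode not in ("per_repeat", "shared"):
        raise ConfigurationError(f"unknown cnn_mode {cnn_mode!r}")
    n_repeats = DEFAULT_REPEATS[experiment_id] if n_repeats is None else n_repeats
    index_of = {id(r): i for i, r in enumerate(cohort)}
    bio_all = biomarker_matrix(cohort)

    needs_cnn = experiment_id >= 2
    needs_rad = experiment_id in (4, 5)
    recipe = EXPERIMENT_RECIPES.get(experiment_id)
    rad_all = radiomics_matrix(cohort) if needs_rad else None
    boxes_all = None
    feats_all = None
    model = shared_cnn
    if needs_cnn:
        for r in cohort:
            if r.volume is None or r.volume.size == 0:
                raise ConfigurationError(
                    f"experiment {experiment_id} requires nodule volumes"
                )
        boxes_all = normalize_boxes(np.stack([r.volume for r in cohort]))
        train_config = train_config or TrainConfig()
        if cnn_mode == "shared" and shared_features is not None:
            feats_all = np.asarray(shared_features)
            scores_all = (
                np.asarray(shared_scores)
                if shared_scores is not None
                else np.full(len(cohort), 0.5)
            )
            if len(feats_all) != len(cohort):
                raise ConfigurationError("shared_features misaligned with cohort")
        elif cnn_mode == "shared":
            if model is None:
                pre_pair = _split_for_mode(
                    cohort, supervision, derive_seed(seed, 9999), ratio, best_k
                )
                pre_idx = [index_of[id(r)] for r in pre_pair.train.records]
                model = build_model(arch, seed=derive_seed(seed, 7))
                logger.info("training shared CNN on %d boxes", len(pre_idx))
                train_cnn(
                    model, boxes_all[pre_idx], pre_pair.train.labels, train_config
                )
            feats_all = model.extract_features(boxes_all)
            scores_all = model.predict_scores(boxes_all)

    results: dict[str, list] = {}

    def record(name: str, scores, labels):
        curve = roc_auc(scores, labels)
        results.setdefault(name, []).append(curve)

    for rep in range(n_repeats):
        rep_seed = derive_seed(seed, rep)
        pair = _split_for_mode(cohort, supervision, rep_seed, ratio, best_k)
        tr_idx = np.array([index_of[id(r)] for r in pair.train.records])
        te_idx = np.array([index_of[id(r)] for r in pair.test.records])
        y_tr, y_te = pair.train.labels, pair.test.labels

        if experiment_id == 1:
            for kind in ("logistic", "random_forest"):
                scorer = fit_classifier(
                    bio_all[tr_idx], y_tr, kind, seed=rep_seed, n_trees=rf_trees
                )
                record(kind, scorer(bio_all[te_idx]), y_te)
            continue

        if cnn_mode == "per_repeat":
            model = build_model(arch, seed=derive_seed(seed, rep, 7))
            train_cnn(model, boxes_all[tr_idx], y_tr, train_config)
            f_tr = model.extract_features(boxes_all[tr_idx])
            f_te = model.extract_features(boxes_all[te_idx])
        else:
            f_tr, f_te = feats_all[tr_idx], feats_all[te_idx]

        if experiment_id == 2:
            cnn_scores = (
                scores_all[te_idx]
                if cnn_mode == "shared"
                else model.predict_scores(boxes_all[te_idx])
            )
            record("cnn", cnn_scores, y_te)
            fused_tr, fused_te = f_tr, f_te
        else:
            fused_tr = fuse_cohort(
                f_tr,
                biomarkers=bio_all[tr_idx],
                radiomics=rad_all[tr_idx] if needs_rad else None,
                recipe=recipe,
            )
            fused_te = fuse_cohort(
                f_te,
                biomarkers=bio_all[te_idx],
                radiomics=rad_all[te_idx] if needs_rad else None,
                recipe=recipe,
            )
        scorer = fit_classifier(
            fused_tr, y_tr, "random_forest", seed=rep_seed, n_trees=rf_trees
        )
        record("cnn_rf", scorer(fused_te), y_te)

    out: dict[str, ExperimentResult] = {}
    for name, curves in results.items():
        aucs = np.array([c.auc for c in curves])
        out[name] = ExperimentResult(
            experiment_id=experiment_id,
            supervision=supervision,
            model_name=name,
            auc_samples=aucs,
            mean_auc=float(aucs.mean()),
            mean_roc=average_roc(curves),
        )
    return out


def results_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """Tidy summary (experiment × model × supervision -> mean AUC)."""
    rows = [
        {
            "experiment": r.experiment_id,
            "model": r.model_name,
            "supervision": r.supervision,
            "n_repeats": len(r.auc_samples),
            "mean_auc": round(r.mean_auc, 6),
            "std_auc": round(float(r.auc_samples.std(ddof=1)), 6)
            if len(r.auc_samples) > 1
            else 0.0,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(["experiment", "model", "supervision"]).reset_index(
        drop=True
    )
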