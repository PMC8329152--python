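"""Semi-supervised stage: biomarker-space KNN pseudo-labeling of R3 nodules.

Intermediate-malignancy (R3) nodules sit near the benign/suspicious decision
boundary but show biomarker similarity to labeled nodules on either side.
A K-nearest-neighbors vote in raw 8-dimensional biomarker space (Euclidean
distance, unstandardized: all scales share a ~1-5 range) assigns them
provisional binary labels, enlarging the training set of distribution B.

The best-K selection procedure repeats a fresh 80:20 split of distribution A
many times (default 1000), evaluates every odd K in 1..51 (26 candidates) on
the validation part, and picks the K most frequently run-best; ties break by
higher mean validation accuracy, then smaller K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import (
    LabeledDataset,
    NoduleRecord,
    SplitPair,
    biomarker_matrix,
    build_distribution_A,
    split,
    split_indices,
)
from .exceptions import ConfigurationError, LabelingError

logger = logging.getLogger(__name__)

#: Odd K in 1..51 — the 26 candidate neighborhood sizes scanned by best-K
#: selection.
DEFAULT_K_GRID = tuple(range(1, 52, 2))

#: Default neighborhood size for pseudo-labeling (re-derivable via
#: :func:`select_best_k`).
DEFAULT_K = 21


def knn_classify(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority vote of the k Euclidean-nearest training points per query.

    ``k`` must be odd (no vote ties for binary labels) and at most the
    training-set size.  Distance ties at the k-th neighbor are resolved in
    favor of the earlier-indexed training record (stable sort), which keeps
    results permutation-checkable and seed-independent.
    """
    train_features = np.asarray(train_features, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if k % 2 == 0 or k < 1:
        raise ConfigurationError(f"k must be a positive odd integer, got {k}")
    if k > len(train_features):
        raise ConfigurationError(
            f"k={k} exceeds training set size {len(train_features)}"
        )
    dists = cdist(queries, train_features)
    nearest = np.argsort(dists, axis=1, kind="stable")[:, :k]
    votes = train_labels[nearest].sum(axis=1)
    return (votes * 2 > k).astype(int)


@dataclass
class KSelectionResult:
    """Outcome of the repeated-split best-K scan."""

    best_k: int
    accuracy_table: pd.DataFrame  # index: run, columns: K, values: val accuracy
    frequency_table: pd.Series  # per-K count of being the run-best
    n_runs: int

    def __post_init__(self) -> None:
        if self.best_k % 2 == 0:
            raise ValueError("best_k must be odd")
        if list(self.accuracy_table.columns) != list(self.frequency_table.index):
            raise ValueError("accuracy and frequency tables cover different K grids")


def select_best_k(
    dist_a: LabeledDataset,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    n_runs: int = 1000,
    ratio: float = 0.8,
    seed: int = 0,
) -> KSelectionResult:
    """Repeated-split scan for the best KNN neighborhood size.

    Per run: a fresh 80:20 split of distribution A, validation accuracy for
    every candidate K, and the run-best K recorded.  The final best K
    maximizes run-best frequency; ties break by higher mean validation
    accuracy, then by smaller K.
    """
    if any(k % 2 == 0 for k in k_grid):
        raise ConfigurationError("all candidate K values must be odd")
    features = biomarker_matrix(dist_a.records)
    labels = dist_a.labels
    if len(np.unique(labels)) < 2:
        raise LabelingError("distribution A must contain both classes")
    n = len(labels)
    n_train = int(round(ratio * n))
    if max(k_grid) > n_train:
        raise ConfigurationError(
            f"largest candidate K {max(k_grid)} exceeds train size {n_train}"
        )
    rng = np.random.default_rng(seed)
    acc = np.zeros((n_runs, len(k_grid)))
    best_per_run = np.zeros(n_runs, dtype=int)
    run = 0
    while run < n_runs:
        train_idx, val_idx = split_indices(n, ratio, rng)
        if len(np.unique(labels[train_idx])) < 2:
            logger.warning("run %d: single-class train split, resampled", run)
            continue
        d = cdist(features[val_idx], features[train_idx])
        order = np.argsort(d, axis=1, kind="stable")
        votes_sorted = labels[train_idx][order]
        cumvotes = np.cumsum(votes_sorted, axis=1)
        for j, k in enumerate(k_grid):
            pred = (cumvotes[:, k - 1] * 2 > k).astype(int)
            acc[run, j] = float((pred == labels[val_idx]).mean())
        best_per_run[run] = int(np.argmax(acc[run]))  # argmax: smaller K on ties
        run += 1
    freq = np.bincount(best_per_run, minlength=len(k_grid))
    mean_acc = acc.mean(axis=0)
    # frequency first, then mean accuracy, then smaller K (lexsort is stable)
    order = np.lexsort((np.arange(len(k_grid)), -mean_acc, -freq))
    best_k = int(k_grid[order[0]])
    return KSelectionResult(
        best_k=best_k,
        accuracy_table=pd.DataFrame(acc, columns=list(k_grid)),
        frequency_table=pd.Series(freq, index=list(k_grid), name="run_best_count"),
        n_runs=n_runs,
    )


def build_distribution_B(
    records: list[NoduleRecord],
    k: int = DEFAULT_K,
    seed: int = 0,
    ratio: float = 0.8,
    stratify: bool = False,
) -> SplitPair:
    """Semi-supervised train/test pair (R123 vs R345).

    The non-R3 records are split exactly as distribution A would be for the
    same seed (so the semi-supervised train set is a superset of the fully
    supervised one and the test sets coincide).  Train-side R3 records are
    pseudo-labeled by KNN on the train-side originals' biomarkers;
    test-side R3 records are dropped, since test sets never contain R3.
    """
    pair_a = split(build_distribution_A(records), ratio, seed, stratify=stratify)
    if len(np.unique(pair_a.train.labels)) < 2:
        raise LabelingError("no R12/R45 signal in train: cannot pseudo-label")
    r3_records = [r for r in records if r.malignancy == 3]

    train_records = list(pair_a.train.records)
    train_labels = list(pair_a.train.labels)
    train_prov = list(pair_a.train.provenance)
    if r3_records:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        if len(r3_records) >= 5:
            r3_train_idx, _ = split_indices(len(r3_records), ratio, rng)
        else:
            r3_train_idx = np.arange(len(r3_records))
        r3_train = [r3_records[i] for i in r3_train_idx]
        if r3_train:
            pseudo = knn_classify(
                biomarker_matrix(pair_a.train.records),
                pair_a.train.labels,
                biomarker_matrix(r3_train),
                k,
            )
            train_records.extend(r3_train)
            train_labels.extend(int(p) for p in pseudo)
            train_prov.extend(["pseudo"] * len(r3_train))

    train = LabeledDataset(
        train_records,
        np.array(train_labels),
        np.array(train_prov, dtype=object),
        "B",
    )
    test = LabeledDataset(
        list(pair_a.test.records), pair_a.test.labels, pair_a.test.provenance, "B"
    )
    return SplitPair(train, test, ratio, seed)
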