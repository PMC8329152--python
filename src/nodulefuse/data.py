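"""Core nodule records, binary-label dataset construction, and seeded splitting.

The pipeline treats malignancy-suspicion estimation as binary classification
over radiologist 1-5 malignancy scores (R1..R5):

* Distribution A (fully supervised): R1/R2 -> label 0 ("benign"),
  R4/R5 -> label 1 ("malignant"); intermediate R3 nodules are dropped.
* Distribution B (semi-supervised): R3 nodules are kept in the *training*
  side and pseudo-labeled in biomarker space (see
  :mod:`nodulefuse.pseudolabel`); test sets never contain R3 nodules so the
  two supervision modes are compared on identical ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, SplitError

#: Canonical biomarker column order used everywhere downstream (feature
#: matrices, KNN pseudo-labeling, fusion).
BIOMARKER_NAMES = (
    "subtlety",
    "int_structure",
    "calcification",
    "sphericity",
    "margin",
    "lobulation",
    "spiculation",
    "texture",
)

#: Ordinal range (lo, hi) of each biomarker, following the LIDC annotation
#: schema: most characteristics are scored 1-5, internal structure 1-4 and
#: calcification 1-6.  Categorical scales are treated numerically downstream
#: (Euclidean KNN, forests), mirroring common practice on this schema.
BIOMARKER_RANGES = {
    "subtlety": (1, 5),
    "int_structure": (1, 4),
    "calcification": (1, 6),
    "sphericity": (1, 5),
    "margin": (1, 5),
    "lobulation": (1, 5),
    "spiculation": (1, 5),
    "texture": (1, 5),
}

DEFAULT_BOX_SHAPE = (32, 32, 16)


@dataclass
class NoduleRecord:
    """One annotated nodule: ordinal biomarkers, malignancy score, image box.

    ``volume`` and ``mask`` are (X, Y, Z) grids of identical shape;
    ``spacing_mm`` gives the physical voxel size along each axis.
    """

    patient_id: str
    subtlety: int
    int_structure: int
    calcification: int
    sphericity: int
    margin: int
    lobulation: int
    spiculation: int
    texture: int
    malignancy: int
    volume: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 1 <= int(self.malignancy) <= 5:
            raise ValueError(f"malignancy must be in 1..5, got {self.malignancy}")
        for name in BIOMARKER_NAMES:
            lo, hi = BIOMARKER_RANGES[name]
            val = int(getattr(self, name))
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside ordinal range [{lo},{hi}]")
        self.volume = np.asarray(self.volume, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.volume.shape != self.mask.shape:
            raise ValueError(
                f"volume shape {self.volume.shape} != mask shape {self.mask.shape}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def biomarkers(self) -> np.ndarray:
        """The 8 ordinal biomarker scores as a float vector (canonical order)."""
        return np.array([float(getattr(self, n)) for n in BIOMARKER_NAMES])


def biomarker_matrix(records: Sequence[NoduleRecord]) -> np.ndarray:
    """Stack biomarker vectors into an (n, 8) matrix."""
    return np.array([r.biomarkers for r in records], dtype=float)


def malignancy_scores(records: Sequence[NoduleRecord]) -> np.ndarray:
    return np.array([r.malignancy for r in records], dtype=int)


@dataclass
class LabeledDataset:
    """Nodules with binary labels and pseudo-label provenance.

    ``distribution_kind`` is "A" (fully supervised, no R3) or "B"
    (semi-supervised, train-side R3 pseudo-labeled).
    """

    records: list[NoduleRecord]
    labels: np.ndarray
    provenance: np.ndarray  # per-record: "original" or "pseudo"
    distribution_kind: str = "A"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = len(self.records)
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValueError("labels/provenance length must match records")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if self.distribution_kind not in ("A", "B"):
            raise ValueError("distribution_kind must be 'A' or 'B'")
        if self.distribution_kind == "A":
            if any(r.malignancy == 3 for r in self.records):
                raise ValueError("distribution A may not contain malignancy-3 records")
            if (self.provenance == "pseudo").any():
                raise ValueError("pseudo provenance only allowed in distribution B")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            [self.records[i] for i in idx],
            self.labels[idx],
            self.provenance[idx],
            self.distribution_kind,
        )


@dataclass
class SplitPair:
    """A disjoint train/test pair; test sets never contain R3 records."""

    train: LabeledDataset
    test: LabeledDataset
    ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        train_ids = {id(r) for r in self.train.records}
        if any(id(r) in train_ids for r in self.test.records):
            raise ValueError("train and test sets overlap")
        if any(r.malignancy == 3 for r in self.test.records):
            raise ValueError("test set contains malignancy-3 records")


def build_distribution_A(records: Iterable[NoduleRecord]) -> LabeledDataset:
    """Binary dataset dropping intermediate nodules: R12 -> 0, R45 -> 1."""
    kept: list[NoduleRecord] = []
    labels: list[int] = []
    for rec in records:
        if rec.malignancy == 3:
            continue
        kept.append(rec)
        labels.append(0 if rec.malignancy <= 2 else 1)
    if not kept:
        raise EmptyDatasetError("no records left after excluding malignancy-3 nodules")
    return LabeledDataset(
        kept, np.array(labels), np.array(["original"] * len(kept), dtype=object), "A"
    )


def split_indices(
    n: int,
    ratio: float,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
    groups: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test index split.

    Unstratified uniform by default.  ``labels`` switches to per-class
    (stratified) splitting; ``groups`` keeps all records of one group
    (e.g. patient) on the same side.
    """
    if not 0.0 < ratio < 1.0:
        raise SplitError(f"ratio must be in (0,1), got {ratio}")
    if n < 5:
        raise SplitError(f"cannot split {n} < 5 records")
    if groups is not None:
        uniq = np.array(sorted(set(groups)))
        perm = rng.permutation(len(uniq))
        n_train_g = int(round(ratio * len(uniq)))
        train_groups = set(uniq[perm[:n_train_g]])
        is_train = np.array([g in train_groups for g in groups])
        return np.where(is_train)[0], np.where(~is_train)[0]
    if labels is not None:
        labels = np.asarray(labels)
        train_parts, test_parts = [], []
        for cls in np.unique(labels):
            cls_idx = np.where(labels == cls)[0]
            perm = rng.permutation(len(cls_idx))
            n_train_c = int(round(ratio * len(cls_idx)))
            train_parts.append(cls_idx[perm[:n_train_c]])
            test_parts.append(cls_idx[perm[n_train_c:]])
        return np.concatenate(train_parts), np.concatenate(test_parts)
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    return perm[:n_train], perm[n_train:]


def split(
    dataset: LabeledDataset,
    ratio: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
    group_by_patient: bool = False,
) -> SplitPair:
    """Seeded 80:20-style split of a labeled dataset into a SplitPair."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = split_indices(
        len(dataset),
        ratio,
        rng,
        labels=dataset.labels if stratify else None,
        groups=[r.patient_id for r in dataset.records] if group_by_patient else None,
    )
    return SplitPair(dataset.subset(train_idx), dataset.subset(test_idx), ratio, seed)


# ---------------------------------------------------------------------------
# Tabular / array-container I/O
# ---------------------------------------------------------------------------

def save_cohort(records: Sequence[NoduleRecord], out_dir: str) -> None:
    """Persist a cohort: CSV of annotations + one array container of grids."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id}
        row.update({n: int(getattr(rec, n)) for n in BIOMARKER_NAMES})
        row["malignancy"] = int(rec.malignancy)
        row["spacing_x"], row["spacing_y"], row["spacing_z"] = rec.spacing_mm
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
    volumes = np.stack([r.volume for r in records]) if records else np.zeros((0,))
    masks = np.stack([r.mask for r in records]) if records else np.zeros((0,))
    np.savez_compressed(
        os.path.join(out_dir, "grids.npz"), volumes=volumes, masks=masks
    )


def load_cohort(in_dir: str) -> list[NoduleRecord]:
    """Load a cohort written by :func:`save_cohort` (row order preserved)."""
    table = pd.read_csv(os.path.join(in_dir, "cohort.csv"))
    grids = np.load(os.path.join(in_dir, "grids.npz"))
    volumes, masks = grids["volumes"], grids["masks"]
    records = []
    for i, row in table.iterrows():
        records.append(
            NoduleRecord(
                patient_id=str(row["patient_id"]),
                **{n: int(row[n]) for n in BIOMARKER_NAMES},
                malignancy=int(row["malignancy"]),
                volume=volumes[i],
                mask=masks[i],
                spacing_mm=(
                    float(row["spacing_x"]),
                    float(row["spacing_y"]),
                    float(row["spacing_z"]),
                ),
            )
        )
    return records
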