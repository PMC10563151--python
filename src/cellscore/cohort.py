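"""Event matrices, labeled samples and cohorts.

A sample is one cytometry acquisition: an n_i x D event matrix (one row per
cell, one column per panel channel) plus sample-level targets — a binary
diagnosis label and/or a real-valued burden in [0, 1], the fraction of the
sample's cells that are pathogenic.  Cell-level labels are never part of a
cohort; they exist only as simulation ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .panel import MarkerPanel


@dataclass
class EventMatrix:
    """One sample's n_i x D matrix of per-cell measurements."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"event matrix for {self.sample_id!r} must be 2-D")
        if self.values.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id!r} has no events")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"sample {self.sample_id!r} contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleRecord:
    """Event matrix plus sample-level targets.

    At least one of `label` (binary diagnosis) and `burden` (pathogenic cell
    fraction in [0, 1]) must be present.  When both are present they must be
    consistent: burden > 0 iff label = 1.
    """

    events: EventMatrix
    label: Optional[int] = None
    burden: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label is None and self.burden is None:
            raise ValueError(f"sample {self.sample_id!r} needs a label or a burden")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label for {self.sample_id!r} must be 0 or 1, got {self.label}")
        if self.burden is not None:
            if not (0.0 <= self.burden <= 1.0):
                raise ValueError(f"burden for {self.sample_id!r} must be in [0, 1], got {self.burden}")
            if self.label is not None and (self.burden > 0) != (self.label == 1):
                raise ValueError(
                    f"sample {self.sample_id!r}: burden {self.burden} inconsistent with label {self.label}"
                )

    @property
    def sample_id(self) -> str:
        return self.events.sample_id

    @property
    def effective_label(self) -> int:
        """Diagnosis label, derived from burden when only burden is given."""
        if self.label is not None:
            return int(self.label)
        return int(self.burden > 0)  # type: ignore[operator]


@dataclass
class Cohort:
    """Samples sharing one marker panel, with optional split assignment."""

    panel: MarkerPanel
    samples: List[SampleRecord]
    split_assignment: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in cohort: {dupes}")
        for s in self.samples:
            if s.events.n_channels != self.panel.size:
                raise ValueError(
                    f"sample {s.sample_id!r} has {s.events.n_channels} channels, "
                    f"panel has {self.panel.size}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample {sample_id!r} in cohort")

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.effective_label for s in self.samples], dtype=int)

    def positives(self) -> List[SampleRecord]:
        return [s for s in self.samples if s.effective_label == 1]

    def negatives(self) -> List[SampleRecord]:
        return [s for s in self.samples if s.effective_label == 0]

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        wanted = list(sample_ids)
        by_id = {s.sample_id: s for s in self.samples}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"sample ids not in cohort: {missing}")
        return Cohort(
            panel=self.panel,
            samples=[by_id[i] for i in wanted],
            split_assignment={i: self.split_assignment[i] for i in wanted if i in self.split_assignment},
        )

    def split(self, name: object) -> "Cohort":
        ids = [i for i, v in self.split_assignment.items() if v == name]
        if not ids:
            raise KeyError(f"no samples assigned to split {name!r}")
        return self.subset(ids)

    def with_panel(self, panel: MarkerPanel) -> "Cohort":
        return Cohort(panel=panel, samples=self.samples, split_assignment=dict(self.split_assignment))

    def transformed(self, panel: Optional[MarkerPanel] = None) -> "Cohort":
        """Apply the panel's per-channel transforms to every sample."""
        panel = panel or self.panel
        new_samples = [
            replace(s, events=EventMatrix(s.sample_id, panel.transform_matrix(s.events.values)))
            for s in self.samples
        ]
        return Cohort(panel=panel, samples=new_samples, split_assignment=dict(self.split_assignment))


def apply_transform(events: EventMatrix, panel: MarkerPanel) -> EventMatrix:
    """Apply the panel's per-channel transforms to one event matrix."""
    return EventMatrix(events.sample_id, panel.transform_matrix(events.values))


def make_splits(cohort: Cohort, n_folds: int, seed: int) -> Cohort:
    """Assign each sample to one of `n_folds` class-stratified folds.

    Deterministic given `seed`; per-fold class proportions are within one
    sample of the cohort proportions (property of stratified K-fold).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = cohort.labels
    for cls in (0, 1):
        n_cls = int(np.sum(labels == cls))
        if n_cls == 0:
            raise ValueError(f"cohort has no samples of class {cls}")
        if n_cls < n_folds:
            raise ValueError(
                f"class {cls} has {n_cls} samples, fewer than {n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: Dict[str, object] = {}
    ids = cohort.sample_ids
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in val_idx:
            assignment[ids[i]] = fold
    return Cohort(panel=cohort.panel, samples=cohort.samples, split_assignment=assignment)


def train_val_split(cohort: Cohort, val_fraction: float, seed: int) -> Tuple[Cohort, Cohort]:
    """Stratified train/validation split by sample."""
    labels = cohort.labels
    rng = np.random.default_rng(seed)
    train_ids: List[str] = []
    val_ids: List[str] = []
    ids = np.array(cohort.sample_ids)
    for cls in (0, 1):
        cls_ids = ids[labels == cls]
        if len(cls_ids) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot split")
        perm = rng.permutation(len(cls_ids))
        n_val = max(1, int(round(val_fraction * len(cls_ids))))
        val_ids.extend(cls_ids[perm[:n_val]])
        train_ids.extend(cls_ids[perm[n_val:]])
    order = {sid: k for k, sid in enumerate(cohort.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    val_ids.sort(key=order.__getitem__)
    return cohort.subset(train_ids), cohort.subset(val_ids)
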