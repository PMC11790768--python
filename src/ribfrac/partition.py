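"""Leakage-safe grouped partitioning of patch samples.

All representations of one fracture carry the same group id; a split that
separated them would leak near-duplicate views of the test fractures into
training. Every partition operation here therefore assigns whole groups, and
stratifies the assignment by terminal class so that small runs keep every
class on both sides of each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, StratificationError
from .mining import PatchSample


@dataclass
class GroupedDataset:
    """Patch samples plus the group structure used for all partitioning."""

    samples: list[PatchSample]
    groups: dict[str, list[int]]

    @classmethod
    def from_samples(cls, samples: list[PatchSample]) -> "GroupedDataset":
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            groups.setdefault(s.group_id, []).append(i)
        return cls(samples=list(samples), groups=groups)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_ids(self) -> set[str]:
        return set(self.groups)

    def group_label(self, group_id: str) -> str:
        return self.samples[self.groups[group_id][0]].label

    def subset(self, group_ids: list[str]) -> "GroupedDataset":
        """New dataset holding exactly the given groups (sample order kept)."""
        keep = sorted(i for g in group_ids for i in self.groups[g])
        return GroupedDataset.from_samples([self.samples[i] for i in keep])


def _groups_by_class(ds: GroupedDataset) -> dict[str, list[tuple[str, int]]]:
    """label -> [(group_id, group size)], deterministic order."""
    by_class: dict[str, list[tuple[str, int]]] = {}
    for gid in sorted(ds.groups):
        by_class.setdefault(ds.group_label(gid), []).append((gid, len(ds.groups[gid])))
    return by_class


def group_split(
    ds: GroupedDataset,
    test_fraction: float = 0.30,
    seed: int = 0,
    tolerance: float | None = 0.03,
) -> tuple[GroupedDataset, GroupedDataset]:
    """Split into train/test with whole groups, stratified by class.

    Within each class, groups are shuffled and assigned to the test side
    while that brings the class's test sample count closer to
    ``test_fraction`` of the class total; each class ends up with at least
    one group on each side. The realized overall test fraction must land
    within ``tolerance`` of the target (set ``tolerance=None`` to skip the
    check, e.g. for deliberately tiny fixtures).
    """
    if not 0.0 < test_fraction < 1.0:
        raise DataError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    test_groups: list[str] = []
    train_groups: list[str] = []
    for label, groups in _groups_by_class(ds).items():
        if len(groups) < 2:
            raise StratificationError(
                f"class {label!r} has {len(groups)} group(s); cannot appear on both sides"
            )
        order = rng.permutation(len(groups))
        shuffled = [groups[i] for i in order]
        class_total = sum(size for _, size in groups)
        target = test_fraction * class_total
        picked: list[str] = []
        current = 0
        for gid, size in shuffled:
            if abs(current + size - target) < abs(current - target):
                picked.append(gid)
                current += size
        if not picked:
            picked = [shuffled[0][0]]
        if len(picked) == len(groups):
            picked = picked[:-1]
        chosen = set(picked)
        test_groups.extend(picked)
        train_groups.extend(gid for gid, _ in shuffled if gid not in chosen)

    test = ds.subset(test_groups)
    train = ds.subset(train_groups)
    realized = len(test) / len(ds)
    if tolerance is not None and abs(realized - test_fraction) > tolerance:
        raise StratificationError(
            f"realized test fraction {realized:.3f} outside "
            f"{test_fraction}+/-{tolerance}; groups too coarse for this target"
        )
    return train, test


def kfold_groups(
    train: GroupedDataset, k: int = 5, seed: int = 0
) -> list[tuple[GroupedDataset, GroupedDataset]]:
    """Stratified grouped k-fold: ``k`` (fit, validation) pairs.

    Groups of each class are shuffled and dealt round-robin to the folds, so
    per-class group counts per fold differ by at most one. Every fold is the
    validation set exactly once; group integrity holds within every pair.
    """
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")
    if train.n_groups < k:
        raise DataError(f"{train.n_groups} groups cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for _, groups in _groups_by_class(train).items():
        order = rng.permutation(len(groups))
        for pos, i in enumerate(order):
            folds[(pos + offset) % k].append(groups[i][0])
        offset += len(groups) % k  # rotate start so small classes spread out
    pairs = []
    for f in range(k):
        val_ids = folds[f]
        fit_ids = [g for other in range(k) if other != f for g in folds[other]]
        pairs.append((train.subset(fit_ids), train.subset(val_ids)))
    return pairs


def check_no_leakage(*datasets: GroupedDataset) -> None:
    """Raise if any group id appears in more than one of the datasets."""
    seen: set[str] = set()
    for ds in datasets:
        ids = ds.group_ids
        overlap = seen & ids
        if overlap:
            raise DataError(f"group leakage across partitions: {sorted(overlap)[:5]} ...")
        seen |= ids


def split_manifest(
    assignments: dict[str, tuple[str, int | None]], path: str | Path
) -> pd.DataFrame:
    """Write the split manifest CSV (group_id, partition, fold) for reruns."""
    df = pd.DataFrame(
        [
            {"group_id": g, "partition": part, "fold": "" if fold is None else fold}
            for g, (part, fold) in sorted(assignments.items())
        ],
        columns=["group_id", "partition", "fold"],
    )
    df.to_csv(path, index=False)
    return df
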