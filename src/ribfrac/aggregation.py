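"""Lesion-level aggregation of patch predictions.

A fracture is seen by the classifier through up to 17 shifted patch
representations. Two rules collapse those into one diagnosis per fracture:

* the presence indicator ``Y`` over the predicted labels
  (``y_hat_1 .. y_hat_n``):

      Y = 0  if  sum_i y_hat_i = 0      (every representation said class 0)
      Y = 1  otherwise                  (any representation saw a fracture)

  so a fracture is detected even on the weakest signal — a single nonzero
  vote among the representations suffices;

* when ``Y = 1``, the fracture type ``k`` maximizes the per-class mean of
  the pre-softmax scores over the representations:

      k = argmax_c (1/n) * sum_i logit_i_c

  taken over the fracture classes only (class 0 is excluded: returning it
  would contradict ``Y = 1``). Ties break toward the lowest class index.

Negatives are singleton groups, so aggregation is the identity for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .classifier import LogitRecord


@dataclass
class LogitGroup:
    """All representations of one aggregation group.

    ``labels[i]`` is the argmax of row ``i`` of ``score_matrix`` (the
    classifier's per-patch decision); the matrix holds the pre-softmax
    scores ``logit_i_c``.
    """

    group_id: str
    labels: np.ndarray  # shape (n,), integer predicted labels
    score_matrix: np.ndarray  # shape (n, c_max)
    true_label: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.score_matrix = np.asarray(self.score_matrix, dtype=np.float64)
        if self.labels.ndim != 1 or self.score_matrix.ndim != 2:
            raise DataError("labels must be 1-D and score_matrix 2-D")
        if len(self.labels) != len(self.score_matrix):
            raise DataError("labels and score_matrix disagree on n")
        if len(self.labels) < 1:
            raise DataError("a group needs at least one representation")
        if not np.array_equal(self.labels, self.score_matrix.argmax(axis=1)):
            raise DataError("labels must equal the row-wise argmax of score_matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def c_max(self) -> int:
        return self.score_matrix.shape[1]


@dataclass
class AggregatedPrediction:
    """One diagnosis per group: the gate Y and the final class."""

    group_id: str
    Y: int
    final_label: int
    mean_scores: np.ndarray
    true_label: int

    def __post_init__(self) -> None:
        if (self.Y == 0) != (self.final_label == 0):
            raise DataError("Y = 0 exactly when final_label = 0")


def indicator_Y(labels) -> int:
    """Fracture-presence gate: 0 iff every predicted label is class 0."""
    arr = np.asarray(labels, dtype=np.int64)
    if arr.size == 0:
        raise DataError("indicator_Y needs at least one predicted label")
    if (arr < 0).any():
        raise DataError("predicted labels must be >= 0")
    return 0 if arr.sum() == 0 else 1


def select_class_k(score_matrix) -> int:
    """Mean-logit class choice over the fracture classes (class 0 excluded)."""
    m = np.asarray(score_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 2:
        raise DataError("score_matrix must be (n >= 1) x (c_max >= 2)")
    means = m.mean(axis=0)
    return int(np.argmax(means[1:])) + 1


def aggregate_group(g: LogitGroup) -> AggregatedPrediction:
    """Apply the Y gate, then the mean-logit type choice when a fracture
    was detected."""
    y = indicator_Y(g.labels)
    final = 0 if y == 0 else select_class_k(g.score_matrix)
    return AggregatedPrediction(
        group_id=g.group_id,
        Y=y,
        final_label=final,
        mean_scores=g.score_matrix.mean(axis=0),
        true_label=g.true_label,
    )


def groups_from_records(records: list[LogitRecord]) -> list[LogitGroup]:
    """Assemble LogitGroups from per-patch records (order-stable by first
    appearance of each group id)."""
    if not records:
        raise DataError("no records to group")
    order: list[str] = []
    by_group: dict[str, list[LogitRecord]] = {}
    for r in records:
        gid = r.sample.group_id
        if gid not in by_group:
            by_group[gid] = []
            order.append(gid)
        by_group[gid].append(r)
    groups = []
    for gid in order:
        rs = by_group[gid]
        truths = {r.true_label for r in rs}
        if len(truths) != 1:
            raise DataError(f"group {gid!r} mixes true labels {sorted(truths)}")
        groups.append(
            LogitGroup(
                group_id=gid,
                labels=np.array([r.predicted_label for r in rs]),
                score_matrix=np.stack([r.scores for r in rs]),
                true_label=truths.pop(),
            )
        )
    return groups
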