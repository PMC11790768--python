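"""Hierarchical three-level scoring of patch- and lesion-level predictions.

Three taxonomy levels, each restricted to the items whose *true* terminal
label is in scope:

* high — every item; binary fracture vs no-fracture (balanced by
  construction, reported with accuracy);
* mid  — true fractures only; nondisplaced vs displaced (imbalanced,
  reported with macro F1/precision/recall);
* low  — true displaced fractures only; the three displaced subtypes.

A prediction can fall outside a level's classes (e.g. a true displaced
fracture predicted ``no_fracture`` at mid level). Such predictions are kept
in an explicit ``out_of_level`` confusion column: they count against the
recall of the true class but against no in-level class's precision.
Dropping them would silently inflate every score.

Two assessments share this machinery: "standard" scores every patch as an
independent item; "aggregated" scores one item per group (the fracture- or
negative-level diagnosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DataError
from .labels import CLASSES, label_index
from .aggregation import AggregatedPrediction
from .classifier import LogitRecord

OUT_OF_LEVEL = "out_of_level"


@dataclass(frozen=True)
class TaxonomyLevel:
    """One level of the hierarchy: scope predicate plus terminal->level map.

    ``class_map`` sends a terminal label index to the level's class index,
    or ``None`` for predictions outside the level.
    """

    name: str
    class_names: tuple[str, ...]
    class_map: Callable[[int], int | None]
    in_scope: Callable[[int], bool]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


_NONDISPLACED = label_index("nondisplaced")

HIGH_LEVEL = TaxonomyLevel(
    name="high",
    class_names=("no_fracture", "fracture"),
    class_map=lambda t: 0 if t == 0 else 1,
    in_scope=lambda t: True,
)

MID_LEVEL = TaxonomyLevel(
    name="mid",
    class_names=("nondisplaced", "displaced"),
    class_map=lambda t: None if t == 0 else (0 if t == _NONDISPLACED else 1),
    in_scope=lambda t: t != 0,
)

LOW_LEVEL = TaxonomyLevel(
    name="low",
    class_names=("ad_latus", "cum_contractione", "cum_distractione"),
    class_map=lambda t: t - 2 if t >= 2 else None,
    in_scope=lambda t: t >= 2,
)

ALL_LEVELS = (HIGH_LEVEL, MID_LEVEL, LOW_LEVEL)


@dataclass
class MetricsReport:
    """Scores and confusion matrices for one (level, assessment) pair.

    ``confusion_abs`` rows are the level's true classes; columns are the
    level's predicted classes plus, when the level does not cover all
    terminal labels, a trailing ``out_of_level`` column. ``confusion_rel``
    is row-normalized (rows with zero support stay all-zero and are listed
    in ``zero_support``).
    """

    level: str
    assessment: str
    n_items: int
    row_names: tuple[str, ...]
    col_names: tuple[str, ...]
    confusion_abs: np.ndarray
    confusion_rel: np.ndarray
    accuracy: float | None = None
    macro_f1: float | None = None
    macro_precision: float | None = None
    macro_recall: float | None = None
    per_class: dict = field(default_factory=dict)
    zero_support: list[str] = field(default_factory=list)
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "assessment": self.assessment,
            "n_items": self.n_items,
            "row_names": list(self.row_names),
            "col_names": list(self.col_names),
            "confusion_abs": self.confusion_abs.tolist(),
            "confusion_rel": self.confusion_rel.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "per_class": self.per_class,
            "zero_support": self.zero_support,
            "empty": self.empty,
        }


def score_level(
    truths: Sequence[int],
    preds: Sequence[int],
    level: TaxonomyLevel,
    assessment: str = "standard",
) -> MetricsReport:
    """Score terminal-label predictions at one taxonomy level.

    Items are restricted to those whose true label is in the level's scope;
    truths and predictions are then mapped through the level's class map.
    """
    t = np.asarray(truths, dtype=np.int64)
    p = np.asarray(preds, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise DataError("truths and preds must be aligned 1-D sequences")

    scope = np.array([level.in_scope(v) for v in t], dtype=bool)
    t, p = t[scope], p[scope]
    nc = level.n_classes
    has_out = any(level.class_map(i) is None for i in range(len(CLASSES)))
    ncol = nc + (1 if has_out else 0)
    col_names = level.class_names + ((OUT_OF_LEVEL,) if has_out else ())

    conf = np.zeros((nc, ncol), dtype=np.int64)
    if t.size == 0:
        return MetricsReport(
            level=level.name,
            assessment=assessment,
            n_items=0,
            row_names=level.class_names,
            col_names=col_names,
            confusion_abs=conf,
            confusion_rel=conf.astype(float),
            zero_support=list(level.class_names),
            empty=True,
        )

    for ti, pi in zip(t, p):
        row = level.class_map(int(ti))
        mapped = level.class_map(int(pi))
        col = nc if mapped is None else mapped
        conf[row, col] += 1

    row_sums = conf.sum(axis=1)
    col_sums = conf.sum(axis=0)
    diag = np.array([conf[i, i] for i in range(nc)], dtype=np.float64)

    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row_sums > 0, diag / row_sums, 0.0)
        precision = np.where(col_sums[:nc] > 0, diag / col_sums[:nc], 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
        rel = np.where(row_sums[:, None] > 0, conf / row_sums[:, None], 0.0)

    per_class = {
        name: {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f1": float(f1[i]),
            "support": int(row_sums[i]),
        }
        for i, name in enumerate(level.class_names)
    }
    return MetricsReport(
        level=level.name,
        assessment=assessment,
        n_items=int(t.size),
        row_names=level.class_names,
        col_names=col_names,
        confusion_abs=conf,
        confusion_rel=rel,
        accuracy=float(diag.sum() / t.size),
        macro_f1=float(f1.mean()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        per_class=per_class,
        zero_support=[n for i, n in enumerate(level.class_names) if row_sums[i] == 0],
    )


def assess_standard(
    records: Sequence[LogitRecord], level: TaxonomyLevel
) -> MetricsReport:
    """Score every patch as an independent item."""
    if not records:
        raise DataError("no records to assess")
    return score_level(
        [r.true_label for r in records],
        [r.predicted_label for r in records],
        level,
        assessment="standard",
    )


def assess_aggregated(
    groups: Sequence[AggregatedPrediction], level: TaxonomyLevel
) -> MetricsReport:
    """Score one item per aggregation group (lesion-level diagnosis)."""
    if not groups:
        raise DataError("no aggregated predictions to assess")
    return score_level(
        [g.true_label for g in groups],
        [g.final_label for g in groups],
        level,
        assessment="aggregated",
    )


def summary_table(reports: Sequence[MetricsReport]) -> str:
    """Plain-text overview: one row per (level, assessment)."""
    lines = [
        f"{'level':<6} {'assessment':<11} {'n':>6} {'accuracy':>9} "
        f"{'F1':>7} {'precision':>10} {'recall':>7}"
    ]
    for r in reports:
        fmt = lambda v: "    -" if v is None else f"{v:.3f}"
        lines.append(
            f"{r.level:<6} {r.assessment:<11} {r.n_items:>6} {fmt(r.accuracy):>9} "
            f"{fmt(r.macro_f1):>7} {fmt(r.macro_precision):>10} {fmt(r.macro_recall):>7}"
        )
    return "\n".join(lines)
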