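"""Scoring of ontology-class predictions.

Two prediction regimes are scored:

* single-label — classical classifiers emit exactly one class per
  molecule; per-class confusion counts give precision, recall and F1,
  with a macro average across classes;
* multi-label — the recurrent network emits a (possibly empty) class
  set per molecule; besides per-class scores this yields a per-molecule
  F1 distribution and the set of *abstentions*, molecules for which no
  class score cleared the threshold.

Because a near-miss prediction (a sibling or grandparent of the true
class) is more useful than one in a distant branch, predictions are
additionally compared by ontology distance: for every molecule, every
(asserted parent, predicted parent) pair contributes the number of
subsumption edges between the two classes, 0 denoting an exact match.
Prediction sets are condensed first so redundant superclasses do not
dilute the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

from .ontology import OntologyGraph

__all__ = [
    "ConfusionCounts",
    "ClassReport",
    "precision",
    "recall",
    "f1",
    "SingleLabelReport",
    "score_single_label",
    "MultiLabelReport",
    "score_multi_label",
    "PathLengthReport",
    "path_length_report",
    "mean_parent_count",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 by convention when no positive predictions."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 by convention when no positive instances."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    p, r = precision(counts), recall(counts)
    return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class ClassReport:
    """Confusion counts and derived metrics for one class.

    ``zero_division`` names the metrics whose denominator was zero and
    were set to 0 by convention.
    """

    class_id: str
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    zero_division: tuple[str, ...] = ()


def _class_report(class_id: str, counts: ConfusionCounts) -> ClassReport:
    flags = []
    if counts.tp + counts.fp == 0:
        flags.append("precision")
    if counts.tp + counts.fn == 0:
        flags.append("recall")
    if f1(counts) == 0.0 and (precision(counts) + recall(counts)) == 0.0:
        flags.append("f1")
    return ClassReport(
        class_id=class_id,
        counts=counts,
        precision=precision(counts),
        recall=recall(counts),
        f1=f1(counts),
        zero_division=tuple(flags),
    )


@dataclass
class SingleLabelReport:
    per_class: list[ClassReport]
    macro_precision: float
    macro_recall: float
    macro_f1: float


def _check_keys(predictions: dict, truth: dict) -> None:
    extra = set(predictions) - set(truth)
    missing = set(truth) - set(predictions)
    if extra or missing:
        raise ValueError(
            f"prediction/truth member mismatch: {len(extra)} unknown to "
            f"truth, {len(missing)} missing from predictions"
        )


def score_single_label(
    predictions: dict[str, str],
    truth: dict[str, str],
    classes: list[str],
) -> SingleLabelReport:
    """Per-class confusion scoring of one-label-per-molecule predictions.

    For a class c: tp = members of c predicted c, fp = members of other
    classes predicted c, fn = members of c predicted otherwise.
    """
    _check_keys(predictions, truth)
    reports = []
    for c in classes:
        tp = sum(1 for m, t in truth.items() if t == c and predictions[m] == c)
        fp = sum(1 for m, t in truth.items() if t != c and predictions[m] == c)
        fn = sum(1 for m, t in truth.items() if t == c and predictions[m] != c)
        reports.append(_class_report(c, ConfusionCounts(tp, fp, fn)))
    return SingleLabelReport(
        per_class=reports,
        macro_precision=fmean(r.precision for r in reports) if reports else 0.0,
        macro_recall=fmean(r.recall for r in reports) if reports else 0.0,
        macro_f1=fmean(r.f1 for r in reports) if reports else 0.0,
    )


@dataclass
class MultiLabelReport:
    per_class: list[ClassReport]
    macro_f1: float
    per_molecule_f1: dict[str, float]
    abstentions: set[str]


def score_multi_label(
    predictions: dict[str, set[str]],
    truth: dict[str, set[str]],
    classes: list[str],
) -> MultiLabelReport:
    """Set-valued scoring with per-molecule F1 and abstention reporting.

    A molecule's F1 compares its predicted set against its truth set;
    an empty predicted set is an abstention (F1 = 0 when the truth set
    is non-empty).
    """
    _check_keys(predictions, truth)
    reports = []
    for c in classes:
        tp = sum(1 for m in truth if c in truth[m] and c in predictions[m])
        fp = sum(1 for m in truth if c not in truth[m] and c in predictions[m])
        fn = sum(1 for m in truth if c in truth[m] and c not in predictions[m])
        reports.append(_class_report(c, ConfusionCounts(tp, fp, fn)))
    per_molecule: dict[str, float] = {}
    abstentions: set[str] = set()
    for m in truth:
        pred, true = predictions[m], truth[m]
        if not pred:
            abstentions.add(m)
        tp = len(pred & true)
        per_molecule[m] = f1(
            ConfusionCounts(tp=tp, fp=len(pred - true), fn=len(true - pred))
        )
    return MultiLabelReport(
        per_class=reports,
        macro_f1=fmean(r.f1 for r in reports) if reports else 0.0,
        per_molecule_f1=per_molecule,
        abstentions=abstentions,
    )


@dataclass
class PathLengthReport:
    """Ontology distances between predicted and asserted parent classes.

    ``pairwise`` holds, per molecule, one length for every (asserted,
    predicted) pair that is connected in the subsumption graph;
    ``n_no_path`` counts disconnected pairs, which are excluded from
    the mean.  The overall mean weights each pair equally.
    """

    pairwise: dict[str, list[int]]
    per_molecule_min: dict[str, int]
    per_molecule_max: dict[str, int]
    mean: float
    n_no_path: int

    @property
    def max(self) -> int:
        return max((v for vs in self.pairwise.values() for v in vs), default=0)


def path_length_report(
    graph: OntologyGraph,
    asserted: dict[str, set[str]],
    predicted: dict[str, set[str]],
) -> PathLengthReport:
    """All-pairs subsumption distances between asserted and predicted parents.

    ``predicted`` sets are expected to be condensed already (no
    predicted class a superclass of another); an identical
    (asserted, predicted) pair contributes length 0.
    """
    _check_keys(predicted, asserted)
    pairwise: dict[str, list[int]] = {}
    per_min: dict[str, int] = {}
    per_max: dict[str, int] = {}
    n_no_path = 0
    all_lengths: list[int] = []
    for m in asserted:
        lengths = []
        for a in sorted(asserted[m]):
            for p in sorted(predicted[m]):
                d = graph.path_length(p, a)
                if d is None:
                    n_no_path += 1
                else:
                    lengths.append(d)
        pairwise[m] = lengths
        if lengths:
            per_min[m] = min(lengths)
            per_max[m] = max(lengths)
        all_lengths.extend(lengths)
    return PathLengthReport(
        pairwise=pairwise,
        per_molecule_min=per_min,
        per_molecule_max=per_max,
        mean=fmean(all_lengths) if all_lengths else 0.0,
        n_no_path=n_no_path,
    )


def mean_parent_count(
    predictions: dict[str, set[str]], graph: OntologyGraph
) -> float:
    """Average non-redundant predicted-parent count per molecule.

    Each prediction set is condensed first, so a class accompanied by
    one of its superclasses counts once.
    """
    if not predictions:
        return 0.0
    return fmean(len(graph.condense(s)) for s in predictions.values())
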