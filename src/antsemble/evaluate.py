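"""Top-t lists, performance metrics, and double-fault diversity measures.

A classifier's output for a sample is a score vector over the ``L`` genus
labels; evaluation turns it into a *top-t list* (the ``t`` highest-scoring
labels, most likely first) and counts a prediction correct when the true
label is anywhere in the list.  Three metrics summarise a batch of lists:
accuracy, the unweighted (macro) mean of per-label precision, and the minimum
per-label precision — the worst-case guarantee across genera.

Pairwise classifier diversity uses the double-fault family over per-sample
correctness indicators: both-correct ``bc``, both-fault ``df``, some-correct
``sc`` and only-one-correct ``oc``, with the exact identities
``sc = bc + oc`` and ``bc + oc + df = 1``.  Ensemble-level diversity is the
unweighted mean over all classifier pairs.
"""

from __future__ import annotations

import itertools
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TopTList",
    "top_t",
    "correctness",
    "accuracy_at",
    "label_precision",
    "MetricsRow",
    "MetricsReport",
    "metrics_report",
    "PairDiversity",
    "pairwise_diversity",
    "DiversityReport",
    "ensemble_diversity",
    "diversity_report",
]


@dataclass(frozen=True)
class TopTList:
    """The ``min(t, L)`` most likely labels for one sample, best first.

    Ties are broken toward the lower label index, so for fixed scores the
    top-t list is always a prefix of the top-(t+1) list.
    """

    t: int
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("top-t labels must be distinct")

    def __contains__(self, label: int) -> bool:
        return label in self.labels


def top_t(scores: np.ndarray, t: int) -> TopTList:
    """Rank labels by descending score; ties toward the lower label index.

    ``scores[i]`` is the score of label ``i+1``.  ``t`` larger than ``L``
    yields the full ranking.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    s = np.asarray(scores, dtype=np.float64)
    order = np.lexsort((np.arange(len(s)), -s))  # primary: -score, then index
    take = min(t, len(s))
    return TopTList(t, tuple(int(i) + 1 for i in order[:take]))


def correctness(lists: Sequence[TopTList], truths: Sequence[int]) -> np.ndarray:
    """Boolean per-sample vector: is the true label within the top-t list?"""
    if len(lists) != len(truths):
        raise ValueError("lists and truths must have equal length")
    return np.asarray([g in lst for lst, g in zip(lists, truths)], dtype=bool)


def accuracy_at(lists: Sequence[TopTList], truths: Sequence[int]) -> float:
    """Fraction of samples whose true label appears in their list."""
    if len(lists) == 0:
        raise ValueError("cannot compute accuracy of an empty evaluation")
    return float(correctness(lists, truths).mean())


def label_precision(lists: Sequence[TopTList], truths: Sequence[int],
                    label: int) -> float:
    """Precision of one label under list predictions.

    A label counts as *predicted* for a sample whenever it appears in the
    sample's top-t list; precision is true positives over predictions, with
    the 0/0 case defined as 0 (a never-predicted label scores zero rather
    than being excluded).
    """
    predicted = sum(1 for lst in lists if label in lst)
    if predicted == 0:
        return 0.0
    hits = sum(1 for lst, g in zip(lists, truths) if g == label and label in lst)
    return hits / predicted


MetricsRow = namedtuple("MetricsRow",
                        ["accuracy", "average_precision", "minimum_precision"])


@dataclass
class MetricsReport:
    """Accuracy / average precision / minimum precision per list size t."""

    per_t: dict[int, MetricsRow]
    per_label: dict[int, dict[int, float]]  # t -> {label: precision}
    name: str = ""

    def to_frame(self):
        import pandas as pd

        rows = {
            t: {"accuracy": m.accuracy,
                "average_precision": m.average_precision,
                "minimum_precision": m.minimum_precision}
            for t, m in sorted(self.per_t.items())
        }
        frame = pd.DataFrame(rows).T
        frame.index.name = "t"
        return frame

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "per_t": {str(t): m._asdict() for t, m in sorted(self.per_t.items())},
        }


def metrics_report(
    lists_per_t: Mapping[int, Sequence[TopTList]],
    truths: Sequence[int],
    name: str = "",
) -> MetricsReport:
    """Aggregate the three metrics over the labels present in ``truths``.

    Average precision is the unweighted mean of per-label precisions; the
    minimum is taken over the same label set.
    """
    if len(truths) == 0:
        raise ValueError("empty truth set")
    labels = sorted(set(int(g) for g in truths))
    per_t: dict[int, MetricsRow] = {}
    per_label: dict[int, dict[int, float]] = {}
    for t, lists in lists_per_t.items():
        precisions = {g: label_precision(lists, truths, g) for g in labels}
        per_label[t] = precisions
        values = list(precisions.values())
        per_t[t] = MetricsRow(
            accuracy=accuracy_at(lists, truths),
            average_precision=float(np.mean(values)),
            minimum_precision=float(np.min(values)),
        )
    return MetricsReport(per_t=per_t, per_label=per_label, name=name)


PairDiversity = namedtuple("PairDiversity", ["bc", "df", "sc", "oc"])


def pairwise_diversity(a: np.ndarray, b: np.ndarray) -> PairDiversity:
    """Double-fault diversity of two correctness vectors.

    ``bc``: both correct; ``df``: both fault; ``sc``: at least one correct;
    ``oc``: exactly one correct.  Exact identities: ``sc = bc + oc`` and
    ``bc + oc + df = 1``.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("correctness vectors must be equal-length, non-empty 1-D")
    return PairDiversity(
        bc=float((a & b).mean()),
        df=float((~a & ~b).mean()),
        sc=float((a | b).mean()),
        oc=float((a ^ b).mean()),
    )


@dataclass
class DiversityReport:
    """Pairwise diversity measures and their unweighted averages.

    ``pairs`` maps a member-name pair to its measures; ``average`` is the
    mean over all pairs.  When built for several list sizes, ``per_t`` holds
    one report per ``t``.
    """

    pairs: dict[tuple[str, str], PairDiversity] = field(default_factory=dict)
    average: PairDiversity | None = None
    per_t: dict[int, "DiversityReport"] = field(default_factory=dict)
    name: str = ""

    def to_frame(self):
        import pandas as pd

        source = self.per_t if self.per_t else {0: self}
        rows = []
        for t, rep in sorted(source.items()):
            for (na, nb), d in rep.pairs.items():
                rows.append({"t": t, "pair": f"{na}|{nb}", **d._asdict()})
            if rep.average is not None:
                rows.append({"t": t, "pair": "average", **rep.average._asdict()})
        return pd.DataFrame(rows)


def ensemble_diversity(
    members: Sequence[np.ndarray],
    names: Sequence[str] | None = None,
) -> DiversityReport:
    """All-pairs diversity of an ensemble's correctness vectors.

    Requires at least two members; the report's ``average`` is the unweighted
    mean of each measure over the ``C(m, 2)`` pairs.
    """
    if len(members) < 2:
        raise ValueError("an ensemble needs at least two members")
    if names is None:
        names = [f"member{i}" for i in range(len(members))]
    report = DiversityReport()
    acc = np.zeros(4)
    npairs = 0
    for i, j in itertools.combinations(range(len(members)), 2):
        d = pairwise_diversity(members[i], members[j])
        report.pairs[(names[i], names[j])] = d
        acc += np.asarray(d)
        npairs += 1
    report.average = PairDiversity(*(acc / npairs))
    return report


def diversity_report(
    members_by_t: Mapping[int, Sequence[np.ndarray]],
    names: Sequence[str] | None = None,
    name: str = "",
) -> DiversityReport:
    """Diversity at each list size ``t`` (Table-style shape)."""
    out = DiversityReport(name=name)
    for t, members in sorted(members_by_t.items()):
        out.per_t[t] = ensemble_diversity(members, names)
    return out
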