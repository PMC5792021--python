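"""Late-fusion ensembles over training regimes and views.

A specimen with exactly one picture per view is classified by letting each
ensemble member score its designated view's picture and summing the softmax
output vectors element-wise; the summed vector is then ranked into a top-t
list.  Four configurations are supported:

* ``G`` — the single general model applied to each of the three views;
* ``S`` — the three view-specific models;
* ``T`` — the three transfer models;
* ``All`` — all nine (regime, view) combinations.

Summation (rather than averaging) is used; both give identical rankings,
and sums keep the aggregated mass equal to the member count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import VIEWS, MultiViewDataset, SpecimenRecord, View
from .evaluate import MetricsReport, TopTList, metrics_report, top_t
from .training import TrainedModel, score_image

__all__ = [
    "ENSEMBLE_KINDS",
    "EnsembleMember",
    "Ensemble",
    "AggregatedScore",
    "MissingModelError",
    "build_ensemble",
    "aggregate_scores",
    "predict_specimen",
    "evaluate_ensemble",
    "evaluate_single_view",
    "specimen_correctness",
]

ENSEMBLE_KINDS = ("G", "S", "T", "All")

_KIND_REGIMES = {"G": ("general",), "S": ("specific",), "T": ("transfer",),
                 "All": ("general", "specific", "transfer")}


class MissingModelError(KeyError):
    """A required (regime, view) model is absent."""

    def __init__(self, regime: str, view: View | None):
        self.regime, self.view = regime, view
        v = view.value if view else "any view"
        super().__init__(f"missing trained model: regime={regime!r}, view={v}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return self.args[0]


@dataclass(frozen=True)
class EnsembleMember:
    """One member: a model applied to one view's picture of the specimen."""

    regime: str
    view: View
    model: TrainedModel


@dataclass
class Ensemble:
    kind: str
    members: list[EnsembleMember]

    @property
    def n_labels(self) -> int:
        return self.members[0].model.arch.n_labels


@dataclass
class AggregatedScore:
    """Element-wise sum of member score vectors; mass equals member_count."""

    total: np.ndarray
    member_count: int


def _index_models(models: Iterable[TrainedModel]) -> dict:
    index: dict[tuple[str, View | None], TrainedModel] = {}
    for m in models:
        index[(m.regime, m.view)] = m
    return index


def build_ensemble(kind: str, models: Iterable[TrainedModel]) -> Ensemble:
    """Resolve an ensemble configuration against the available models.

    ``G`` resolves all three members to the single general model (one weight
    set scored on each view's picture); ``S``/``T`` need one model per view;
    ``All`` is the union of the three.  Raises :class:`MissingModelError`
    naming the first absent (regime, view).
    """
    if kind not in ENSEMBLE_KINDS:
        raise ValueError(f"unknown ensemble kind {kind!r}; expected one of "
                         f"{ENSEMBLE_KINDS}")
    index = _index_models(models)
    members: list[EnsembleMember] = []
    for regime in _KIND_REGIMES[kind]:
        for view in VIEWS:
            if regime == "general":
                model = index.get(("general", None))
                if model is None:
                    raise MissingModelError("general", None)
            else:
                model = index.get((regime, view))
                if model is None:
                    raise MissingModelError(regime, view)
            members.append(EnsembleMember(regime, view, model))
    return Ensemble(kind, members)


def aggregate_scores(scores: Sequence[np.ndarray]) -> AggregatedScore:
    """Element-wise summation of member softmax vectors (no renormalization)."""
    if len(scores) < 1:
        raise ValueError("need at least one member score")
    lengths = {len(s) for s in scores}
    if len(lengths) != 1:
        raise ValueError(f"score vectors differ in length: {sorted(lengths)}")
    total = np.sum(np.stack([np.asarray(s, dtype=np.float64) for s in scores]),
                   axis=0)
    return AggregatedScore(total=total, member_count=len(scores))


def _one_picture(specimen: SpecimenRecord, view: View):
    pics = specimen.pictures(view)
    if len(pics) != 1:
        raise ValueError(
            f"specimen {specimen.specimen_id!r} has {len(pics)} pictures in the "
            f"{view.value} view; ensemble prediction requires exactly one"
        )
    return pics[0]


def predict_specimen(ensemble: Ensemble, specimen: SpecimenRecord,
                     t: int) -> TopTList:
    """Score each member on its view's picture, sum, and rank into a top-t list.

    The specimen must have exactly one picture per view; anything else is
    refused rather than silently resolved.
    """
    scores = [
        score_image(member.model, _one_picture(specimen, member.view))
        for member in ensemble.members
    ]
    return top_t(aggregate_scores(scores).total, t)


def evaluate_ensemble(
    ensemble: Ensemble,
    test: MultiViewDataset,
    ts: Sequence[int] = (1, 3, 5),
) -> MetricsReport:
    """Specimen-level metrics of an ensemble at each list size in ``ts``."""
    if len(test) == 0:
        raise ValueError("empty test set")
    aggregated: list[np.ndarray] = []
    truths: list[int] = []
    for specimen in test.specimens:
        scores = [
            score_image(member.model, _one_picture(specimen, member.view))
            for member in ensemble.members
        ]
        aggregated.append(aggregate_scores(scores).total)
        truths.append(specimen.genus)
    lists_per_t = {t: [top_t(s, t) for s in aggregated] for t in ts}
    return metrics_report(lists_per_t, truths, name=f"ensemble-{ensemble.kind}")


def evaluate_single_view(
    model: TrainedModel,
    ds: MultiViewDataset,
    view: View,
    ts: Sequence[int] = (1, 3, 5),
) -> MetricsReport:
    """Per-picture metrics of a single model on one view's pictures."""
    lists_per_t: dict[int, list[TopTList]] = {t: [] for t in ts}
    truths: list[int] = []
    for specimen in ds.specimens:
        for sample in specimen.pictures(view):
            scores = score_image(model, sample)
            for t in ts:
                lists_per_t[t].append(top_t(scores, t))
            truths.append(specimen.genus)
    if not truths:
        raise ValueError(f"dataset has no pictures in the {view.value} view")
    return metrics_report(lists_per_t, truths,
                          name=f"{model.regime}-{view.value}")


def specimen_correctness(
    members: Sequence[EnsembleMember],
    ds: MultiViewDataset,
    ts: Sequence[int] = (1, 3, 5),
) -> dict[int, list[np.ndarray]]:
    """Per-member specimen-level correctness vectors at each ``t``.

    The substrate for diversity analysis: member ``i``'s vector marks the
    specimens whose true genus is within that member's own top-t list.
    """
    truths = [s.genus for s in ds.specimens]
    out: dict[int, list[np.ndarray]] = {t: [] for t in ts}
    for member in members:
        scores = [
            score_image(member.model, _one_picture(s, member.view))
            for s in ds.specimens
        ]
        for t in ts:
            lists = [top_t(sc, t) for sc in scores]
            out[t].append(
                np.asarray([g in lst for lst, g in zip(lists, truths)],
                           dtype=bool)
            )
    return out
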