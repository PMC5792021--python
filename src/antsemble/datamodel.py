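"""Multi-view specimen dataset representation and manifest I/O.

A *specimen* is one physical individual photographed in up to three standard
views (head, dorsum, profile); the classification label is its genus, coded as
a contiguous integer in ``1..L``.  A dataset is a collection of specimens, each
holding a (possibly empty) list of grayscale pictures per view.

This module provides manifest reading/writing, minimum-support label
filtering, Table-style cardinality summaries, and the stratified
train/validation/test split in which validation and test are restricted to
specimens with exactly one picture per view.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "View",
    "VIEWS",
    "ImageSample",
    "SpecimenRecord",
    "MultiViewDataset",
    "DatasetSplit",
    "CardinalitySummary",
    "ManifestError",
    "EmptyDatasetError",
    "read_manifest",
    "write_manifest",
    "load_image",
    "to_square",
    "filter_labels_by_support",
    "cardinality_summary",
    "split_dataset",
    "flatten_to_samples",
    "largest_remainder_quotas",
]


class View(str, Enum):
    """One of the three standard photographic perspectives of a specimen.

    The canonical ordering (head < dorsum < profile) is used wherever views
    are enumerated, so every report and every flattened sample stream is
    deterministic.
    """

    HEAD = "head"
    DORSUM = "dorsum"
    PROFILE = "profile"

    @classmethod
    def parse(cls, token: str) -> "View":
        t = str(token).strip().lower()
        aliases = {
            "head": cls.HEAD, "h": cls.HEAD,
            "dorsum": cls.DORSUM, "dorsal": cls.DORSUM, "d": cls.DORSUM,
            "profile": cls.PROFILE, "lateral": cls.PROFILE, "p": cls.PROFILE,
        }
        if t not in aliases:
            raise ValueError(f"unknown view token {token!r} "
                             f"(expected one of head/dorsum/profile)")
        return aliases[t]

    @property
    def short(self) -> str:
        return {"head": "h", "dorsum": "d", "profile": "p"}[self.value]


#: Canonical view order used everywhere views are enumerated.
VIEWS: tuple[View, View, View] = (View.HEAD, View.DORSUM, View.PROFILE)


class ManifestError(ValueError):
    """A manifest row could not be interpreted; carries the row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"manifest row {row}: {message}")


class EmptyDatasetError(ValueError):
    """An operation produced or received a dataset with no specimens."""


@dataclass
class ImageSample:
    """A single grayscale picture of a specimen from one view.

    ``pixels`` is a 2-D float array with intensities in [0, 1].
    """

    specimen_id: str
    view: View
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"intensities must lie in [0,1], got [{lo}, {hi}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SpecimenRecord:
    """One specimen: its genus label and its pictures grouped by view."""

    specimen_id: str
    genus: int
    images_by_view: dict[View, list[ImageSample]] = field(default_factory=dict)

    def pictures(self, view: View) -> list[ImageSample]:
        return self.images_by_view.get(view, [])

    def n_pictures(self, view: View | None = None) -> int:
        if view is not None:
            return len(self.pictures(view))
        return sum(len(self.pictures(v)) for v in VIEWS)

    def has_exactly_one_per_view(self) -> bool:
        """True iff N_h = N_d = N_p = 1 (the validation/test contract)."""
        return all(len(self.pictures(v)) == 1 for v in VIEWS)

    def has_all_views(self) -> bool:
        return all(len(self.pictures(v)) >= 1 for v in VIEWS)


@dataclass
class MultiViewDataset:
    """A list of specimens with genus labels in ``1..n_labels``.

    ``label_names`` optionally maps the contiguous integer label back to the
    original genus name from the manifest.
    """

    specimens: list[SpecimenRecord]
    label_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen_ids must be unique")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.specimens)

    @property
    def n_labels(self) -> int:
        return len({s.genus for s in self.specimens})

    @property
    def labels(self) -> list[int]:
        return sorted({s.genus for s in self.specimens})

    def genus_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for s in self.specimens:
            counts[s.genus] = counts.get(s.genus, 0) + 1
        return counts

    def n_pictures(self) -> int:
        return sum(s.n_pictures() for s in self.specimens)

    def subset(self, specimen_ids: Iterable[str]) -> "MultiViewDataset":
        keep = set(specimen_ids)
        return MultiViewDataset(
            [s for s in self.specimens if s.specimen_id in keep],
            label_names=self.label_names,
        )


@dataclass
class DatasetSplit:
    """Train/validation/test partition of a dataset.

    Validation and test contain only specimens with exactly one picture per
    view; everything else (including specimens with extra pictures) stays in
    train, so the full picture base is available for weight fitting.
    """

    train: MultiViewDataset
    validation: MultiViewDataset
    test: MultiViewDataset
    seed: int
    fractions: tuple[float, float, float]

    @property
    def parts(self) -> tuple[MultiViewDataset, MultiViewDataset, MultiViewDataset]:
        return (self.train, self.validation, self.test)


@dataclass
class CardinalitySummary:
    """Per-constraint specimen counts and rates, one row per constraint."""

    rows: list[tuple[str, int, float]]
    total: int

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {d: {"count": c, "rate": r} for d, c, r in self.rows}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["constraint", "count", "rate"])


# ---------------------------------------------------------------------------
# image loading helpers


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a grayscale [0,1] float array.

    Color inputs are collapsed with luminance weights (0.299, 0.587, 0.114).
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    arr = arr.astype(np.float32)
    if arr.max(initial=0.0) > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def to_square(pixels: np.ndarray, size: int) -> np.ndarray:
    """Pad to square with zeros, then bilinear-resize to ``size`` x ``size``."""
    from PIL import Image

    h, w = pixels.shape
    if (h, w) == (size, size):
        return np.asarray(pixels, dtype=np.float32)
    side = max(h, w)
    padded = np.zeros((side, side), dtype=np.float32)
    top, left = (side - h) // 2, (side - w) // 2
    padded[top:top + h, left:left + w] = pixels
    im = Image.fromarray(padded, mode="F").resize((size, size), Image.BILINEAR)
    return np.clip(np.asarray(im, dtype=np.float32), 0.0, 1.0)


# ---------------------------------------------------------------------------
# manifest I/O


def _iter_manifest_rows(path: Path) -> Iterator[tuple[int, dict]]:
    if path.suffix.lower() in {".jsonl", ".json"}:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    yield i, json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ManifestError(i, f"invalid JSON: {exc}") from exc
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # row 1 is the header
                yield i, row


def read_manifest(path: str | Path) -> MultiViewDataset:
    """Read a dataset manifest (CSV or JSON-lines) and its images.

    Each row must provide ``specimen_id``, ``genus``, ``view`` (one of
    head/dorsum/profile) and ``path`` (image location, relative paths resolved
    against the manifest directory).  Genus values are mapped to contiguous
    integer labels ``1..L`` in sorted order of the original names; the mapping
    is kept in ``label_names``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")

    raw_rows: list[tuple[int, str, str, View, Path]] = []
    for rowno, row in _iter_manifest_rows(path):
        try:
            sid = str(row["specimen_id"])
            genus = str(row["genus"])
            view = View.parse(row["view"])
            img_path = Path(str(row["path"]))
        except KeyError as exc:
            raise ManifestError(rowno, f"missing field {exc}") from exc
        except ValueError as exc:
            raise ManifestError(rowno, str(exc)) from exc
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        raw_rows.append((rowno, sid, genus, view, img_path))

    if not raw_rows:
        raise EmptyDatasetError(f"manifest {path} contains no rows")

    genus_names = sorted({g for _, _, g, _, _ in raw_rows})
    genus_to_label = {g: i + 1 for i, g in enumerate(genus_names)}

    specimens: dict[str, SpecimenRecord] = {}
    for rowno, sid, genus, view, img_path in raw_rows:
        label = genus_to_label[genus]
        rec = specimens.get(sid)
        if rec is None:
            rec = specimens[sid] = SpecimenRecord(sid, label, {v: [] for v in VIEWS})
        elif rec.genus != label:
            raise ManifestError(rowno, f"specimen {sid!r} has conflicting genus labels")
        try:
            pixels = load_image(img_path)
        except FileNotFoundError as exc:
            raise ManifestError(rowno, f"image not found: {img_path}") from exc
        except Exception as exc:  # unreadable / corrupt image
            raise ManifestError(rowno, f"unreadable image {img_path}: {exc}") from exc
        rec.images_by_view[view].append(ImageSample(sid, view, pixels))

    label_names = {v: k for k, v in genus_to_label.items()}
    return MultiViewDataset(list(specimens.values()), label_names=label_names)


def write_manifest(ds: MultiViewDataset, directory: str | Path,
                   image_format: str = "png") -> Path:
    """Write a dataset to ``directory`` as PNG images plus ``manifest.csv``.

    Returns the manifest path.  A ``labels.json`` sidecar records the integer
    label -> name mapping.
    """
    from PIL import Image

    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "genus", "view", "path"])
        for spec in ds.specimens:
            name = (ds.label_names or {}).get(spec.genus, f"genus{spec.genus:03d}")
            for view in VIEWS:
                for idx, sample in enumerate(spec.pictures(view)):
                    rel = Path("images") / (
                        f"{spec.specimen_id}_{view.value}_{idx}.{image_format}"
                    )
                    arr = np.clip(np.rint(sample.pixels * 255), 0, 255).astype(np.uint8)
                    Image.fromarray(arr, mode="L").save(directory / rel)
                    writer.writerow([spec.specimen_id, name, view.value, rel.as_posix()])
    with open(directory / "labels.json", "w", encoding="utf-8") as fh:
        json.dump({str(k): v for k, v in (ds.label_names or {}).items()},
                  fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# filtering / summaries / splitting


def filter_labels_by_support(
    ds: MultiViewDataset, min_specimens: int
) -> tuple[MultiViewDataset, dict[int, int]]:
    """Keep only genera represented by at least ``min_specimens`` specimens.

    Labels are re-indexed to contiguous ``1..L'`` preserving order; the
    old -> new mapping is returned alongside the filtered dataset.  Raises
    :class:`EmptyDatasetError` when nothing survives.
    """
    if min_specimens < 1:
        raise ValueError("min_specimens must be >= 1")
    counts = ds.genus_counts()
    kept = sorted(g for g, c in counts.items() if c >= min_specimens)
    if not kept:
        raise EmptyDatasetError(
            f"no genus has >= {min_specimens} specimens (max support "
            f"{max(counts.values(), default=0)})"
        )
    mapping = {old: new + 1 for new, old in enumerate(kept)}
    specimens = [
        SpecimenRecord(s.specimen_id, mapping[s.genus],
                       {v: list(s.pictures(v)) for v in VIEWS})
        for s in ds.specimens
        if s.genus in mapping
    ]
    names = None
    if ds.label_names is not None:
        names = {mapping[g]: ds.label_names.get(g, str(g)) for g in kept}
    return MultiViewDataset(specimens, label_names=names), mapping


#: The six cardinality constraints summarised for any dataset, in report order.
_CONSTRAINTS: list[tuple[str, "callable"]] = [
    ("N_h + N_p + N_d >= 1", lambda s: s.n_pictures() >= 1),
    ("N_h = N_p = N_d = 1", SpecimenRecord.has_exactly_one_per_view),
    ("N_h >= 1 and N_p >= 1 and N_d >= 1", SpecimenRecord.has_all_views),
    ("N_h >= 1", lambda s: s.n_pictures(View.HEAD) >= 1),
    ("N_p >= 1", lambda s: s.n_pictures(View.PROFILE) >= 1),
    ("N_d >= 1", lambda s: s.n_pictures(View.DORSUM) >= 1),
]


def cardinality_summary(ds: MultiViewDataset) -> CardinalitySummary:
    """Count specimens satisfying each standard cardinality constraint.

    Rates are counts over the total number of specimens (0 for an empty
    dataset).
    """
    total = len(ds)
    rows = []
    for desc, pred in _CONSTRAINTS:
        count = sum(1 for s in ds.specimens if pred(s))
        rows.append((desc, count, count / total if total else 0.0))
    return CardinalitySummary(rows=rows, total=total)


def largest_remainder_quotas(total: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``total`` seats to ``fractions`` by the largest-remainder rule.

    Deterministic: remainder ties are broken toward the earlier fraction.
    """
    exact = [total * f for f in fractions]
    quotas = [int(np.floor(e)) for e in exact]
    remainders = [e - q for e, q in zip(exact, quotas)]
    leftover = total - sum(quotas)
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        quotas[i] += 1
    return quotas


def split_dataset(
    ds: MultiViewDataset,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train/validation/test split of a multi-view dataset.

    Per-genus specimen quotas follow the largest-remainder apportionment of
    ``fractions``.  Validation and test specimens are drawn (uniformly, seeded)
    only from those with exactly one picture per view; all remaining specimens
    — including every one with extra pictures — go to train, so no picture is
    discarded from the training base.  A genus without enough one-per-view
    specimens gets a reduced (possibly zero) validation/test quota, with a
    warning.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot split an empty dataset")
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError("fractions must be three non-negative reals summing to 1")

    rng = np.random.default_rng(seed)
    by_genus: dict[int, list[SpecimenRecord]] = {}
    for s in ds.specimens:
        by_genus.setdefault(s.genus, []).append(s)

    train_ids: list[str] = []
    val_ids: list[str] = []
    test_ids: list[str] = []
    for genus in sorted(by_genus):
        members = sorted(by_genus[genus], key=lambda s: s.specimen_id)
        _, n_val, n_test = largest_remainder_quotas(len(members), fr)
        eligible = [s for s in members if s.has_exactly_one_per_view()]
        if len(eligible) < n_val + n_test:
            warnings.warn(
                f"genus {genus}: only {len(eligible)} specimens with exactly one "
                f"picture per view; validation/test quota {n_val}+{n_test} reduced",
                stacklevel=2,
            )
        order = rng.permutation(len(eligible))
        chosen = [eligible[i].specimen_id for i in order]
        take_val = chosen[: min(n_val, len(chosen))]
        take_test = chosen[len(take_val): len(take_val) + n_test]
        val_ids.extend(take_val)
        test_ids.extend(take_test)
        held = set(take_val) | set(take_test)
        train_ids.extend(s.specimen_id for s in members if s.specimen_id not in held)

    return DatasetSplit(
        train=ds.subset(train_ids),
        validation=ds.subset(val_ids),
        test=ds.subset(test_ids),
        seed=seed,
        fractions=fr,
    )


def flatten_to_samples(
    ds: MultiViewDataset,
    views: Iterable[View] | None = None,
    shuffle_seed: int | None = None,
) -> list[tuple[ImageSample, int]]:
    """Flatten a dataset to a per-picture stream of ``(sample, genus)`` pairs.

    One element per picture (not per specimen).  Order is specimen order, then
    canonical view order, then picture index — deterministic; pass
    ``shuffle_seed`` for a seeded shuffle instead.
    """
    wanted = tuple(views) if views is not None else VIEWS
    out: list[tuple[ImageSample, int]] = []
    for spec in ds.specimens:
        for view in VIEWS:
            if view not in wanted:
                continue
            for sample in spec.pictures(view):
                out.append((sample, spec.genus))
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        order = rng.permutation(len(out))
        out = [out[i] for i in order]
    return out
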