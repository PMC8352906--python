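"""Longitudinal cut-mark series on long bones.

A butchered carcass is summarised as one numeric series: each of the four
long bones (humerus, radius, femur, tibia) is divided into ``n_bins`` equal
segments along its proximo-distal axis, cut-mark counts are accumulated per
segment, and the four per-bone vectors are concatenated in a fixed anatomical
order (forelimb then hindlimb, stylopod before zeugopod).  Two representations
are used downstream:

* **raw** — per-bin counts; carries both anatomical patterning and overall
  mark intensity (bulk defleshing of a fully fleshed carcass produces more
  marks than scrap removal from a carnivore kill);
* **relative** — per-bin percentage of the assemblage total (sums to 100);
  carries patterning only, so assemblages with very different mark counts but
  the same anatomical distribution look alike.

Positions are normalised fractions of bone length measured from the proximal
end.  Bone templates scanned distal-end-first (the tibia, in the source
scanning convention) are flagged with ``orientation="distal_first"`` and their
binned vectors are reversed at ingestion, so every internal series is
proximal-first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed anatomical order of the concatenated series.
ELEMENTS: tuple[str, ...] = ("humerus", "radius", "femur", "tibia")

#: Class labels: P = primary access (fully fleshed carcass),
#: S = secondary access (carnivore-consumed carcass).
PRIMARY = "P"
SECONDARY = "S"
CLASS_ORDER: tuple[str, str] = (PRIMARY, SECONDARY)


@dataclass(frozen=True)
class BoneTemplate:
    """Binning template for one skeletal element.

    Parameters
    ----------
    element:
        One of :data:`ELEMENTS`.
    n_bins:
        Number of equal-width bins along the proximo-distal axis.
    orientation:
        ``"proximal_first"`` if position 0 is the proximal end,
        ``"distal_first"`` if the element was digitised the opposite way
        (binned vectors are reversed so index 0 is always proximal).
    """

    element: str
    n_bins: int = 30
    orientation: str = "proximal_first"

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}; expected one of {ELEMENTS}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.orientation not in ("proximal_first", "distal_first"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def default_templates(n_bins: int = 30) -> dict[str, BoneTemplate]:
    """One template per element; tibia digitised distal-end-first."""
    return {
        el: BoneTemplate(el, n_bins, "distal_first" if el == "tibia" else "proximal_first")
        for el in ELEMENTS
    }


@dataclass(frozen=True)
class CutMarkRecord:
    """One cut mark on one specimen.

    ``position`` is the fraction of bone length from the proximal end after
    orientation correction, in [0, 1].
    """

    sample_id: str
    element: str
    position: float

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r} in record {self.sample_id!r}")
        if not (0.0 <= self.position <= 1.0):
            raise ValueError(
                f"position {self.position} out of [0, 1] in record {self.sample_id!r}"
            )


@dataclass
class AssemblageSeries:
    """Concatenated longitudinal series for one carcass / assemblage.

    ``values`` has length ``4 * n_bins`` with elements in :data:`ELEMENTS`
    order.  In ``raw`` mode values are nonnegative counts summing to
    ``total_marks``; in ``relative`` mode they are percentages summing to 100.
    """

    sample_id: str
    values: np.ndarray
    mode: str = "raw"
    total_marks: int = 0
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("raw", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def copy(self) -> "AssemblageSeries":
        return dataclasses.replace(self, values=self.values.copy())


def bin_marks(records: Iterable[CutMarkRecord], template: BoneTemplate) -> np.ndarray:
    """Discretise the marks of one sample+element into the template's bins.

    Bins are half-open ``[i/n, (i+1)/n)`` with position 1.0 assigned to the
    last bin.  For ``distal_first`` templates the vector is reversed so index
    0 is proximal.  Returns an integer count vector of length ``n_bins``.
    """
    n = template.n_bins
    counts = np.zeros(n, dtype=int)
    for rec in records:
        if rec.element != template.element:
            raise ValueError(
                f"record {rec.sample_id!r} has element {rec.element!r}, "
                f"template expects {template.element!r}"
            )
        idx = min(int(np.floor(rec.position * n)), n - 1)
        counts[idx] += 1
    if template.orientation == "distal_first":
        counts = counts[::-1].copy()
    return counts


def build_series(
    records: Iterable[CutMarkRecord],
    templates: Mapping[str, BoneTemplate] | None = None,
    sample_id: str | None = None,
) -> AssemblageSeries:
    """Concatenate per-element binned counts into one raw series.

    Missing elements contribute zero vectors (legal: differential preservation
    of long-bone portions is a real feature of archaeofaunal assemblages).
    Record order is irrelevant.
    """
    if templates is None:
        templates = default_templates()
    n_bins = {t.n_bins for t in templates.values()}
    if len(n_bins) != 1:
        raise ValueError("all templates in one study must share n_bins")
    records = list(records)
    if sample_id is None:
        sample_id = records[0].sample_id if records else ""
    per_element: dict[str, list[CutMarkRecord]] = {el: [] for el in ELEMENTS}
    for rec in records:
        per_element[rec.element].append(rec)
    parts = [bin_marks(per_element[el], templates[el]) for el in ELEMENTS]
    values = np.concatenate(parts).astype(float)
    return AssemblageSeries(sample_id, values, mode="raw", total_marks=len(records))


def to_relative(series: AssemblageSeries) -> AssemblageSeries:
    """Convert a raw series to per-bin percentages of the assemblage total.

    Raises ``ValueError`` on an all-zero assemblage (no patterning exists) or
    if the input is not raw.
    """
    if series.mode != "raw":
        raise ValueError("to_relative expects a raw-mode series")
    total = series.values.sum()
    if total <= 0:
        raise ValueError(
            f"assemblage {series.sample_id!r} has no marks; relative patterning undefined"
        )
    return dataclasses.replace(
        series, values=100.0 * series.values / total, mode="relative"
    )


@dataclass
class LabeledDataset:
    """A set of assemblage series with class labels.

    ``labels[i]`` is the class (:data:`PRIMARY` / :data:`SECONDARY`) of
    ``series[i]``.
    """

    series: list[AssemblageSeries]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.series) != len(self.labels):
            raise ValueError("series and labels must have equal length")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def X(self) -> np.ndarray:
        """Series values stacked into an (n_samples, series_length) matrix."""
        return np.stack([s.values for s in self.series])

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.series]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.series[i] for i in indices], [self.labels[i] for i in indices]
        )

    def by_class(self, label: str) -> list[AssemblageSeries]:
        return [s for s, lab in zip(self.series, self.labels) if lab == label]

    def to_relative(self) -> "LabeledDataset":
        return LabeledDataset([to_relative(s) for s in self.series], list(self.labels))


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_records_csv(path) -> tuple[dict[str, list[CutMarkRecord]], dict[str, str]]:
    """Read cut-mark records from CSV with columns sample_id,label,element,position.

    Returns (records grouped by sample_id, label per sample_id).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "label": str, "element": str})
    required = {"sample_id", "label", "element", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    records: dict[str, list[CutMarkRecord]] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        rec = CutMarkRecord(row.sample_id, row.element, float(row.position))
        records.setdefault(row.sample_id, []).append(rec)
        labels[row.sample_id] = row.label
    return records, labels


def load_dataset_csv(
    path, templates: Mapping[str, BoneTemplate] | None = None
) -> LabeledDataset:
    """Build a raw-mode :class:`LabeledDataset` from a records CSV."""
    records, labels = read_records_csv(path)
    series = [
        build_series(recs, templates, sample_id=sid) for sid, recs in records.items()
    ]
    return LabeledDataset(series, [labels[s.sample_id] for s in series])


def write_series_csv(dataset: LabeledDataset, path) -> None:
    """Write one row per sample: sample_id, label, mode, v1..vL."""
    length = dataset.X.shape[1]
    cols = ["sample_id", "label", "mode"] + [f"v{i + 1}" for i in range(length)]
    rows = [
        [s.sample_id, lab, s.mode, *s.values.tolist()]
        for s, lab in zip(dataset.series, dataset.labels)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_series_csv(path) -> LabeledDataset:
    """Inverse of :func:`write_series_csv`."""
    df = pd.read_csv(path, dtype={"sample_id": str, "label": str, "mode": str})
    value_cols = [c for c in df.columns if c.startswith("v")]
    series, labels = [], []
    for row in df.itertuples(index=False):
        values = np.array([getattr(row, c) for c in value_cols], dtype=float)
        mode = row.mode
        total = int(round(values.sum())) if mode == "raw" else 0
        series.append(AssemblageSeries(row.sample_id, values, mode=mode, total_marks=total))
        labels.append(row.label)
    return LabeledDataset(series, labels)
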