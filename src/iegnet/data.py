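"""Expression-table data model: reading, section averaging, normalization.

The pipeline starts from long-format densitometry tables: one row per
(animal, treatment group, ROI, adjacent-section replicate) with a
relative-dpm optical-density value, plus one reference-region channel
(gcc) per animal.  Three adjacent sections per animal are averaged, then
every analysis ROI is normalized against the same animal's gcc value
(ratio by default; subtraction available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import ROIRegistry, default_registry

__all__ = [
    "SectionMeasurement",
    "ExpressionTable",
    "StudyDataset",
    "read_long_table",
    "write_long_table",
    "measurements_to_frame",
    "average_sections",
    "normalize_by_reference",
    "load_study",
    "write_wide_tables",
]

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("animal_id", "group", "roi", "section", "value")


@dataclass(frozen=True)
class SectionMeasurement:
    """One optical-density reading from one section of one animal."""

    animal_id: str
    group: str
    roi: str
    section: int
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(
                f"negative relative-dpm value {self.value} "
                f"({self.animal_id}/{self.roi}/section {self.section})"
            )
        if self.section < 1:
            raise ValueError(f"section index must be >= 1, got {self.section}")


@dataclass
class ExpressionTable:
    """Normalized animal x ROI expression values for one treatment group."""

    group: str
    animals: list[str]
    rois: list[str]
    values: np.ndarray  # shape (n_animals, n_rois)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.animals), len(self.rois)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.animals)} animals x {len(self.rois)} ROIs"
            )
        if np.isnan(self.values).any():
            raise ValueError(f"missing cells in expression table for {self.group!r}")
        if len(self.animals) < 3:
            raise ValueError(
                f"group {self.group!r} has n={len(self.animals)} < 3 animals; "
                "correlation p-values need df = n-2 >= 1"
            )

    @property
    def n(self) -> int:
        return len(self.animals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.animals, columns=self.rois)

    @classmethod
    def from_frame(cls, group: str, frame: pd.DataFrame) -> "ExpressionTable":
        return cls(
            group=group,
            animals=list(frame.index.astype(str)),
            rois=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class StudyDataset:
    """All per-group expression tables of one study, sharing one registry."""

    registry: ROIRegistry
    tables: dict[str, ExpressionTable]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = list(self.registry.abbreviations)
        for label, table in self.tables.items():
            if table.rois != ref:
                raise ValueError(
                    f"group {label!r} ROI ordering differs from the registry"
                )

    @property
    def groups(self) -> list[str]:
        return list(self.tables)

    def table(self, group: str) -> ExpressionTable:
        try:
            return self.tables[group]
        except KeyError:
            raise ValueError(
                f"group {group!r} not in dataset (have {self.groups})"
            ) from None


def measurements_to_frame(measurements: Iterable[SectionMeasurement]) -> pd.DataFrame:
    rows = [(m.animal_id, m.group, m.roi, m.section, m.value) for m in measurements]
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def write_long_table(measurements: Iterable[SectionMeasurement], path: str | Path) -> Path:
    """Write measurements as long-format CSV/TSV (separator from suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    measurements_to_frame(measurements).to_csv(path, sep=sep, index=False)
    return path


def read_long_table(
    path: str | Path,
    registry: ROIRegistry | None = None,
    groups: Sequence[str] | None = None,
) -> list[SectionMeasurement]:
    """Parse a long-format table into measurements, validating against the registry.

    Every ROI must be either an analysis ROI of ``registry`` or its
    reference channel; unknown abbreviations and negative values are
    rejected.  If ``groups`` is given, unknown group labels are rejected
    too.  Row count is preserved one-to-one.
    """
    registry = registry or default_registry()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    missing = set(LONG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    known = set(registry.abbreviations) | {registry.reference_roi}
    bad_rois = sorted(set(frame["roi"].astype(str)) - known)
    if bad_rois:
        raise ValueError(f"{path}: unknown ROI abbreviations {bad_rois}")
    if groups is not None:
        bad_groups = sorted(set(frame["group"].astype(str)) - set(groups))
        if bad_groups:
            raise ValueError(f"{path}: unknown group labels {bad_groups}")
    if (frame["value"] < 0).any():
        bad = frame.loc[frame["value"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative value {bad['value']} for "
            f"{bad['animal_id']}/{bad['roi']}"
        )

    return [
        SectionMeasurement(
            animal_id=str(r.animal_id),
            group=str(r.group),
            roi=str(r.roi),
            section=int(r.section),
            value=float(r.value),
        )
        for r in frame.itertuples(index=False)
    ]


def average_sections(measurements: Sequence[SectionMeasurement]) -> pd.DataFrame:
    """Average adjacent-section replicates per (animal, group, ROI).

    Returns a frame with columns ``animal_id, group, roi, mean, sd,
    n_sections``.  The sd is the sample standard deviation (ddof=1),
    defined as 0 for a single replicate.  The replicate count is
    data-driven; a count other than 3 is logged as a warning because the
    assay protocol cuts three adjacent sections per animal.
    """
    if not measurements:
        raise ValueError("no measurements to average")
    frame = measurements_to_frame(measurements)
    agg = (
        frame.groupby(["animal_id", "group", "roi"], sort=False)["value"]
        .agg(mean="mean", sd="std", n_sections="count")
        .reset_index()
    )
    agg["sd"] = agg["sd"].fillna(0.0)
    odd = agg.loc[agg["n_sections"] != 3]
    if len(odd):
        logger.warning(
            "%d (animal, ROI) cells have a replicate count != 3 (protocol "
            "averages three adjacent sections)", len(odd)
        )
    return agg


def normalize_by_reference(
    averaged: pd.DataFrame,
    registry: ROIRegistry | None = None,
    mode: str = "ratio",
) -> StudyDataset:
    """Normalize section-averaged values against the reference channel.

    ``ratio`` divides every analysis-ROI value by the same animal's
    reference value (default; matches the near-unit scale of published
    relative-dpm means); ``subtract`` subtracts it.  The reference
    channel is removed from the analysis ROIs.  Missing cells are hard
    errors: with five animals per group there is no room for imputation.
    """
    registry = registry or default_registry()
    if mode not in {"ratio", "subtract"}:
        raise ValueError(f"unknown normalization mode {mode!r}")

    ref_rows = averaged.loc[averaged["roi"] == registry.reference_roi]
    ref_by_animal = dict(zip(ref_rows["animal_id"], ref_rows["mean"]))
    roi_order = list(registry.abbreviations)

    tables: dict[str, ExpressionTable] = {}
    for group, sub in averaged.groupby("group", sort=False):
        sub = sub.loc[sub["roi"] != registry.reference_roi]
        animals = sorted(set(sub["animal_id"]))
        for animal in animals:
            if animal not in ref_by_animal:
                raise ValueError(
                    f"animal {animal!r} has no reference ({registry.reference_roi}) value"
                )
            if mode == "ratio" and ref_by_animal[animal] == 0:
                raise ValueError(
                    f"animal {animal!r} has a zero reference value; "
                    "ratio normalization is undefined"
                )
        wide = sub.pivot(index="animal_id", columns="roi", values="mean")
        missing_rois = set(roi_order) - set(wide.columns)
        if missing_rois:
            raise ValueError(
                f"group {group!r} is missing ROIs {sorted(missing_rois)}"
            )
        wide = wide.reindex(index=animals, columns=roi_order)
        if wide.isna().any().any():
            bad = wide.stack(future_stack=True)
            bad = bad[bad.isna()].index.tolist()[:5]
            raise ValueError(f"group {group!r} has missing cells, e.g. {bad}")
        ref = np.array([ref_by_animal[a] for a in animals], dtype=float)
        if mode == "ratio":
            values = wide.to_numpy(dtype=float) / ref[:, None]
        else:
            values = wide.to_numpy(dtype=float) - ref[:, None]
        tables[str(group)] = ExpressionTable(
            group=str(group), animals=animals, rois=roi_order, values=values
        )

    return StudyDataset(
        registry=registry,
        tables=tables,
        provenance={
            "normalization_mode": mode,
            "reference_roi": registry.reference_roi,
            "normalization_scope": "per-animal",
        },
    )


def load_study(
    path: str | Path,
    registry: ROIRegistry | None = None,
    mode: str = "ratio",
) -> StudyDataset:
    """Read a long-format file, average sections, and normalize; one call."""
    registry = registry or default_registry()
    measurements = read_long_table(path, registry)
    return normalize_by_reference(average_sections(measurements), registry, mode)


def write_wide_tables(dataset: StudyDataset, directory: str | Path) -> list[Path]:
    """Write one wide-format (animals x ROIs) CSV per group."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, table in dataset.tables.items():
        safe = label.replace("/", "-")
        out = directory / f"expression_{safe}.csv"
        table.to_frame().to_csv(out)
        paths.append(out)
    return paths
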