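"""Core data model shared by every stage of the pipeline.

A study is a set of wings, each belonging to one sampled population.  A wing
is represented either by a fixed number of homologous landmarks (k x 2
coordinates, millimetres) or by a closed outline contour of one wing cell,
anchored on named landmarks.  Cox1 barcode sequences travel alongside as a
:class:`SequenceSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Specimen",
    "LandmarkConfiguration",
    "OutlineContour",
    "Dataset",
    "SequenceSet",
    "DatasetError",
    "ParseError",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending record."""


class DatasetError(ValueError):
    """A parsed file violates dataset-level invariants."""


@dataclass(frozen=True)
class Specimen:
    """One individual wing's identity."""

    id: str
    population: str
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.population:
            raise DatasetError(f"specimen {self.id!r}: population label is empty")


@dataclass
class LandmarkConfiguration:
    """One wing's k landmarks as an ordered (k, 2) array in millimetres."""

    specimen: Specimen
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DatasetError(
                f"specimen {self.specimen.id!r}: coordinates must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if self.k < 3:
            raise DatasetError(f"specimen {self.specimen.id!r}: need k >= 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise DatasetError(f"specimen {self.specimen.id!r}: non-finite coordinates")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


# canonical anchor landmark indices (1-based) for the two wing cells analysed
OUTLINES1_ANCHORS = (1, 2, 3, 4)   # cell between r-m cross vein, M, radiale, arculus
OUTLINES2_ANCHORS = (8, 9, 10)     # cell m4


@dataclass
class OutlineContour:
    """A closed contour of one wing cell, counter-clockwise, in millimetres.

    ``anchor_landmarks`` are the 1-based indices of the landmarks that define
    the cell; the first contour point coincides with the first anchor.
    """

    specimen: Specimen
    points: np.ndarray
    anchor_landmarks: tuple[int, ...] = OUTLINES1_ANCHORS
    outline_set: str = "outlines1"  # outlines1 | outlines2 | custom

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DatasetError(
                f"specimen {self.specimen.id!r}: contour must be (m, 2), "
                f"got {self.points.shape}"
            )
        if self.m < 8:
            raise DatasetError(f"specimen {self.specimen.id!r}: need m >= 8 contour points")
        if self.outline_set not in ("outlines1", "outlines2", "custom"):
            raise DatasetError(f"unknown outline_set {self.outline_set!r}")

    @property
    def m(self) -> int:
        return self.points.shape[0]


@dataclass
class Dataset:
    """A homogeneous collection of configurations plus the population grouping."""

    configurations: list = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_configurations(cls, configs: Iterable) -> "Dataset":
        configs = list(configs)
        groups: dict[str, list[str]] = {}
        for c in configs:
            groups.setdefault(c.specimen.population, []).append(c.specimen.id)
        return cls(configurations=configs, groups=groups)

    def validate(self) -> None:
        ids = [c.specimen.id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate specimen ids: {dup}")
        ks = {c.k for c in self.configurations if isinstance(c, LandmarkConfiguration)}
        if len(ks) > 1:
            raise DatasetError(f"inconsistent landmark counts across records: {sorted(ks)}")
        member_of = {}
        for pop, members in self.groups.items():
            for sid in members:
                if sid in member_of:
                    raise DatasetError(f"specimen {sid!r} assigned to multiple groups")
                member_of[sid] = pop
        for c in self.configurations:
            if c.specimen.id not in member_of:
                raise DatasetError(f"specimen {c.specimen.id!r} missing from groups")

    @property
    def n(self) -> int:
        return len(self.configurations)

    def labels(self) -> list[str]:
        """Population label per configuration, in configuration order."""
        return [c.specimen.population for c in self.configurations]

    def coordinate_array(self) -> np.ndarray:
        """(n, k, 2) array for landmark datasets."""
        return np.stack([c.coords for c in self.configurations])


@dataclass
class SequenceSet:
    """Nucleotide sequences with population labels.

    ``aligned`` is only set by :meth:`check_aligned`; operations that require
    an alignment must refuse unaligned sets.
    """

    records: list[tuple[str, str, str]]  # (id, population, sequence)
    aligned: bool = False
    length: int | None = None

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate sequence ids: {dup}")

    def check_aligned(self) -> bool:
        lengths = {len(r[2]) for r in self.records}
        if len(lengths) == 1:
            self.aligned = True
            self.length = lengths.pop()
        else:
            self.aligned = False
            self.length = None
        return self.aligned

    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def populations(self) -> dict[str, str]:
        return {r[0]: r[1] for r in self.records}

    def sequences(self) -> dict[str, str]:
        return {r[0]: r[2] for r in self.records}


def group_sizes(labels: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return out


def split_by_group(values: Sequence[float], labels: Sequence[str]) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    return {g: values[np.asarray([l == g for l in labels])] for g in dict.fromkeys(labels)}
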