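"""Core data model for microplate reporter-gene experiments.

A plate experiment is a collection of wells, each holding one time series
per measurement channel (absorbance, one or more fluorescence channels).
Times are kept in minutes since the start of the experiment throughout the
package; parsers convert on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ABSORBANCE",
    "WellSeries",
    "PlateExperiment",
    "fluorescence_channel",
    "normalize_well_label",
    "well_labels",
]

#: Canonical channel name for optical density readings.
ABSORBANCE = "absorbance"

_LABEL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


def fluorescence_channel(name: str = "gfp") -> str:
    """Canonical channel name for a named fluorescence signal."""
    return f"fluorescence:{name}"


def normalize_well_label(label: str) -> str:
    """Validate and upper-case a plate coordinate such as ``a6`` -> ``A6``."""
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"invalid well label {label!r}; expected e.g. 'A6'")
    row, col = m.group(1).upper(), int(m.group(2))
    if col < 1:
        raise ValueError(f"invalid well label {label!r}: column must be >= 1")
    return f"{row}{col}"


def well_labels(rows: int = 8, columns: int = 12) -> list[str]:
    """Row-major labels 'A1'..'H12' for a plate of the given shape."""
    return [
        f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(columns)
    ]


@dataclass
class WellSeries:
    """One channel's timestamped readings in one well.

    Parameters
    ----------
    well_label : str
        Plate coordinate, e.g. ``"A6"``.
    channel : str
        ``"absorbance"`` or ``"fluorescence:<name>"``.
    times : ndarray
        Minutes since experiment start, strictly increasing.
    values : ndarray
        Raw instrument readings (arbitrary units).
    outlier_mask : ndarray of bool
        True marks a point excluded from all downstream computation.
    corrected_values : ndarray, optional
        Background-corrected readings, same length as ``times``.
    """

    well_label: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    outlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    corrected_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.well_label = normalize_well_label(self.well_label)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.times.shape, dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.corrected_values is not None:
            self.corrected_values = np.asarray(self.corrected_values, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = self.times.size
        if self.values.size != n or self.outlier_mask.size != n:
            raise ValueError(
                f"{self.well_label}/{self.channel}: times, values and "
                "outlier_mask must have equal length"
            )
        if self.corrected_values is not None and self.corrected_values.size != n:
            raise ValueError(
                f"{self.well_label}/{self.channel}: corrected_values length mismatch"
            )
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"{self.well_label}/{self.channel}: times must be strictly increasing"
            )

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def inlier(self) -> np.ndarray:
        """Boolean mask of points NOT flagged as outliers."""
        return ~self.outlier_mask

    def active_values(self) -> np.ndarray:
        """Corrected values if present, raw values otherwise."""
        return self.values if self.corrected_values is None else self.corrected_values

    def inlier_points(self, corrected: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to non-outlier points."""
        v = self.active_values() if corrected else self.values
        keep = self.inlier
        return self.times[keep], v[keep]

    def replace(self, **kwargs) -> "WellSeries":
        d = dict(
            well_label=self.well_label,
            channel=self.channel,
            times=self.times.copy(),
            values=self.values.copy(),
            outlier_mask=self.outlier_mask.copy(),
            corrected_values=None
            if self.corrected_values is None
            else self.corrected_values.copy(),
        )
        d.update(kwargs)
        return WellSeries(**d)


@dataclass
class PlateExperiment:
    """All wells of one microplate run plus grouping and correction metadata."""

    plate_shape: tuple[int, int] = (8, 12)
    wells: dict[str, dict[str, WellSeries]] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    well_groups: dict[str, list[str]] = field(default_factory=dict)
    background_assignments: list[dict] = field(default_factory=list)

    def _check_label(self, label: str) -> str:
        label = normalize_well_label(label)
        rows, cols = self.plate_shape
        row = ord(label[0]) - ord("A")
        col = int(label[1:])
        if row >= rows or col > cols:
            raise ValueError(
                f"well {label} outside plate of shape {rows}x{cols}"
            )
        return label

    def add_series(self, series: WellSeries) -> None:
        label = self._check_label(series.well_label)
        self.wells.setdefault(label, {})[series.channel] = series

    def get_series(self, well_label: str, channel: str) -> WellSeries:
        label = normalize_well_label(well_label)
        try:
            return self.wells[label][channel]
        except KeyError:
            raise KeyError(f"no series for well {label}, channel {channel!r}") from None

    def define_group(self, name: str, members: Iterable[str]) -> None:
        labels = [normalize_well_label(m) for m in members]
        missing = [m for m in labels if m not in self.wells]
        if missing:
            raise ValueError(f"group {name!r} references unknown wells: {missing}")
        self.well_groups[name] = labels

    def channels(self) -> list[str]:
        out: list[str] = []
        for series_map in self.wells.values():
            for ch in series_map:
                if ch not in out:
                    out.append(ch)
        return sorted(out)

    def iter_series(self) -> Iterable[WellSeries]:
        for label in sorted(self.wells):
            for ch in sorted(self.wells[label]):
                yield self.wells[label][ch]
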