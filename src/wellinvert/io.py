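"""Parsing, saving and export of plate experiments.

Instrument formats are handled by *dialects*: plug-in functions registered
under a name, mapping raw file text to a :class:`~wellinvert.plate.PlateExperiment`.
Two dialects are built in:

``long-csv``
    A minimal instrument-agnostic format with one reading per row and the
    header ``well,channel,time,value``.  The time column may carry a unit
    tag (``time``, ``time_min``, ``time_s``, ``time (s)`` ...); seconds and
    hours are converted to minutes at parse time.

``wellinvert-json``
    The package's own versioned JSON schema (see ``docs/json_schema.md``),
    used both for archival saves (no results) and result export.  A
    parse -> write -> parse round trip is lossless for times, values,
    labels, masks, groups and metadata.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate import PlateExperiment, WellSeries, normalize_well_label

__all__ = [
    "ParseError",
    "register_dialect",
    "registered_dialects",
    "parse_experiment",
    "write_experiment_json",
    "save_experiment",
    "load_experiment",
    "export_curves",
    "export_summary_curve",
]

SCHEMA_VERSION = 1

_DIALECTS: dict[str, Callable[[str], PlateExperiment]] = {}


class ParseError(ValueError):
    """Raised for malformed instrument files; message names the offending line."""


def register_dialect(name: str):
    """Decorator registering a parser plug-in under ``name``."""

    def deco(fn: Callable[[str], PlateExperiment]):
        _DIALECTS[name] = fn
        return fn

    return deco


def registered_dialects() -> list[str]:
    return sorted(_DIALECTS)


def parse_experiment(source: str, dialect: str) -> PlateExperiment:
    """Parse raw file content with the named dialect plug-in.

    Times are converted to minutes; no outliers are flagged and no
    background correction is applied.
    """
    if dialect not in _DIALECTS:
        raise KeyError(
            f"unknown dialect {dialect!r}; registered: {registered_dialects()}"
        )
    if not source or not source.strip():
        raise ParseError("empty input")
    return _DIALECTS[dialect](source)


# ---------------------------------------------------------------------------
# long-CSV dialect
# ---------------------------------------------------------------------------

_TIME_UNIT = {
    "min": 1.0, "minute": 1.0, "minutes": 1.0, "m": 1.0,
    "s": 1.0 / 60.0, "sec": 1.0 / 60.0, "seconds": 1.0 / 60.0,
    "h": 60.0, "hr": 60.0, "hours": 60.0,
}


def _time_unit_factor(header: str) -> float:
    """Minutes-per-unit factor from a header like ``time_s`` or ``time (h)``."""
    m = re.match(r"^time(?:[_\s]*[\(\[]?([a-zA-Z]+)[\)\]]?)?$", header.strip())
    if m is None:
        raise ParseError(f"unrecognized time column header {header!r}")
    unit = (m.group(1) or "min").lower()
    if unit not in _TIME_UNIT:
        raise ParseError(f"unknown time unit {unit!r} in header {header!r}")
    return _TIME_UNIT[unit]


@register_dialect("long-csv")
def _parse_long_csv(source: str) -> PlateExperiment:
    reader = csv.reader(_io.StringIO(source))
    rows = [(i + 1, row) for i, row in enumerate(reader) if row and any(c.strip() for c in row)]
    if not rows:
        raise ParseError("no data rows")
    header_line, header = rows[0]
    cols = [c.strip().lower() for c in header]
    if len(cols) < 4 or cols[0] != "well" or cols[1] != "channel" or not cols[2].startswith("time") or cols[3] != "value":
        raise ParseError(
            f"line {header_line}: expected header 'well,channel,time,value', got {header!r}"
        )
    factor = _time_unit_factor(cols[2])

    data: dict[tuple[str, str], list[tuple[float, float]]] = {}
    seen: dict[tuple[str, str], set[float]] = {}
    for lineno, row in rows[1:]:
        if len(row) < 4:
            raise ParseError(f"line {lineno}: expected 4 fields, got {len(row)}")
        try:
            label = normalize_well_label(row[0])
        except ValueError as e:
            raise ParseError(f"line {lineno}: {e}") from None
        channel = row[1].strip()
        try:
            t = float(row[2]) * factor
            v = float(row[3])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric time or value {row[2:4]!r}") from None
        key = (label, channel)
        if t in seen.setdefault(key, set()):
            raise ParseError(
                f"line {lineno}: duplicate timestamp {row[2]} for well {label}, channel {channel}"
            )
        seen[key].add(t)
        data.setdefault(key, []).append((t, v))

    exp = PlateExperiment()
    for (label, channel), pts in data.items():
        pts.sort(key=lambda p: p[0])
        times = np.array([p[0] for p in pts])
        values = np.array([p[1] for p in pts])
        exp.add_series(WellSeries(label, channel, times, values))
    return exp


# ---------------------------------------------------------------------------
# wellinvert-json dialect
# ---------------------------------------------------------------------------


def write_experiment_json(
    exp: PlateExperiment,
    include_results: bool = False,
    results: Sequence | None = None,
) -> dict:
    """Serialize an experiment to the wellinvert-json document (a dict).

    With ``include_results=False`` this is the archival form: it carries
    everything needed to reproduce an analysis (raw data, outlier masks,
    corrections, background assignments, groups) but no results.  With
    ``include_results=True`` the estimation results are embedded as well.
    """
    if include_results and not results:
        raise ValueError("include_results=True but no results given")
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "plate_shape": list(exp.plate_shape),
        "metadata": dict(exp.metadata),
        "wells": {},
        "well_groups": {k: list(v) for k, v in exp.well_groups.items()},
        "background_assignments": [dict(b) for b in exp.background_assignments],
    }
    for series in exp.iter_series():
        w = doc["wells"].setdefault(series.well_label, {})
        w[series.channel] = {
            "times": series.times.tolist(),
            "values": series.values.tolist(),
            "outlier_mask": series.outlier_mask.astype(bool).tolist(),
            "corrected_values": None
            if series.corrected_values is None
            else series.corrected_values.tolist(),
        }
    if include_results:
        doc["results"] = [_result_to_dict(r) for r in results]  # type: ignore[union-attr]
    return doc


def _result_to_dict(result) -> dict:
    return {
        "well_label": result.well_label,
        "quantity": result.quantity,
        "times": np.asarray(result.times).tolist(),
        "values": np.asarray(result.values).tolist(),
        "validity_mask": np.asarray(result.validity_mask).astype(bool).tolist(),
        "lambda": None if result.lam is None else float(result.lam),
    }


@register_dialect("wellinvert-json")
def _parse_wellinvert_json(source: str) -> PlateExperiment:
    try:
        doc = json.loads(source)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e}") from None
    if "schema_version" not in doc:
        raise ParseError("missing schema_version field")
    exp = PlateExperiment(plate_shape=tuple(doc.get("plate_shape", (8, 12))))
    exp.metadata = {str(k): str(v) for k, v in doc.get("metadata", {}).items()}
    for label, channels in doc.get("wells", {}).items():
        for channel, block in channels.items():
            exp.add_series(
                WellSeries(
                    label,
                    channel,
                    np.asarray(block["times"], dtype=float),
                    np.asarray(block["values"], dtype=float),
                    outlier_mask=np.asarray(
                        block.get("outlier_mask") or [False] * len(block["times"]),
                        dtype=bool,
                    ),
                    corrected_values=None
                    if block.get("corrected_values") is None
                    else np.asarray(block["corrected_values"], dtype=float),
                )
            )
    for name, members in doc.get("well_groups", {}).items():
        exp.define_group(name, members)
    exp.background_assignments = [dict(b) for b in doc.get("background_assignments", [])]
    return exp


def save_experiment(exp: PlateExperiment, path, include_results=False, results=None) -> None:
    doc = write_experiment_json(exp, include_results=include_results, results=results)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_experiment(path) -> PlateExperiment:
    with open(path) as fh:
        return parse_experiment(fh.read(), dialect="wellinvert-json")


# ---------------------------------------------------------------------------
# Curve export
# ---------------------------------------------------------------------------


def export_curves(
    results: Mapping[tuple[str, str], object],
    wells: Iterable[str],
    quantities: Iterable[str],
    format: str = "csv",
):
    """Tabulate estimation results, one row per (well, quantity, time).

    ``results`` maps ``(well_label, quantity)`` to an estimation result.
    Returns a CSV string (``format="csv"``) or a JSON-serializable list of
    records (``format="json"``); numbers keep full precision.
    """
    wells = [normalize_well_label(w) for w in wells]
    quantities = list(quantities)
    missing = [
        (w, q) for w in wells for q in quantities if (w, q) not in results
    ]
    if missing:
        raise KeyError(f"missing results for (well, quantity) pairs: {missing}")
    records = []
    for w in wells:
        for q in quantities:
            r = results[(w, q)]
            for t, v, ok in zip(r.times, r.values, r.validity_mask):
                records.append(
                    {"well": w, "quantity": q, "time": float(t),
                     "value": float(v), "valid": bool(ok)}
                )
    if format == "json":
        return records
    if format == "csv":
        df = pd.DataFrame.from_records(
            records, columns=["well", "quantity", "time", "value", "valid"]
        )
        return df.to_csv(index=False, float_format="%.17g")
    raise ValueError(f"unknown export format {format!r}")


def export_summary_curve(curve, format: str = "csv"):
    """Export a group summary curve with columns time, mean, sd, sem, n."""
    df = pd.DataFrame(
        {"time": curve.grid, "mean": curve.mean, "sd": curve.sd,
         "sem": curve.sem, "n": curve.n}
    )
    if format == "json":
        return df.to_dict(orient="records")
    if format == "csv":
        return df.to_csv(index=False, float_format="%.17g")
    raise ValueError(f"unknown export format {format!r}")
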