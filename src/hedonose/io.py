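"""Text formats: raw measurement files, rating CSVs, feature CSVs.

Measurement dialect (one file per measurement)::

    # odorant=<id>
    # repetition=<n>
    # injection_end=<seconds>
    time  s00  s01 ... s15
    0.0   ...
    ...

Delimiter is auto-detected among tab, comma and whitespace.  Ratings are CSVs
with header ``subject,odorant,session,vas,cohort``; features are CSVs whose
first column is the sample id ``odorant:repetition`` followed by the 120
named feature columns.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .data import (
    Measurement,
    MeasurementFormatError,
    MeasurementSet,
    N_SENSORS,
    RatingTable,
    SensorTrace,
)
from .features import FEATURE_NAMES, FeatureMatrix, N_FEATURES, RAW

SENSOR_COLUMNS = [f"s{i:02d}" for i in range(N_SENSORS)]
_HEADER_RE = re.compile(r"^#\s*(\w+)\s*=\s*(.+?)\s*$")


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any whitespace


def _parse_measurement_text(text: str, source: str) -> Measurement:
    meta: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        m = _HEADER_RE.match(line)
        if m:
            meta[m.group(1)] = m.group(2)
        else:
            break
    for key in ("odorant", "repetition"):
        if key not in meta:
            raise MeasurementFormatError(f"{source}: missing '# {key}=' header")

    header_line = lines[i]
    delim = _sniff_delimiter(header_line)
    columns = header_line.split(delim) if delim else header_line.split()
    columns = [c.strip() for c in columns]
    if columns[0] != "time":
        raise MeasurementFormatError(f"{source}: first column must be 'time'")
    for sensor_idx, name in enumerate(SENSOR_COLUMNS):
        if name not in columns:
            raise MeasurementFormatError(f"{source}: sensor {sensor_idx} missing")

    rows = []
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(delim) if delim else line.split()
        if len(parts) != len(columns):
            raise MeasurementFormatError(
                f"{source}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise MeasurementFormatError(f"{source}:{lineno}: {exc}") from None
    if len(rows) < 4:
        raise MeasurementFormatError(f"{source}: fewer than 4 data rows")
    table = pd.DataFrame(rows, columns=columns)

    times = table["time"].to_numpy()
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0)) + 1
        raise MeasurementFormatError(
            f"{source}: time not strictly increasing at data row {bad + 1}"
        )

    traces = [
        SensorTrace(sensor_id=s, times=times, values=table[SENSOR_COLUMNS[s]].to_numpy())
        for s in range(N_SENSORS)
    ]
    return Measurement(
        odorant_id=meta["odorant"],
        repetition=int(meta["repetition"]),
        traces=traces,
        injection_end=float(meta.get("injection_end", 30.0)),
    )


def read_measurements(path: str | Path, on_error: str = "raise") -> MeasurementSet:
    """Read a measurement file or a directory of ``*.txt`` measurement files.

    Malformed files are never silently dropped: with ``on_error='raise'``
    (default) a single error listing every offending file is raised; with
    ``on_error='collect'`` the valid measurements are returned and the error
    messages stored under ``metadata['errors']``.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    if not files:
        raise MeasurementFormatError(f"no measurement files found under {path}")
    measurements, errors = [], []
    for f in files:
        try:
            measurements.append(_parse_measurement_text(f.read_text(), f.name))
        except MeasurementFormatError as exc:
            errors.append(str(exc))
    if errors and on_error == "raise":
        raise MeasurementFormatError(
            f"{len(errors)} malformed measurement file(s):\n" + "\n".join(errors)
        )
    return MeasurementSet(measurements, metadata={"errors": errors} if errors else {})


def write_measurements(
    measurements: MeasurementSet | Iterable[Measurement],
    directory: str | Path,
    fmt: str = "%.9g",
) -> list[Path]:
    """Write one dialect text file per measurement; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in measurements:
        safe = m.odorant_id.replace("/", "_").replace(":", "_")
        p = directory / f"{safe}_rep{m.repetition}.txt"
        times = m.traces[0].times
        body = np.column_stack([times] + [m.trace(s).values for s in range(N_SENSORS)])
        lines = [
            f"# odorant={m.odorant_id}",
            f"# repetition={m.repetition}",
            f"# injection_end={m.injection_end:g}",
            "\t".join(["time"] + SENSOR_COLUMNS),
        ]
        lines += ["\t".join(fmt % x for x in row) for row in body]
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths


def read_ratings(path: str | Path) -> RatingTable:
    """Read a ratings CSV (columns subject,odorant,session,vas,cohort)."""
    frame = pd.read_csv(path, dtype={"subject": str, "odorant": str, "cohort": str})
    return RatingTable(frame)


def write_ratings(ratings: RatingTable, path: str | Path) -> None:
    ratings.to_frame().to_csv(path, index=False)


def _split_sample_id(sample_id: str) -> str:
    return sample_id.rsplit(":", 1)[0]


def write_features(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV (sample id column + 120 named columns)."""
    matrix.to_frame().to_csv(path, index=True)


def read_features(path: str | Path, state: str = RAW) -> FeatureMatrix:
    """Read a feature CSV back; ``state`` declares its normalization state."""
    frame = pd.read_csv(path, index_col=0)
    if list(frame.columns) != list(FEATURE_NAMES):
        raise ValueError(
            f"feature CSV must have the canonical {N_FEATURES} columns; "
            f"got {len(frame.columns)}"
        )
    sample_ids = [str(s) for s in frame.index]
    return FeatureMatrix(
        sample_ids=sample_ids,
        odorant_ids=[_split_sample_id(s) for s in sample_ids],
        values=frame.to_numpy(dtype=float).reshape(len(sample_ids), N_FEATURES),
        state=state,
    )
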