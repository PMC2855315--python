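"""Domain containers for eNose measurements and human pleasantness ratings.

The instrument modelled here is a 16-sensor electronic nose: eight quartz
microbalance (QMB) sensors and eight metal-oxide (MOX) sensors sampled as
time-dependent signals while an odorant headspace is injected.  Human
pleasantness is collected on a visual-analogue scale (VAS) scored 0-30 and
aggregated per odorant as the median over all ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: sensors 0-7 are QMB, 8-15 are MOX (configurable convention)
QMB_SENSORS: tuple[int, ...] = tuple(range(0, 8))
MOX_SENSORS: tuple[int, ...] = tuple(range(8, 16))
N_SENSORS: int = 16

VAS_MIN: float = 0.0
VAS_MAX: float = 30.0
VAS_MID: float = 15.0


def module_for_sensor(sensor_id: int) -> str:
    """Module tag ('QMB' or 'MOX') for a sensor index under the default layout."""
    if sensor_id in QMB_SENSORS:
        return "QMB"
    if sensor_id in MOX_SENSORS:
        return "MOX"
    raise ValueError(f"sensor_id {sensor_id} outside 0-15")


class MeasurementFormatError(ValueError):
    """Raised when raw measurement data violate the format or its invariants."""


@dataclass
class SensorTrace:
    """One sensor's time-dependent response within a single measurement."""

    sensor_id: int
    times: np.ndarray
    values: np.ndarray
    module_tag: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise MeasurementFormatError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise MeasurementFormatError(
                f"sensor {self.sensor_id}: {len(self.times)} times vs "
                f"{len(self.values)} values"
            )
        if len(self.times) < 4:
            raise MeasurementFormatError(
                f"sensor {self.sensor_id}: need at least 4 samples, got {len(self.times)}"
            )
        if not np.all(np.diff(self.times) > 0):
            bad = int(np.argmax(np.diff(self.times) <= 0))
            raise MeasurementFormatError(
                f"sensor {self.sensor_id}: times not strictly increasing at index {bad + 1}"
            )
        expected = module_for_sensor(self.sensor_id)
        if self.module_tag is None:
            self.module_tag = expected
        elif self.module_tag != expected:
            raise MeasurementFormatError(
                f"sensor {self.sensor_id} tagged {self.module_tag}, expected {expected}"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Measurement:
    """One odorant presentation: 16 sensor traces plus identity and timing."""

    odorant_id: str
    repetition: int
    traces: list[SensorTrace]
    injection_end: float = 30.0

    def __post_init__(self) -> None:
        ids = sorted(t.sensor_id for t in self.traces)
        if ids != list(range(N_SENSORS)):
            missing = sorted(set(range(N_SENSORS)) - set(ids))
            if missing:
                raise MeasurementFormatError(
                    f"odorant {self.odorant_id!r} rep {self.repetition}: "
                    f"sensor {missing[0]} missing"
                )
            raise MeasurementFormatError(
                f"odorant {self.odorant_id!r} rep {self.repetition}: duplicate sensors"
            )
        self.traces = sorted(self.traces, key=lambda t: t.sensor_id)
        if self.repetition < 1:
            raise MeasurementFormatError("repetition index must be >= 1")

    @property
    def sample_id(self) -> str:
        return f"{self.odorant_id}:{self.repetition}"

    def trace(self, sensor_id: int) -> SensorTrace:
        return self.traces[sensor_id]


@dataclass
class MeasurementSet:
    """A collection of measurements over an odorant catalogue."""

    measurements: list[Measurement]
    metadata: dict = field(default_factory=dict)

    @property
    def odorants(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.measurements:
            seen.setdefault(m.odorant_id, None)
        return list(seen)

    def by_odorant(self, odorant_id: str) -> list[Measurement]:
        return [m for m in self.measurements if m.odorant_id == odorant_id]

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)


@dataclass(frozen=True)
class RatingRecord:
    """A single VAS pleasantness rating (0-30)."""

    subject_id: str
    odorant_id: str
    session: int
    vas: float
    cohort: str = "default"


class RatingTable:
    """Subject x odorant x session VAS ratings with uniqueness and bound checks.

    Backed by a pandas DataFrame with columns
    ``subject, odorant, session, vas, cohort``.
    """

    COLUMNS = ["subject", "odorant", "session", "vas", "cohort"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"rating table missing columns: {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["session"] = frame["session"].astype(int)
        frame["vas"] = frame["vas"].astype(float)
        bad = frame[(frame["vas"] < VAS_MIN) | (frame["vas"] > VAS_MAX)]
        if len(bad):
            rows = bad.index.tolist()[:5]
            raise ValueError(
                f"{len(bad)} VAS values outside [0, 30] (rows {rows}); "
                f"first offending value {bad['vas'].iloc[0]}"
            )
        dup = frame.duplicated(subset=["subject", "odorant", "session"], keep=False)
        if dup.any():
            keys = (
                frame.loc[dup, ["subject", "odorant", "session"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise ValueError(
                "duplicate (subject, odorant, session) entries: "
                + ", ".join(map(str, list(keys)[:10]))
            )
        self._frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[RatingRecord]) -> "RatingTable":
        rows = [
            (r.subject_id, r.odorant_id, r.session, r.vas, r.cohort) for r in records
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def subjects(self) -> list[str]:
        return sorted(self._frame["subject"].unique())

    @property
    def odorants(self) -> list[str]:
        return sorted(self._frame["odorant"].unique())

    @property
    def cohorts(self) -> list[str]:
        return sorted(self._frame["cohort"].unique())

    def __len__(self) -> int:
        return len(self._frame)


@dataclass
class PleasantnessTable:
    """Per-odorant median VAS pleasantness with rating counts."""

    median_vas: pd.Series  # index: odorant_id, values in [0, 30]
    n_ratings: pd.Series

    def __post_init__(self) -> None:
        self.median_vas = self.median_vas.astype(float)
        self.n_ratings = self.n_ratings.astype(int)

    @property
    def odorants(self) -> list[str]:
        return list(self.median_vas.index)

    def centered(self) -> pd.Series:
        """Median VAS centered at the scale midpoint (15), range [-15, 15]."""
        return self.median_vas - VAS_MID

    def __getitem__(self, odorant_id: str) -> float:
        return float(self.median_vas[odorant_id])

    def __len__(self) -> int:
        return len(self.median_vas)


def median_pleasantness(ratings: RatingTable | pd.DataFrame) -> PleasantnessTable:
    """Aggregate a rating table to per-odorant median pleasantness.

    Both sessions and all subjects are pooled; the even-count median is the
    mean of the two middle values.  Odorants with zero ratings cannot appear
    by construction of :class:`RatingTable`.
    """
    frame = ratings.to_frame() if isinstance(ratings, RatingTable) else ratings
    grouped = frame.groupby("odorant")["vas"]
    return PleasantnessTable(median_vas=grouped.median(), n_ratings=grouped.count())


def centered_to_vas(values: "np.ndarray | pd.Series | float"):
    """Map centered pleasantness (midpoint 0) back onto the 0-30 VAS scale."""
    return values + VAS_MID


def as_pleasantness_table(
    targets: "PleasantnessTable | RatingTable | Mapping[str, float] | pd.Series",
) -> PleasantnessTable:
    """Coerce any supported target container to a :class:`PleasantnessTable`."""
    if isinstance(targets, PleasantnessTable):
        return targets
    if isinstance(targets, RatingTable):
        return median_pleasantness(targets)
    series = pd.Series(dict(targets)) if not isinstance(targets, pd.Series) else targets
    return PleasantnessTable(
        median_vas=series.astype(float), n_ratings=pd.Series(1, index=series.index)
    )
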