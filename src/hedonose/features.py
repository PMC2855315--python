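"""Kinetic feature extraction and matrix normalization for eNose signatures.

Each sensor trace contributes four kinetic parameters (peak height, latency to
peak, half-max times on the rise and decay flanks).  Because absolute response
amplitude fluctuates between repetitions while the relative heights of the 8
sensors within a module are stable, the per-module pairwise max ratios are
appended: C(8,2) = 28 for the MOX module and 28 for the QMB module, giving a
canonical 120-feature signature per measurement (16 x 4 + 28 + 28).

The feature matrix is normalized in two steps: columns to zero mean / unit SD
(removes sensor-type bias) then rows to unit Euclidean norm (removes the
per-measurement vapor-concentration gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    MOX_SENSORS,
    N_SENSORS,
    QMB_SENSORS,
    Measurement,
    MeasurementSet,
    SensorTrace,
)

KINETIC_PARAMS = ("max", "tmax", "thalf_rise", "thalf_decay")
N_FEATURES = 120

#: canonical feature layout: 16 sensors x 4 kinetic params, 28 MOX ratios,
#: 28 QMB ratios (pairs (i, j), i < j, lexicographic)
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"s{s:02d}_{p}" for s in range(N_SENSORS) for p in KINETIC_PARAMS]
    + [f"mox_r{i:02d}_{j:02d}" for i, j in combinations(MOX_SENSORS, 2)]
    + [f"qmb_r{i:02d}_{j:02d}" for i, j in combinations(QMB_SENSORS, 2)]
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the feature extractor.

    baseline_window
        Seconds of pre-injection signal averaged into the baseline that is
        subtracted before any kinetic parameter is read off.  The window is
        measured from the first timestamp.
    epsilon
        Floor added to both numerator and denominator of the max ratios so
        they stay finite and strictly positive for degenerate (flat) traces.
    row_norm
        Norm used in the row-normalization step, ``l2`` (default) or ``l1``.
    """

    baseline_window: float = 5.0
    epsilon: float = 1e-9
    row_norm: str = "l2"


@dataclass
class SensorParams:
    """The four kinetic parameters of one baseline-corrected sensor trace."""

    max_value: float
    latency_to_max: float
    t_half_rise: float
    t_half_decay: float
    flags: frozenset[str] = frozenset()

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.max_value, self.latency_to_max, self.t_half_rise, self.t_half_decay)


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def extract_sensor_params(
    trace: SensorTrace, baseline_window: float = 5.0
) -> SensorParams:
    """Extract (max, latency-to-max, half-max rise time, half-max decay time).

    The baseline is the mean of the samples within ``baseline_window`` seconds
    of the first timestamp and is subtracted before reading parameters.  Both
    half-max times are first crossings of max/2 (linear interpolation between
    samples), on the rise flank before the peak and the decay flank after it.
    A signal that never decays below half max gets the last timestamp, flagged
    ``no_decay_half``; an all-constant trace is degenerate: max 0 and all
    three times equal to the peak time, flagged ``degenerate``.
    """
    t = trace.times
    v = trace.values
    flags: set[str] = set()

    in_window = t <= t[0] + baseline_window
    if not in_window.any():
        in_window = np.zeros_like(t, dtype=bool)
        in_window[0] = True
    corrected = v - v[in_window].mean()

    peak_idx = int(np.argmax(corrected))  # first maximum
    peak_time = float(t[peak_idx])
    max_value = float(corrected[peak_idx])
    if max_value <= 0.0:
        flags.add("degenerate")
        if max_value < 0.0:
            flags.add("negative_max_clipped")
        return SensorParams(0.0, peak_time, peak_time, peak_time, frozenset(flags))

    half = max_value / 2.0

    # rise flank: first crossing of max/2 at or before the peak
    if corrected[0] >= half:
        t_half_rise = float(t[0])
        flags.add("rise_above_half_at_start")
    else:
        idx = int(np.argmax(corrected[: peak_idx + 1] >= half))
        t_half_rise = _interp_crossing(
            float(t[idx - 1]), float(corrected[idx - 1]), float(t[idx]),
            float(corrected[idx]), half,
        )

    # decay flank: first crossing below max/2 after the peak
    after = corrected[peak_idx:]
    below = after <= half
    below[0] = False  # the peak itself is above half by construction
    if not below.any():
        t_half_decay = float(t[-1])
        flags.add("no_decay_half")
    else:
        rel = int(np.argmax(below))
        idx = peak_idx + rel
        t_half_decay = _interp_crossing(
            float(t[idx - 1]), float(corrected[idx - 1]), float(t[idx]),
            float(corrected[idx]), half,
        )

    return SensorParams(max_value, peak_time, t_half_rise, t_half_decay, frozenset(flags))


def max_ratios(maxima: Sequence[float], epsilon: float = 1e-9) -> np.ndarray:
    """All C(8,2)=28 pairwise ratios (m_i + eps)/(m_j + eps), i < j, lexicographic."""
    m = np.asarray(maxima, dtype=float)
    if m.shape != (8,):
        raise ValueError(f"expected 8 maxima, got shape {m.shape}")
    pairs = list(combinations(range(8), 2))
    return np.array([(m[i] + epsilon) / (m[j] + epsilon) for i, j in pairs])


@dataclass
class FeatureVector:
    """The canonical 120-entry signature of one measurement."""

    sample_id: str
    odorant_id: str
    values: np.ndarray
    flags: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")

    def __len__(self) -> int:
        return N_FEATURES


def extract_features(
    measurement: Measurement, config: FeatureConfig | None = None
) -> FeatureVector:
    """Turn a 16-trace measurement into its 120-feature signature.

    Ratios are computed on the baseline-corrected maxima with the epsilon
    floor, per module, pairs (i, j) with i < j in sensor order.
    """
    config = config or FeatureConfig()
    params = [
        extract_sensor_params(measurement.trace(s), config.baseline_window)
        for s in range(N_SENSORS)
    ]
    kinetic = np.concatenate([p.as_tuple() for p in params])
    maxima = np.array([p.max_value for p in params])
    mox = max_ratios(maxima[list(MOX_SENSORS)], config.epsilon)
    qmb = max_ratios(maxima[list(QMB_SENSORS)], config.epsilon)
    flags = {s: p.flags for s, p in enumerate(params) if p.flags}
    return FeatureVector(
        sample_id=measurement.sample_id,
        odorant_id=measurement.odorant_id,
        values=np.concatenate([kinetic, mox, qmb]),
        flags=flags,
    )


RAW = "raw"
COLUMN_NORMALIZED = "column_normalized"
FULLY_NORMALIZED = "fully_normalized"


@dataclass
class FeatureMatrix:
    """n_samples x 120 signature matrix with explicit normalization state."""

    sample_ids: list[str]
    odorant_ids: list[str]
    values: np.ndarray
    state: str = RAW
    zero_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, got {self.values.shape}"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")
        if len(self.odorant_ids) != self.values.shape[0]:
            raise ValueError("odorant_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(FEATURE_NAMES),
        )

    def subset(self, row_indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(row_indices)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            odorant_ids=[self.odorant_ids[i] for i in idx],
            values=self.values[idx],
            state=self.state,
        )

    def rows_for_odorants(self, odorants: Iterable[str]) -> "FeatureMatrix":
        wanted = set(odorants)
        return self.subset(
            [i for i, o in enumerate(self.odorant_ids) if o in wanted]
        )


def build_feature_matrix(
    measurements: MeasurementSet | Iterable[Measurement],
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Extract signatures for every measurement into a raw FeatureMatrix."""
    vectors = [extract_features(m, config) for m in measurements]
    if not vectors:
        return FeatureMatrix([], [], np.empty((0, N_FEATURES)))
    return FeatureMatrix(
        sample_ids=[v.sample_id for v in vectors],
        odorant_ids=[v.odorant_id for v in vectors],
        values=np.vstack([v.values for v in vectors]),
    )


class Normalizer:
    """Column z-scoring followed by row unit-norm scaling.

    Column statistics (mean, SD) are estimated once on a training matrix and
    frozen, so novel-odorant matrices are transformed with the same
    preprocessing the model was trained under.  Constant columns map to zero;
    all-zero rows are left as zeros and flagged.
    """

    def __init__(self, row_norm: str = "l2"):
        if row_norm not in ("l2", "l1"):
            raise ValueError("row_norm must be 'l2' or 'l1'")
        self.row_norm = row_norm
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.means_ is not None

    def fit(self, matrix: FeatureMatrix) -> "Normalizer":
        if matrix.state != RAW:
            raise ValueError(f"can only fit on a raw matrix, got {matrix.state}")
        if matrix.n_samples < 2:
            raise ValueError("column SD undefined for fewer than 2 samples")
        self.means_ = matrix.values.mean(axis=0)
        self.sds_ = matrix.values.std(axis=0)
        return self

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if not self.fitted:
            raise ValueError("Normalizer is not fitted")
        if matrix.state != RAW:
            raise ValueError(f"can only transform a raw matrix, got {matrix.state}")
        sds = np.where(self.sds_ == 0.0, 1.0, self.sds_)
        cols = (matrix.values - self.means_) / sds
        cols[:, self.sds_ == 0.0] = 0.0

        if self.row_norm == "l2":
            norms = np.linalg.norm(cols, axis=1)
        else:
            norms = np.abs(cols).sum(axis=1)
        zero_rows = np.flatnonzero(norms == 0.0).tolist()
        safe = np.where(norms == 0.0, 1.0, norms)
        rows = cols / safe[:, None]
        return FeatureMatrix(
            sample_ids=list(matrix.sample_ids),
            odorant_ids=list(matrix.odorant_ids),
            values=rows,
            state=FULLY_NORMALIZED,
            zero_rows=zero_rows,
        )

    def fit_transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        return self.fit(matrix).transform(matrix)

    def column_normalize(self, matrix: FeatureMatrix) -> FeatureMatrix:
        """Apply only the column step (diagnostic intermediate state)."""
        if not self.fitted:
            raise ValueError("Normalizer is not fitted")
        sds = np.where(self.sds_ == 0.0, 1.0, self.sds_)
        cols = (matrix.values - self.means_) / sds
        cols[:, self.sds_ == 0.0] = 0.0
        return FeatureMatrix(
            sample_ids=list(matrix.sample_ids),
            odorant_ids=list(matrix.odorant_ids),
            values=cols,
            state=COLUMN_NORMALIZED,
        )


def normalize(matrix: FeatureMatrix, row_norm: str = "l2") -> FeatureMatrix:
    """Convenience: fit a Normalizer on ``matrix`` itself and transform it."""
    return Normalizer(row_norm=row_norm).fit_transform(matrix)
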