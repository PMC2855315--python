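"""Synthetic eNose measurements and human rating tables.

The generator emulates the statistical structure the analysis pipeline
relies on, without attempting real MOX/QMB chemistry:

* each odorant is a latent descriptor vector (standard-normal coordinates)
  whose projection on one hidden direction determines true pleasantness on
  the 0-30 VAS scale;
* each sensor responds with a saturating-rise / exponential-decay waveform
  whose amplitude is a softplus of a sensor-specific linear readout of the
  descriptor; a multiplicative "vapor concentration" factor is shared by all
  16 sensors of one measurement (this is exactly what row normalization must
  cancel), plus additive per-sample noise;
* sensor gains are built so the summed response magnitude carries no linear
  information about pleasantness: the per-sensor loadings on the
  pleasantness direction are heterogeneous and sum to zero, so intensity
  and hedonics are decoupled while the response *pattern* remains
  informative;
* occasional failed measurements have their 16 amplitudes re-randomized,
  destroying the odorant pattern (the signature the clustering QC detects);
* raters add subject noise per subject x odorant x session, and an optional
  scale-usage parameter gamma compresses ratings toward the scale extremes
  (gamma = 0 reproduces faithful mid-scale raters).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    Measurement,
    MeasurementSet,
    N_SENSORS,
    RatingTable,
    SensorTrace,
    VAS_MAX,
    VAS_MID,
    VAS_MIN,
)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class OdorantLibrary:
    """Latent descriptors and true pleasantness for a set of odorants."""

    odorant_ids: list[str]
    descriptors: np.ndarray  # (n_odorants, d)
    true_pleasantness: np.ndarray  # (n_odorants,), in [0, 30]
    pleasantness_direction: np.ndarray  # unit vector w, (d,)
    slope: float

    @property
    def n_odorants(self) -> int:
        return len(self.odorant_ids)

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]

    def truth_series(self) -> pd.Series:
        return pd.Series(
            self.true_pleasantness, index=self.odorant_ids, name="true_pleasantness"
        )


def generate_library(
    n_odorants: int = 76,
    d: int = 40,
    seed: int = 0,
    slope: float = 7.5,
    perturbation: float = 3.5,
) -> OdorantLibrary:
    """Draw an odorant library with pleasantness affine in one latent direction.

    Descriptors are i.i.d. standard normal; true pleasantness is
    ``15 + slope * (w . descriptor) + u`` clipped to [0, 30], with w
    unit-norm and u uniform on [-perturbation, perturbation].  The default
    slope 7.5 makes pleasantness span most of the scale (SD 7.5 before
    clipping); the bounded perturbation is the perceptual component not
    written into the molecular descriptor, capping how well any
    descriptor-based predictor can do.
    """
    if n_odorants < 2 or d < 1:
        raise ValueError("need n_odorants >= 2 and d >= 1")
    rng = np.random.default_rng(seed)
    descriptors = rng.standard_normal((n_odorants, d))
    w = rng.standard_normal(d)
    w /= np.linalg.norm(w)
    u = rng.uniform(-perturbation, perturbation, size=n_odorants)
    p = np.clip(VAS_MID + slope * (descriptors @ w) + u, VAS_MIN, VAS_MAX)
    ids = [f"od{i:03d}" for i in range(n_odorants)]
    return OdorantLibrary(ids, descriptors, p, w, slope)


@dataclass
class SensorModel:
    """Response model of one sensor: linear readout gain and kinetics."""

    gain: np.ndarray  # (d,)
    tau_rise: float  # seconds
    tau_decay: float  # seconds
    sigma_add: float = 0.02
    sigma_mult: float = 0.1
    sigma_sensor: float = 0.2

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma_add < 0 or self.sigma_mult < 0 or self.sigma_sensor < 0:
            raise ValueError("noise levels must be non-negative")


def default_sensor_array(
    library: OdorantLibrary,
    seed: int = 0,
    sigma_add: float = 0.02,
    sigma_mult: float = 0.1,
    sigma_sensor: float = 0.2,
    hedonic_loading: float = 0.4,
    background_loading: float = 0.8,
) -> list[SensorModel]:
    """Build 16 sensors whose summed response is hedonically uninformative.

    Each gain is ``background + h_s * w``: the background component is
    orthogonal to the pleasantness direction w, and the per-sensor hedonic
    loadings h_s are drawn from N(0, hedonic_loading) and centered to sum
    to zero across the array.  Individual sensors therefore respond to
    pleasantness weakly and heterogeneously — the realistic regime in which
    the hedonic direction must be estimated from many training odorants —
    while the first-order dependence of the total response magnitude on
    pleasantness cancels exactly.  ``sigma_sensor`` is the per-sensor,
    per-measurement amplitude instability (relative SD) that row
    normalization cannot cancel; it is what makes repeated measurements of
    one odorant scatter, as real eNose repetitions do.
    """
    rng = np.random.default_rng(seed)
    w = library.pleasantness_direction
    d = library.d
    loadings = rng.normal(0.0, 1.0, size=N_SENSORS)
    loadings -= loadings.mean()  # zero-sum: intensity carries no hedonics
    loadings *= hedonic_loading * np.sqrt(N_SENSORS) / np.linalg.norm(loadings)
    sensors = []
    for s in range(N_SENSORS):
        g = rng.standard_normal(d)
        g -= (g @ w) * w  # orthogonalize against the hedonic direction
        norm = np.linalg.norm(g)
        if norm > 0:
            g *= background_loading / norm
        gain = g + loadings[s] * w
        sensors.append(
            SensorModel(
                gain=gain,
                tau_rise=float(rng.uniform(4.0, 12.0)),
                tau_decay=float(rng.uniform(15.0, 60.0)),
                sigma_add=sigma_add,
                sigma_mult=sigma_mult,
                sigma_sensor=sigma_sensor,
            )
        )
    return sensors


def _waveform(
    times: np.ndarray, amplitude: float, tau_rise: float, tau_decay: float,
    injection_end: float,
) -> np.ndarray:
    """Saturating rise during injection, exponential decay after, continuous."""
    rise = amplitude * (1.0 - np.exp(-times / tau_rise))
    peak = amplitude * (1.0 - np.exp(-injection_end / tau_rise))
    decay = peak * np.exp(-(times - injection_end) / tau_decay)
    return np.where(times <= injection_end, rise, decay)


def generate_measurements(
    library: OdorantLibrary,
    sensors: list[SensorModel],
    reps: int = 5,
    failure_rate: float = 0.0,
    seed: int = 0,
    grid_end: float = 300.0,
    dt: float = 1.0,
    injection_end: float = 30.0,
) -> MeasurementSet:
    """Simulate ``reps`` measurements per odorant on a fixed time grid.

    A ``failure_rate`` fraction of measurements (ground truth recorded in
    ``metadata['failed']``) have their amplitudes independently re-randomized,
    which destroys the odorant's sensor pattern while keeping a plausible
    waveform — the minimal model of the instrument instability the
    clustering QC is meant to catch.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 <= failure_rate < 1.0:
        raise ValueError("failure_rate must be in [0, 1)")
    if len(sensors) != N_SENSORS:
        raise ValueError(f"need exactly {N_SENSORS} sensor models")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, grid_end + dt / 2, dt)
    sigma_mult = sensors[0].sigma_mult
    gain_norms = np.array([np.linalg.norm(s.gain) for s in sensors])

    measurements: list[Measurement] = []
    failed: dict[str, bool] = {}
    for i, odorant in enumerate(library.odorant_ids):
        x = library.descriptors[i]
        base_amp = _softplus(np.array([s.gain @ x for s in sensors]))
        for rep in range(1, reps + 1):
            is_failed = bool(rng.random() < failure_rate)
            if is_failed:
                amp = _softplus(rng.standard_normal(N_SENSORS) * gain_norms)
            else:
                amp = base_amp.copy()
            # per-sensor amplitude instability (not shared, not cancellable)
            for s, sensor in enumerate(sensors):
                if sensor.sigma_sensor > 0:
                    amp[s] = amp[s] * max(
                        1.0 + rng.normal(0.0, sensor.sigma_sensor), 0.05
                    )
            concentration = 1.0 + rng.normal(0.0, sigma_mult) if sigma_mult > 0 else 1.0
            traces = []
            for s, sensor in enumerate(sensors):
                clean = _waveform(
                    times, amp[s] * concentration, sensor.tau_rise,
                    sensor.tau_decay, injection_end,
                )
                noise = (
                    rng.normal(0.0, sensor.sigma_add, size=times.shape)
                    if sensor.sigma_add > 0
                    else 0.0
                )
                traces.append(SensorTrace(sensor_id=s, times=times, values=clean + noise))
            m = Measurement(
                odorant_id=odorant, repetition=rep, traces=traces,
                injection_end=injection_end,
            )
            measurements.append(m)
            failed[m.sample_id] = is_failed
    return MeasurementSet(measurements, metadata={"failed": failed})


@dataclass
class RaterModel:
    """A cohort of synthetic raters.

    ``sigma_subj`` is the SD (VAS units) of the noise drawn independently per
    subject x odorant x session.  ``gamma`` controls scale usage: 0 means
    faithful linear use of the VAS; larger values push ratings toward the
    extremes through a smooth arctangent distortion (slope (30/pi)*gamma at
    mid-scale), emulating cohorts that avoid the middle of the scale.
    """

    n_subjects: int = 15
    sigma_subj: float = 6.0
    gamma: float = 0.0
    cohort: str = "cohortA"
    odorant_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.sigma_subj < 0 or self.gamma < 0:
            raise ValueError("sigma_subj and gamma must be non-negative")


def generate_ratings(
    library: OdorantLibrary,
    rater: RaterModel | None = None,
    sessions: int = 2,
    seed: int = 0,
) -> RatingTable:
    """Simulate a VAS rating table for one cohort.

    rating = clip(15 + (30/pi) * atan(gamma * (p_true + offset + eta - 15)), 0, 30)
    for gamma > 0, else clip(p_true + offset + eta, 0, 30), with
    eta ~ N(0, sigma_subj) independent per subject x odorant x session.
    """
    if sessions not in (1, 2):
        raise ValueError("sessions must be 1 or 2")
    rater = rater or RaterModel()
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(rater.n_subjects):
        subject = f"{rater.cohort}_s{k:02d}"
        for i, odorant in enumerate(library.odorant_ids):
            base = library.true_pleasantness[i] + rater.odorant_offsets.get(odorant, 0.0)
            for session in range(1, sessions + 1):
                eta = rng.normal(0.0, rater.sigma_subj) if rater.sigma_subj > 0 else 0.0
                raw = base + eta
                if rater.gamma > 0:
                    value = VAS_MID + (VAS_MAX / np.pi) * np.arctan(
                        rater.gamma * (raw - VAS_MID)
                    )
                else:
                    value = raw
                rows.append(
                    (subject, odorant, session, float(np.clip(value, VAS_MIN, VAS_MAX)),
                     rater.cohort)
                )
    return RatingTable(pd.DataFrame(rows, columns=RatingTable.COLUMNS))


@dataclass
class SimulatedStudy:
    """A complete synthetic study: library, sensors, measurements, ratings."""

    library: OdorantLibrary
    sensors: list[SensorModel]
    measurements: MeasurementSet
    ratings: RatingTable

    @property
    def failed(self) -> dict[str, bool]:
        return self.measurements.metadata.get("failed", {})


def generate_benchmark(
    seed: int = 0,
    n_odorants: int = 76,
    d: int = 40,
    reps: int = 5,
    failure_rate: float = 0.05,
    sigma_add: float = 0.02,
    sigma_mult: float = 0.1,
    sigma_sensor: float = 0.2,
    n_subjects: int = 15,
    sigma_subj: float = 6.0,
    gamma: float = 0.0,
    sessions: int = 2,
) -> SimulatedStudy:
    """The standard synthetic benchmark: a 76-odorant training library
    measured 5 times each, rated twice by 15 subjects.

    Sub-seeds for the library, sensor array, measurements and ratings are
    spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_lib, s_sens, s_meas, s_rate = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    library = generate_library(n_odorants=n_odorants, d=d, seed=s_lib)
    sensors = default_sensor_array(
        library, seed=s_sens, sigma_add=sigma_add, sigma_mult=sigma_mult,
        sigma_sensor=sigma_sensor,
    )
    measurements = generate_measurements(
        library, sensors, reps=reps, failure_rate=failure_rate, seed=s_meas
    )
    ratings = generate_ratings(
        library,
        RaterModel(n_subjects=n_subjects, sigma_subj=sigma_subj, gamma=gamma),
        sessions=sessions,
        seed=s_rate,
    )
    return SimulatedStudy(library, sensors, measurements, ratings)
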