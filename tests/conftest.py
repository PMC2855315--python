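import numpy as np
import pytest
from hypothesis import settings

import hedonose as hn

settings.register_profile("deterministic", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study():
    """The standard synthetic benchmark study (76 odorants x 5 reps)."""
    return hn.generate_benchmark(seed=11)


@pytest.fixture(scope="session")
def prepared(study):
    """QC'd raw feature matrix + QC result for the benchmark study."""
    return hn.prepare_features(study.measurements)


@pytest.fixture(scope="session")
def targets(study):
    return hn.median_pleasantness(study.ratings)


@pytest.fixture(scope="session")
def noiseless_setup():
    """A noise-free, fully learnable study: 60 odorants x 5 reps.

    Pleasantness is exactly linear in the descriptors (no perceptual
    perturbation), sensors respond strongly to the hedonic direction and
    carry no noise, so any shortfall from perfect recovery isolates the
    trainer rather than the data.
    """
    lib = hn.generate_library(60, seed=3, perturbation=0.0)
    sensors = hn.default_sensor_array(
        lib, seed=3, sigma_add=0.0, sigma_mult=0.0, sigma_sensor=0.0,
        hedonic_loading=0.8,
    )
    mset = hn.generate_measurements(lib, sensors, reps=5, failure_rate=0.0, seed=3)
    return lib, mset


def make_trace(times, values, sensor_id=0):
    return hn.SensorTrace(sensor_id=sensor_id, times=np.asarray(times, float),
                          values=np.asarray(values, float))


def make_measurement(odorant="odA", repetition=1, n_samples=40, amplitudes=None,
                     rng=None):
    """A simple synthetic measurement with triangular per-sensor waveforms."""
    rng = rng or np.random.default_rng(0)
    times = np.arange(n_samples, dtype=float)
    traces = []
    for s in range(16):
        a = 1.0 + s if amplitudes is None else amplitudes[s]
        peak = 10 + s % 5
        values = np.where(
            times <= peak, a * times / peak,
            np.clip(a * (1 - (times - peak) / 20.0), 0, None),
        )
        traces.append(make_trace(times, values, sensor_id=s))
    return hn.Measurement(odorant_id=odorant, repetition=repetition, traces=traces)
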