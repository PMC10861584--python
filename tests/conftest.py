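import numpy as np
import pytest

from urovoc.simulate import (
    CANCER,
    NON_CANCER,
    HeaterProtocol,
    SensorTrace,
    SyntheticConfig,
)


@pytest.fixture
def protocol():
    return HeaterProtocol()


@pytest.fixture
def short_protocol():
    """Two 40 s cycles at 1 s sampling: fast traces for simulation-heavy tests."""
    return HeaterProtocol(
        voltage_levels_mv=(2000.0, 3500.0), cycle_duration_s=40.0,
        sampling_interval_s=1.0,
    )


@pytest.fixture
def noiseless_config():
    """Deterministic forced geometry: baseline 100, gap 60, full recovery."""
    return SyntheticConfig(
        n_cancer=1, n_noncancer=1, n_sensors=1,
        baseline_resistance_mean=100.0, baseline_resistance_sd=0.0,
        gap_mean=60.0, gap_sd=0.0,
        fall_time_mean=15.0, fall_time_sd=0.0,
        recovery_fraction=1.0, noise_sd=0.0, seed=1,
    )


def make_trace(resistances, dt=1.0, protocol=None, subject="x", sensor=1):
    r = np.asarray(resistances, dtype=float)
    if protocol is None:
        n_cycles = max(1, int(len(r) * dt // 80.0))
        protocol = HeaterProtocol(
            voltage_levels_mv=tuple([2000.0] * max(n_cycles, 1)),
            cycle_duration_s=80.0, sampling_interval_s=dt,
        )
    return SensorTrace(subject, sensor, np.arange(len(r)) * dt, r, protocol)


def brute_force_cycle(resist, times, lo, hi):
    """Independent plain-loop search: A = first global minimum of the cycle,
    B = first maximum at or before A. Returns (min, gap, t, sl)."""
    a = lo
    for j in range(lo, hi):
        if resist[j] < resist[a]:
            a = j
    b = lo
    for i in range(lo, a + 1):
        if resist[i] > resist[b]:
            b = i
    gap = resist[b] - resist[a]
    t = times[a] - times[b]
    sl = gap / t if t > 0 else 0.0
    return resist[a], gap, t, sl


def two_class_config(mu_cancer, mu_control, sd, n=32, seed=0, noise_sd=5.0,
                     n_cycles=5):
    """Single-sensor config whose every cycle has the given gap separation."""
    gm = {CANCER: [[mu_cancer] * n_cycles], NON_CANCER: [[mu_control] * n_cycles]}
    gs = {CANCER: [[sd] * n_cycles], NON_CANCER: [[sd] * n_cycles]}
    return SyntheticConfig(
        n_cancer=n, n_noncancer=n, n_sensors=1,
        gap_mean=gm, gap_sd=gs, noise_sd=noise_sd, seed=seed,
    )
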