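"""Synthetic MOS gas-sensor cohort generator.

Emulates the resistance response of an n-type metal-oxide-semiconductor
(MOS) sensor array sampling urine headspace under a stepped heater-voltage
protocol.  Each heater step ("cycle") produces a characteristic transient:
the resistance drops from a pre-step baseline to a minimum as reducing VOCs
release free electrons at the hot oxide surface, then partially recovers.
The generator draws per-cycle drop amplitudes from class-conditional normal
distributions so that downstream feature extraction and diagnostics can be
exercised against a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HeaterProtocol",
    "SyntheticConfig",
    "SensorTrace",
    "CohortLabels",
    "default_config",
    "generate_trace",
    "generate_cohort",
    "theoretical_feature_auc",
]

CANCER = "cancer"
NON_CANCER = "non_cancer"
CLASSES = (CANCER, NON_CANCER)

# Exponential-decay sharpness: the drop reaches its drawn minimum after
# DECAY_E_FOLDS time constants (residual exp(-5) < 1%); the decay is
# normalised so the sampled minimum equals baseline - gap exactly at the
# drawn fall time.
DECAY_E_FOLDS = 5.0


@dataclass(frozen=True)
class HeaterProtocol:
    """Heater-voltage step schedule defining the analysis cycles.

    Parameters
    ----------
    voltage_levels_mv : tuple of float
        Ordered heater voltages in millivolts; one resistance cycle per level.
    cycle_duration_s : float
        Seconds each voltage is held.
    sampling_interval_s : float
        Seconds between resistance samples (>= 10 samples per cycle).
    """

    voltage_levels_mv: tuple[float, ...] = (2000.0, 2500.0, 3500.0, 4500.0, 5000.0)
    cycle_duration_s: float = 80.0
    sampling_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if len(self.voltage_levels_mv) == 0:
            raise ValueError("voltage_levels_mv must be non-empty")
        if any(v <= 0 for v in self.voltage_levels_mv):
            raise ValueError("voltage_levels_mv must be strictly positive")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be > 0")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be > 0")
        if self.sampling_interval_s > self.cycle_duration_s / 10:
            raise ValueError(
                "sampling_interval_s must allow >= 10 samples per cycle"
            )

    @property
    def n_cycles(self) -> int:
        return len(self.voltage_levels_mv)

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_duration_s / self.sampling_interval_s))

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_duration_s


def _as_class_array(values, n_sensors: int, n_cycles: int, name: str) -> dict:
    """Coerce {class: array-like (n_sensors, n_cycles)} or scalar to arrays."""
    out = {}
    for cls in CLASSES:
        if isinstance(values, dict):
            v = values[cls]
        else:
            v = values
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            arr = np.full((n_sensors, n_cycles), float(arr))
        if arr.shape != (n_sensors, n_cycles):
            raise ValueError(
                f"{name}[{cls}] must have shape ({n_sensors}, {n_cycles}), "
                f"got {arr.shape}"
            )
        out[cls] = arr
    return out


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``gap_mean`` / ``gap_sd`` are either scalars or mappings
    ``{class: (n_sensors, n_cycles) array}`` of drop-amplitude normal
    parameters in ohms; drops are truncated at zero.  Baselines are
    log-normal (mean/sd given on the ohm scale); fall times are normal,
    truncated to (2 * sampling interval, cycle duration / 2).
    """

    n_cancer: int = 32
    n_noncancer: int = 32
    n_sensors: int = 5
    baseline_resistance_mean: float = 20000.0
    baseline_resistance_sd: float = 1500.0
    gap_mean: dict | float = 500.0
    gap_sd: dict | float = 80.0
    fall_time_mean: float = 15.0
    fall_time_sd: float = 2.0
    recovery_fraction: float = 0.85
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self, protocol: HeaterProtocol) -> None:
        """Validate counts, spreads, and resistance positivity.

        Positivity is checked conservatively: the 4-sigma-low baseline must
        exceed the worst-case cumulative drop (largest single drop plus the
        unrecovered residue of every cycle, plus a 6-sigma noise margin).
        """
        if self.n_cancer < 1 or self.n_noncancer < 1:
            raise ValueError("n_cancer and n_noncancer must be >= 1")
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        for name in ("baseline_resistance_sd", "fall_time_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_resistance_mean <= 0:
            raise ValueError("baseline_resistance_mean must be > 0")
        if not (0.0 <= self.recovery_fraction <= 1.0):
            raise ValueError("recovery_fraction must be in [0, 1]")
        if self.fall_time_mean >= protocol.cycle_duration_s:
            raise ValueError("fall_time_mean must be < cycle_duration_s")
        gm = self.gap_means(protocol)
        gs = self.gap_sds(protocol)
        if any((gm[c] < 0).any() for c in CLASSES):
            raise ValueError("gap_mean must be >= 0")
        if any((gs[c] < 0).any() for c in CLASSES):
            raise ValueError("gap_sd must be >= 0")
        floor = self.baseline_resistance_mean - 4.0 * self.baseline_resistance_sd
        worst = 0.0
        for cls in CLASSES:
            hi = gm[cls] + 4.0 * gs[cls]  # per sensor x cycle
            residue = (1.0 - self.recovery_fraction) * hi.sum(axis=1)
            drop = residue + hi.max(axis=1)
            worst = max(worst, float(drop.max()))
        if floor - worst - 6.0 * self.noise_sd <= 0.0:
            raise ValueError(
                "configuration forces non-positive resistance: "
                "baseline_resistance_mean too small for gap_mean/gap_sd/noise_sd"
            )

    def gap_means(self, protocol: HeaterProtocol) -> dict:
        return _as_class_array(
            self.gap_mean, self.n_sensors, protocol.n_cycles, "gap_mean"
        )

    def gap_sds(self, protocol: HeaterProtocol) -> dict:
        return _as_class_array(
            self.gap_sd, self.n_sensors, protocol.n_cycles, "gap_sd"
        )


@dataclass
class SensorTrace:
    """One subject x sensor resistance time series."""

    subject_id: str
    sensor_index: int  # 1-based, matching the "S2" feature-name convention
    times: np.ndarray  # seconds, strictly increasing from 0
    resistances: np.ndarray  # ohms, strictly positive
    protocol: HeaterProtocol = field(default_factory=HeaterProtocol)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistances = np.asarray(self.resistances, dtype=float)
        if self.times.shape != self.resistances.shape:
            raise ValueError("times and resistances must have the same length")
        if len(self.times) and self.times[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class CohortLabels:
    """subject_id -> class (cancer / non_cancer), optional finer subclass.

    Subclasses ``other_disease`` and ``normal`` both map to class
    ``non_cancer`` (the combined control group used for binary analysis).
    """

    classes: dict[str, str]
    subclasses: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for sid, cls in self.classes.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r} for subject {sid!r}")
        if self.subclasses is not None:
            for sid, sub in self.subclasses.items():
                if sub not in ("cancer", "other_disease", "normal"):
                    raise ValueError(f"unknown subclass {sub!r}")
                expected = CANCER if sub == "cancer" else NON_CANCER
                if self.classes.get(sid) != expected:
                    raise ValueError(
                        f"subclass {sub!r} inconsistent with class for {sid!r}"
                    )

    def is_cancer(self, subject_id: str) -> bool:
        return self.classes[subject_id] == CANCER


def default_config(**overrides) -> SyntheticConfig:
    """Study-scale default configuration: 32 + 32 subjects, 5 sensors.

    The class effect is concentrated in sensor 2, cycles 1 and 4: the
    drop-amplitude distributions are binormal with population AUC 0.64
    (cycle 1, optimal cut-off 30 ohm) and 0.67 (cycle 4, optimal cut-off
    862 ohm); every other sensor x cycle has no class separation.

    ``n_sensors`` / ``n_cycles`` overrides resize the gap arrays (the
    sensor-2 effects are kept whenever they still fit).
    """
    n_sensors = int(overrides.pop("n_sensors", 5))
    n_cycles = int(overrides.pop("n_cycles", 5))
    base_mean = np.full((n_sensors, n_cycles), 500.0)
    base_sd = np.full((n_sensors, n_cycles), 80.0)
    gm = {CANCER: base_mean.copy(), NON_CANCER: base_mean.copy()}
    gs = {CANCER: base_sd.copy(), NON_CANCER: base_sd.copy()}
    if n_sensors >= 2:
        # sensor 2 (index 1), cycle 1: AUC 0.64, Youden cut-off 30 ohm
        gm[CANCER][1, 0], gm[NON_CANCER][1, 0] = 32.5, 27.5
        gs[CANCER][1, 0] = gs[NON_CANCER][1, 0] = 10.0
        if n_cycles >= 4:
            # sensor 2, cycle 4: AUC 0.67, Youden cut-off 862 ohm
            gm[CANCER][1, 3], gm[NON_CANCER][1, 3] = 908.7, 815.3
            gs[CANCER][1, 3] = gs[NON_CANCER][1, 3] = 150.0
    cfg = SyntheticConfig(gap_mean=gm, gap_sd=gs, n_sensors=n_sensors)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _truncnorm_draw(rng, mean: float, sd: float, low: float, high: float) -> float:
    """Inverse-CDF truncated-normal draw consuming exactly one uniform."""
    u = rng.uniform()
    if sd == 0.0:
        return float(min(max(mean, low), high))
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def _lognormal_draw(rng, mean: float, sd: float) -> float:
    """Log-normal draw parameterised by the distribution's own mean/sd."""
    if sd == 0.0:
        return float(mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(math.exp(mu + math.sqrt(sigma2) * rng.standard_normal()))


def generate_trace(
    subject_id: str,
    sensor_index: int,
    class_label: str,
    config: SyntheticConfig,
    protocol: HeaterProtocol,
    rng: np.random.Generator,
    params_out: dict | None = None,
) -> SensorTrace:
    """Generate one sensor's resistance trace for one subject.

    Per cycle the clean signal falls from the cycle-start value along a
    normalised exponential to (start - gap) at the drawn fall time, then
    recovers linearly to (start - (1 - recovery_fraction) * gap) by cycle
    end; the next cycle starts where the previous ended (no reset).
    Additive white noise is applied last, and samples are clipped positive.

    If ``params_out`` is given, the drawn per-cycle ``gap``, ``fall_time``
    and ``start`` values are recorded under those keys (ground truth for
    recovery tests).
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    config.validate(protocol)
    gm = config.gap_means(protocol)[class_label][sensor_index - 1]
    gs = config.gap_sds(protocol)[class_label][sensor_index - 1]
    dt = protocol.sampling_interval_s
    d = protocol.cycle_duration_s
    spc = protocol.samples_per_cycle

    gaps, falls, starts = [], [], []
    segments = []
    start = _lognormal_draw(
        rng, config.baseline_resistance_mean, config.baseline_resistance_sd
    )
    for k in range(protocol.n_cycles):
        gap = _truncnorm_draw(rng, gm[k], gs[k], 0.0, np.inf)
        fall = _truncnorm_draw(
            rng, config.fall_time_mean, config.fall_time_sd, 2.0 * dt, d / 2.0
        )
        tau = np.arange(spc) * dt  # within-cycle sample offsets
        theta = fall / DECAY_E_FOLDS
        norm = -math.expm1(-fall / theta)  # 1 - exp(-F/theta)
        seg = np.empty(spc)
        falling = tau <= fall
        seg[falling] = start - gap * (-np.expm1(-tau[falling] / theta)) / norm
        end_val = start - (1.0 - config.recovery_fraction) * gap
        rec = ~falling
        seg[rec] = (start - gap) + (end_val - (start - gap)) * (
            (tau[rec] - fall) / (d - fall)
        )
        segments.append(seg)
        gaps.append(gap)
        falls.append(fall)
        starts.append(start)
        start = end_val

    clean = np.concatenate(segments)
    if config.noise_sd > 0:
        clean = clean + rng.normal(0.0, config.noise_sd, size=clean.size)
    resist = np.maximum(clean, 1e-6)
    times = np.arange(clean.size) * dt
    if params_out is not None:
        params_out["gap"] = np.array(gaps)
        params_out["fall_time"] = np.array(falls)
        params_out["start"] = np.array(starts)
    return SensorTrace(subject_id, sensor_index, times, resist, protocol)


def generate_cohort(
    config: SyntheticConfig,
    protocol: HeaterProtocol | None = None,
    params_out: dict | None = None,
) -> tuple[list[SensorTrace], CohortLabels]:
    """Generate a full labelled cohort of traces.

    Subjects are generated cancer-first (ids C001.., N001..); each subject
    draws from its own rng substream keyed by (seed, subject index), so a
    subject's traces do not depend on cohort ordering.
    """
    if protocol is None:
        protocol = HeaterProtocol()
    config.validate(protocol)
    traces: list[SensorTrace] = []
    classes: dict[str, str] = {}
    n_total = config.n_cancer + config.n_noncancer
    for idx in range(n_total):
        if idx < config.n_cancer:
            sid, cls = f"C{idx + 1:03d}", CANCER
        else:
            sid, cls = f"N{idx - config.n_cancer + 1:03d}", NON_CANCER
        classes[sid] = cls
        rng = np.random.default_rng([config.seed, idx])
        for s in range(1, config.n_sensors + 1):
            po = {} if params_out is not None else None
            traces.append(
                generate_trace(sid, s, cls, config, protocol, rng, params_out=po)
            )
            if params_out is not None:
                params_out[(sid, s)] = po
    return traces, CohortLabels(classes)


def theoretical_feature_auc(
    config: SyntheticConfig,
    sensor_index: int,
    cycle_index: int,
    protocol: HeaterProtocol | None = None,
) -> float:
    """Binormal AUC of the gap feature for one sensor x cycle.

    Returns Phi(dmu / sqrt(sd_cancer^2 + sd_noncancer^2 + 2 * sigma_eff^2))
    where sigma_eff is the feature-extraction noise floor.  The extracted
    gap is a difference of two sampled resistances, so each endpoint
    contributes one noise_sd of measurement noise: sigma_eff = noise_sd
    (zero when noise_sd = 0).  Gap truncation at zero is ignored, so the
    value is exact only when the class means sit well above zero.
    """
    def pick(value, cls):
        v = value[cls] if isinstance(value, dict) else value
        arr = np.atleast_2d(np.asarray(v, dtype=float))
        if arr.size == 1:
            return float(arr.ravel()[0])
        return float(arr[sensor_index - 1, cycle_index - 1])

    dmu = pick(config.gap_mean, CANCER) - pick(config.gap_mean, NON_CANCER)
    sd_c = pick(config.gap_sd, CANCER)
    sd_n = pick(config.gap_sd, NON_CANCER)
    var = sd_c**2 + sd_n**2 + 2.0 * config.noise_sd**2
    if var == 0.0:
        if dmu == 0.0:
            return 0.5
        return 1.0 if dmu > 0 else 0.0
    return float(stats.norm.cdf(dmu / math.sqrt(var)))
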