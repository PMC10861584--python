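"""Per-cycle transient feature extraction for MOS sensor traces.

Each heater cycle yields four parameters of the resistance transient:

- ``min``: the minimum resistance in the cycle (point A);
- ``gap``: the drop from the pre-minimum maximum (point B, the within-cycle
  maximum at or before A) down to A, in ohms;
- ``t``: the elapsed time from B to A, in seconds;
- ``SL``: the drop slope gap / t in ohm/s (0 when t = 0).

Features are named ``{param}{cycle}S{sensor}`` (e.g. ``gap1S2`` = gap,
cycle 1, sensor 2) and assembled into a subjects x features table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SensorTrace

__all__ = [
    "CycleFeatures",
    "segment_cycles",
    "extract_cycle_features",
    "build_feature_table",
    "feature_name",
    "parse_feature_name",
    "canonical_feature_names",
]

logger = logging.getLogger(__name__)

PARAMS = ("min", "gap", "t", "SL")
_NAME_RE = re.compile(r"^(min|gap|t|sl)(\d+)s(\d+)$", re.IGNORECASE)


@dataclass
class CycleFeatures:
    """Per-cycle features of one trace (arrays indexed by cycle, 0-based)."""

    min_ohm: np.ndarray
    gap_ohm: np.ndarray
    t_s: np.ndarray
    sl_ohm_per_s: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.min_ohm)


def feature_name(param: str, cycle: int, sensor: int) -> str:
    if param not in PARAMS:
        raise ValueError(f"unknown parameter {param!r}, expected one of {PARAMS}")
    return f"{param}{cycle}S{sensor}"


def parse_feature_name(name: str) -> tuple[str, int, int]:
    """Parse e.g. 'gap1S2' -> ('gap', 1, 2). Case-insensitive on input."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a feature name: {name!r}")
    param = m.group(1).lower()
    param = "SL" if param == "sl" else param
    return param, int(m.group(2)), int(m.group(3))


def canonical_feature_names(n_sensors: int = 5, n_cycles: int = 5) -> list[str]:
    """Sensor-major, cycle-minor, param order (min, gap, t, SL)."""
    return [
        feature_name(p, c, s)
        for s in range(1, n_sensors + 1)
        for c in range(1, n_cycles + 1)
        for p in PARAMS
    ]


def segment_cycles(trace: SensorTrace) -> list[tuple[int, tuple[int, int]]]:
    """Split a trace into per-cycle half-open sample ranges.

    Cycle k (1-based) covers times [(k-1)*D, k*D) with D the cycle
    duration; only complete cycles are returned, capped at the protocol's
    cycle count.  A trailing partial cycle is discarded with a warning.
    """
    proto = trace.protocol
    d = proto.cycle_duration_s
    spc = proto.samples_per_cycle
    n = len(trace.times)
    ranges = []
    k = 0
    while k < proto.n_cycles:
        lo = int(np.searchsorted(trace.times, k * d, side="left"))
        hi = int(np.searchsorted(trace.times, (k + 1) * d, side="left"))
        if hi - lo < spc:
            break
        ranges.append((k + 1, (lo, hi)))
        k += 1
    if not ranges:
        raise ValueError(
            f"trace {trace.subject_id!r} S{trace.sensor_index} is shorter than "
            f"one full cycle ({n} samples, {spc} needed)"
        )
    used = ranges[-1][1][1]
    if used < n:
        logger.warning(
            "trace %s S%d: %d trailing samples beyond cycle %d discarded",
            trace.subject_id, trace.sensor_index, n - used, ranges[-1][0],
        )
    return ranges


def extract_cycle_features(trace: SensorTrace) -> CycleFeatures:
    """Compute (min, gap, t, SL) for every complete cycle of a trace.

    A is the cycle minimum (first occurrence on ties); B is the maximum at
    or before A within the cycle (first occurrence on ties).
    """
    r = trace.resistances
    bad = ~np.isfinite(r) | (r <= 0)
    if bad.any():
        idx = int(np.argmax(bad))
        raise ValueError(
            f"non-positive or non-finite resistance at sample {idx} "
            f"(value {r[idx]!r})"
        )
    ranges = segment_cycles(trace)
    mins, gaps, ts, sls = [], [], [], []
    for _, (lo, hi) in ranges:
        seg = r[lo:hi]
        a_rel = int(np.argmin(seg))  # first occurrence
        b_rel = int(np.argmax(seg[: a_rel + 1]))  # first occurrence, at/before A
        a, b = seg[a_rel], seg[b_rel]
        t = trace.times[lo + a_rel] - trace.times[lo + b_rel]
        mins.append(a)
        gaps.append(b - a)
        ts.append(t)
        sls.append((b - a) / t if t > 0 else 0.0)
    return CycleFeatures(
        np.array(mins), np.array(gaps), np.array(ts), np.array(sls)
    )


def build_feature_table(traces: list[SensorTrace]) -> pd.DataFrame:
    """Assemble the subjects x named-features table from a set of traces.

    With 5 sensors and 5 cycles this is the canonical 100-column table.
    Subjects missing a sensor get NaN in that sensor's columns; duplicate
    (subject, sensor) traces are an error.
    """
    if not traces:
        raise ValueError("no traces given")
    n_sensors = max(t.sensor_index for t in traces)
    n_cycles = max(t.protocol.n_cycles for t in traces)
    columns = canonical_feature_names(n_sensors, n_cycles)
    rows: dict[str, dict[str, float]] = {}
    seen: set[tuple[str, int]] = set()
    order: list[str] = []
    for tr in traces:
        key = (tr.subject_id, tr.sensor_index)
        if key in seen:
            raise ValueError(
                f"duplicate trace for subject {tr.subject_id!r} "
                f"sensor {tr.sensor_index}"
            )
        seen.add(key)
        if tr.subject_id not in rows:
            rows[tr.subject_id] = {}
            order.append(tr.subject_id)
        feats = extract_cycle_features(tr)
        row = rows[tr.subject_id]
        for c in range(feats.n_cycles):
            row[feature_name("min", c + 1, tr.sensor_index)] = feats.min_ohm[c]
            row[feature_name("gap", c + 1, tr.sensor_index)] = feats.gap_ohm[c]
            row[feature_name("t", c + 1, tr.sensor_index)] = feats.t_s[c]
            row[feature_name("SL", c + 1, tr.sensor_index)] = feats.sl_ohm_per_s[c]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=order, columns=columns
    )
    df.index.name = "subject_id"
    return df
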