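"""CSV readers/writers for traces, labels, features and configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    CohortLabels,
    HeaterProtocol,
    SensorTrace,
    SyntheticConfig,
    default_config,
)

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_feature_table_csv",
    "read_feature_table_csv",
    "protocol_from_mapping",
    "synthetic_config_from_mapping",
    "load_yaml",
]

TRACE_COLUMNS = ["subject_id", "sensor_index", "time_s", "resistance_ohm"]


def write_traces_csv(traces: list[SensorTrace], path) -> None:
    """Long-format trace table: subject_id,sensor_index,time_s,resistance_ohm."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": tr.subject_id,
                "sensor_index": tr.sensor_index,
                "time_s": tr.times,
                "resistance_ohm": tr.resistances,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, protocol: HeaterProtocol | None = None) -> list[SensorTrace]:
    if protocol is None:
        protocol = HeaterProtocol()
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    traces = []
    for (sid, sensor), grp in df.groupby(["subject_id", "sensor_index"], sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            SensorTrace(
                subject_id=str(sid),
                sensor_index=int(sensor),
                times=grp["time_s"].to_numpy(dtype=float),
                resistances=grp["resistance_ohm"].to_numpy(dtype=float),
                protocol=protocol,
            )
        )
    return traces


def write_labels_csv(labels: CohortLabels, path) -> None:
    rows = {"subject_id": list(labels.classes), "class": list(labels.classes.values())}
    if labels.subclasses is not None:
        rows["subclass"] = [labels.subclasses[s] for s in labels.classes]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path) -> CohortLabels:
    df = pd.read_csv(path)
    for col in ("subject_id", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    classes = dict(zip(df["subject_id"].astype(str), df["class"]))
    subclasses = None
    if "subclass" in df.columns:
        subclasses = dict(zip(df["subject_id"].astype(str), df["subclass"]))
    return CohortLabels(classes, subclasses)


def write_feature_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True, float_format="%.10g")


def read_feature_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id").astype(float)


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def protocol_from_mapping(m: dict | None) -> HeaterProtocol:
    if not m:
        return HeaterProtocol()
    kwargs = {}
    if "voltage_levels_mv" in m:
        kwargs["voltage_levels_mv"] = tuple(float(v) for v in m["voltage_levels_mv"])
    for key in ("cycle_duration_s", "sampling_interval_s"):
        if key in m:
            kwargs[key] = float(m[key])
    return HeaterProtocol(**kwargs)


def synthetic_config_from_mapping(m: dict | None) -> SyntheticConfig:
    """Build a SyntheticConfig from a flat mapping; unset keys keep the
    class-separated cohort defaults."""
    cfg = default_config()
    if not m:
        return cfg
    scalar_keys = (
        "n_cancer", "n_noncancer", "n_sensors",
        "baseline_resistance_mean", "baseline_resistance_sd",
        "fall_time_mean", "fall_time_sd", "recovery_fraction",
        "noise_sd", "seed",
    )
    for key in scalar_keys:
        if key in m:
            cast = int if key in ("n_cancer", "n_noncancer", "n_sensors", "seed") else float
            setattr(cfg, key, cast(m[key]))
    for key in ("gap_mean", "gap_sd"):
        if key in m:
            v = m[key]
            if isinstance(v, dict):
                setattr(cfg, key, {c: np.asarray(a, dtype=float) for c, a in v.items()})
            else:
                setattr(cfg, key, float(v))
    return cfg
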