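"""Subject CSV and report JSON formats.

A subject lives in one delimited text file: column ``sample`` (integer
index), ten EMG channel columns in the fixed order R_TA...L_RF, and two
binary foot-switch columns ``FSW_R``/``FSW_L`` (0 = stance, 1 = swing).
True gait events, when available, sit in a companion CSV with columns
``leg,type,time_ms``.  Reports serialize to JSON with a schema-version
field; missing metrics stay ``null``, never 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventSeries
from .exceptions import DataFormatError
from .synthdata import CHANNEL_NAMES, SubjectRecording

SCHEMA_VERSION = 1

_FSW_COLUMNS = {"right": "FSW_R", "left": "FSW_L"}


def write_subject(
    rec: SubjectRecording, data_path, events_path=None
) -> None:
    """Write a subject recording (and optionally its true events) as CSV."""
    frame = pd.DataFrame({"sample": np.arange(rec.n_samples)})
    for i, name in enumerate(CHANNEL_NAMES):
        frame[name] = rec.channels[i]
    for leg, col in _FSW_COLUMNS.items():
        frame[col] = rec.basographic[leg]
    frame.to_csv(data_path, index=False)
    if events_path is not None and rec.truth_events:
        rows = []
        for leg, series in rec.truth_events.items():
            for t, typ in zip(series.times_ms, series.types):
                rows.append({"leg": leg, "type": typ, "time_ms": t})
        pd.DataFrame(rows, columns=["leg", "type", "time_ms"]).to_csv(
            events_path, index=False
        )


def read_subject(
    data_path, events_path=None, sampling_rate: float = 2000.0
) -> SubjectRecording:
    """Read a subject CSV back into a recording, validating the format."""
    data_path = Path(data_path)
    frame = pd.read_csv(data_path)
    missing = [
        c
        for c in (*CHANNEL_NAMES, *_FSW_COLUMNS.values())
        if c not in frame.columns
    ]
    if missing:
        raise DataFormatError(
            f"{data_path.name}: missing columns {missing}"
        )
    baso = {}
    for leg, col in _FSW_COLUMNS.items():
        values = frame[col].to_numpy()
        bad = np.flatnonzero(~np.isin(values, (0, 1)))
        if bad.size:
            # +2: header line and 1-based file line numbering
            raise DataFormatError(
                f"{data_path.name}: non-binary {col} value "
                f"{values[bad[0]]!r} at line {bad[0] + 2}"
            )
        baso[leg] = values.astype(np.uint8)
    channels = frame[list(CHANNEL_NAMES)].to_numpy().T
    truth = None
    if events_path is not None and Path(events_path).exists():
        truth = _read_events(events_path, sampling_rate)
    return SubjectRecording(
        subject_id=data_path.stem,
        sampling_rate=sampling_rate,
        channels=channels,
        basographic=baso,
        truth_events=truth,
    )


def _read_events(path, sampling_rate: float) -> dict[str, EventSeries]:
    frame = pd.read_csv(path)
    for col in ("leg", "type", "time_ms"):
        if col not in frame.columns:
            raise DataFormatError(f"{Path(path).name}: missing column {col}")
    out = {}
    for leg, grp in frame.groupby("leg", sort=False):
        grp = grp.sort_values("time_ms")
        times = np.round(
            grp["time_ms"].to_numpy() * sampling_rate / 1000.0
        ).astype(np.int64)
        out[str(leg)] = EventSeries(
            leg=str(leg),
            times=times,
            types=list(grp["type"]),
            sampling_rate=sampling_rate,
        )
    return out


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonify(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report, path) -> None:
    """Serialize a report dataclass to JSON (schema-versioned)."""
    payload = {"schema_version": SCHEMA_VERSION, "report": _jsonify(report)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_report(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if "schema_version" not in payload:
        raise DataFormatError(f"{Path(path).name}: missing schema_version")
    return payload["report"]
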