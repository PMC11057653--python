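"""Delimited-text readers and writers for nights and instance tables.

Three per-night files mirror what a device export looks like:

* hypnogram: ``timestamp,stage``
* signals:   ``timestamp,hr,steps``
* records:   ``timestamp,interval_s,stage,cycle_type`` — one row per
  interval, the shape of the raw Short/Long duplicate table.

Instance tables are written as CSV plus a small JSON sidecar recording the
schema name and epoch interval.  Timestamps are ISO-8601 throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .records import EpochTable, SleepRecord
from .synthetic import SyntheticNight


def write_hypnogram(table: EpochTable, path: str | Path) -> None:
    df = table.frame.reset_index().rename(columns={"index": "timestamp"})
    df.to_csv(path, index=False)


def read_hypnogram(path: str | Path, interval: int | None = None) -> EpochTable:
    df = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    if interval is None:
        interval = int((df.index[1] - df.index[0]).total_seconds())
    return EpochTable(df, interval)


def write_signals(night: SyntheticNight, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": night.heart_rate.timestamps,
            "hr": night.heart_rate.frame["hr"].to_numpy(),
            "steps": night.steps.frame["steps"].to_numpy(),
        }
    )
    df.to_csv(path, index=False)


def read_signals(path: str | Path, interval: int | None = None) -> EpochTable:
    df = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    if interval is None:
        interval = int((df.index[1] - df.index[0]).total_seconds())
    return EpochTable(df, interval)


def write_records(records: list[SleepRecord], path: str | Path) -> None:
    """Write records expanded to one row per native interval."""
    rows = []
    for r in records:
        n = r.duration // r.interval
        for k in range(n):
            rows.append(
                {
                    "timestamp": (r.start + pd.Timedelta(seconds=k * r.interval)).isoformat(),
                    "interval_s": r.interval,
                    "stage": r.stage,
                    "cycle_type": r.cycle_type,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records(path: str | Path) -> list[SleepRecord]:
    """Read per-interval rows back as unit-duration records."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return [
        SleepRecord(
            start=row.timestamp,
            duration=int(row.interval_s),
            stage=row.stage,
            cycle_type=row.cycle_type,
            interval=int(row.interval_s) if int(row.interval_s) in (15, 30, 60) else 30,
        )
        for row in df.itertuples()
    ]


def write_instance(table: EpochTable, path: str | Path) -> None:
    path = Path(path)
    df = table.frame.reset_index().rename(columns={"index": "timestamp"})
    df.to_csv(path, index=False)
    sidecar = {"schema_id": table.schema_id, "interval": table.interval}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_instance(path: str | Path) -> EpochTable:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    return EpochTable(df, meta["interval"], meta.get("schema_id"))
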