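"""Sliding-window sequence construction.

Memory-based models consume, for each epoch i, the feature rows of epochs
i−ns … i together with the stage label of epoch i.  Windows never span a
timestamp gap or a night/subject boundary, so a contiguous segment of N
rows yields N − ns sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .records import EpochTable

GROUP_COLS = ("subject", "night_id")


@dataclass
class WindowedDataset:
    """Fixed-length history sequences with terminal-row stage labels."""

    ns: int
    X: np.ndarray            # (n_sequences, ns+1, n_features)
    y: np.ndarray            # (n_sequences,) stage labels
    feature_names: list[str]
    groups: np.ndarray | None = None  # per-sequence group id (subject/night)

    def __post_init__(self) -> None:
        if self.X.ndim != 3 or self.X.shape[1] != self.ns + 1:
            raise ValueError(
                f"X must be (n, ns+1={self.ns + 1}, F), got {self.X.shape}"
            )
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[2]


def make_windows(
    table: EpochTable,
    ns: int,
    *,
    feature_cols: list[str] | None = None,
    label_col: str = "stage",
) -> WindowedDataset:
    """Regenerate a feature table into ns-history sequences.

    ``feature_cols`` defaults to every numeric column except the label and
    grouping columns.  The table is split into contiguous segments at
    timestamp gaps and at changes of the grouping columns present
    (``subject``, ``night_id``); windows are built per segment.
    """
    frame = table.frame
    n = len(frame)
    if not 0 <= ns < n:
        raise ValueError(f"ns={ns} out of range for a {n}-row table")
    if label_col not in frame.columns:
        raise ValueError(f"label column {label_col!r} missing")
    if feature_cols is None:
        feature_cols = [
            c
            for c in frame.columns
            if c != label_col and c not in GROUP_COLS
            and pd.api.types.is_numeric_dtype(frame[c])
        ]
    group_cols = [c for c in GROUP_COLS if c in frame.columns]

    # segment boundaries: timestamp gaps or group changes
    gap = np.zeros(n, dtype=bool)
    deltas = np.diff(frame.index.asi8) / 1e9
    gap[1:] = deltas != table.interval
    for c in group_cols:
        v = frame[c].to_numpy()
        gap[1:] |= v[1:] != v[:-1]
    seg_ids = np.cumsum(gap)

    feats = frame[feature_cols].to_numpy(dtype=float)
    labels = frame[label_col].to_numpy()
    grp = frame[group_cols[0]].to_numpy() if group_cols else None

    xs, ys, gs = [], [], []
    for s in np.unique(seg_ids):
        sel = np.flatnonzero(seg_ids == s)
        if len(sel) < ns + 1:
            continue
        block = feats[sel]
        win = sliding_window_view(block, ns + 1, axis=0)  # (m, F, ns+1)
        xs.append(np.ascontiguousarray(win.transpose(0, 2, 1)))
        ys.append(labels[sel[ns:]])
        if grp is not None:
            gs.append(grp[sel[ns:]])
    if not xs:
        raise ValueError(f"no contiguous segment has at least ns+1={ns + 1} rows")
    return WindowedDataset(
        ns=ns,
        X=np.concatenate(xs),
        y=np.concatenate(ys),
        feature_names=list(feature_cols),
        groups=np.concatenate(gs) if gs else None,
    )


def flatten_windows(ds: WindowedDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Concatenate each sequence row-major into one vector per sample.

    Column names are suffixed by lag: ``hr_lag2`` is the value two epochs
    before the labelled epoch, ``hr_lag0`` the labelled epoch itself.
    """
    n, steps, f = ds.X.shape
    flat = ds.X.reshape(n, steps * f)
    names = [
        f"{name}_lag{ds.ns - k}" for k in range(steps) for name in ds.feature_names
    ]
    return flat, ds.y, names


def unflatten_windows(
    flat: np.ndarray, y: np.ndarray, ns: int, feature_names: list[str]
) -> WindowedDataset:
    """Inverse of :func:`flatten_windows`."""
    f = len(feature_names)
    X = np.asarray(flat, float).reshape(len(flat), ns + 1, f)
    return WindowedDataset(ns=ns, X=X, y=np.asarray(y), feature_names=list(feature_names))


def save_windows(ds: WindowedDataset, path: str | Path) -> None:
    """Serialize as delimited text plus a JSON sidecar (binary-free)."""
    path = Path(path)
    flat, y, names = flatten_windows(ds)
    df = pd.DataFrame(flat, columns=names)
    df["stage"] = y
    df.to_csv(path, index=False)
    sidecar = {"ns": ds.ns, "n_features": ds.n_features, "feature_names": ds.feature_names}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_windows(path: str | Path) -> WindowedDataset:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path)
    y = df.pop("stage").to_numpy()
    return unflatten_windows(df.to_numpy(), y, meta["ns"], meta["feature_names"])
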