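"""Sensor-stream I/O for trackball recordings.

A trackball assay records the rotation of an air-suspended ball with two
optical mouse sensors mounted at 90 degrees. Each sensor logs a timestamped
stream of x/y readings in *dots* (the sensor's native displacement unit,
converted to cm downstream via a calibration constant). This module reads and
validates those per-sensor CSV files, aligns the two streams of a trial, and
merges them into a single 2-D displacement series — the increments of the
animal's *fictive path*. It also reads trial manifests and reads/writes tidy
per-trial metric tables.

Two CSV dialects are supported and must be declared explicitly:

``cumulative``
    each row holds the running position in dots (increments are first
    differences);
``delta``
    each row holds the per-frame displacement in dots.

Which physical ball axis each sensor channel measures is configurable through
an :class:`AxisMap`; the shipped default routes sensor A's x channel to the
forward (y) component of the fictive path and sensor B's x channel to the
lateral (x) component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InputDataError

DIALECTS = ("cumulative", "delta")

#: Column order of the tidy metrics table written by :func:`write_metrics_table`.
METRIC_COLUMNS = (
    "individual_id",
    "trial_number",
    "total_distance",
    "translational_velocity",
    "total_rotation",
    "rotational_velocity",
    "sinuosity",
    "straightness",
    "n_samples",
    "duration_s",
    "n_moving",
    "flags",
)


@dataclass(frozen=True)
class AxisMap:
    """Routing of sensor channels to fictive-path components.

    Each entry is ``(stream, axis, sign)`` where *stream* is ``"a"`` or
    ``"b"``, *axis* is ``"x"`` or ``"y"`` and *sign* is ±1. ``forward`` feeds
    the path's y component, ``lateral`` its x component (right-handed lab
    frame, headings counter-clockwise from +x).
    """

    forward: tuple[str, str, int] = ("a", "x", 1)
    lateral: tuple[str, str, int] = ("b", "x", 1)

    @classmethod
    def from_spec(cls, spec: dict) -> "AxisMap":
        """Build from a config mapping like ``{"forward": "a.x", "lateral": "-b.x"}``."""

        def parse(text: str) -> tuple[str, str, int]:
            text = text.strip()
            sign = 1
            if text.startswith("-"):
                sign, text = -1, text[1:]
            elif text.startswith("+"):
                text = text[1:]
            try:
                stream, axis = text.split(".")
            except ValueError:
                raise InputDataError(
                    f"axis map entry {text!r} is not of the form 'a.x' / '-b.y'"
                ) from None
            if stream not in ("a", "b") or axis not in ("x", "y"):
                raise InputDataError(f"axis map entry {text!r}: stream must be a/b, axis x/y")
            return (stream, axis, sign)

        missing = {"forward", "lateral"} - set(spec)
        if missing:
            raise InputDataError(f"axis map missing entries: {sorted(missing)}")
        return cls(forward=parse(spec["forward"]), lateral=parse(spec["lateral"]))

    def to_spec(self) -> dict:
        def fmt(entry: tuple[str, str, int]) -> str:
            stream, axis, sign = entry
            return f"{'-' if sign < 0 else ''}{stream}.{axis}"

        return {"forward": fmt(self.forward), "lateral": fmt(self.lateral)}


DEFAULT_AXIS_MAP = AxisMap()


@dataclass
class SensorStream:
    """One optical sensor's validated raw recording.

    Parameters
    ----------
    sensor_id
        Identifier, e.g. ``"a"`` or a filename stem.
    timestamps
        Sample times in seconds, non-decreasing.
    x_raw, y_raw
        Integer sensor readings in dots, same length as ``timestamps``.
    dialect
        ``"cumulative"`` or ``"delta"``; always declared, never inferred.
    nominal_rate
        Nominal sampling rate in Hz (default 60), used when timestamps are
        too degenerate to estimate an empirical rate.
    """

    sensor_id: str
    timestamps: np.ndarray
    x_raw: np.ndarray
    y_raw: np.ndarray
    dialect: str
    nominal_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise InputDataError(
                f"sensor {self.sensor_id}: dialect must be one of {DIALECTS}, got {self.dialect!r}"
            )
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x_raw = _as_int_array(self.x_raw, self.sensor_id, "x")
        self.y_raw = _as_int_array(self.y_raw, self.sensor_id, "y")
        n = self.timestamps.shape[0]
        if self.x_raw.shape[0] != n or self.y_raw.shape[0] != n:
            raise InputDataError(
                f"sensor {self.sensor_id}: timestamps ({n}), x ({self.x_raw.shape[0]}) "
                f"and y ({self.y_raw.shape[0]}) must have equal length"
            )
        if n >= 2:
            bad = np.nonzero(np.diff(self.timestamps) < 0)[0]
            if bad.size:
                raise InputDataError(
                    f"sensor {self.sensor_id}: non-monotone timestamp at row {bad[0] + 2}"
                )
        if not (self.nominal_rate > 0):
            raise InputDataError(f"sensor {self.sensor_id}: nominal_rate must be > 0")

    @property
    def n(self) -> int:
        return int(self.timestamps.shape[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n

    @property
    def effective_rate(self) -> float:
        """Empirical sampling rate ``(n - 1) / (t_last - t_first)``; nominal fallback."""
        if self.n >= 2:
            span = self.timestamps[-1] - self.timestamps[0]
            if span > 0:
                return (self.n - 1) / span
        return float(self.nominal_rate)


def _as_int_array(values, sensor_id: str, axis: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = int(np.nonzero(~np.isfinite(arr))[0][0])
        raise InputDataError(f"sensor {sensor_id}: non-finite {axis} reading at row {bad + 2}")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-9):
        bad = int(np.nonzero(np.abs(arr - rounded) > 1e-9)[0][0])
        raise InputDataError(
            f"sensor {sensor_id}: non-integer {axis} reading at row {bad + 2}: {arr[bad]!r}"
        )
    return rounded.astype(np.int64)


@dataclass
class TrialRecord:
    """The two sensor streams of one trial, plus indexing metadata."""

    individual_id: str
    trial_number: int
    stream_a: SensorStream
    stream_b: SensorStream
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trial_number < 1:
            raise InputDataError("trial_number must be a positive integer")


@dataclass
class DisplacementSeries:
    """Per-increment 2-D displacement of the fictive path.

    ``dx`` is the lateral and ``dy`` the forward component; ``units`` is
    ``"dots"`` before calibration and ``"cm"`` after.
    """

    dt: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    units: str
    effective_rate: float

    def __post_init__(self) -> None:
        self.dt = np.asarray(self.dt, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if not (self.dt.shape == self.dx.shape == self.dy.shape):
            raise InputDataError("displacement series: dt, dx, dy must have equal length")
        if self.dt.size and not np.all(self.dt > 0):
            raise InputDataError("displacement series: all dt must be > 0")
        if self.units not in ("dots", "cm"):
            raise InputDataError(f"units must be 'dots' or 'cm', got {self.units!r}")

    @property
    def n(self) -> int:
        return int(self.dx.shape[0])


# ---------------------------------------------------------------------------
# CSV reading / writing


def _looks_like_header(fields: Sequence[str]) -> bool:
    for f in fields:
        f = f.strip()
        if not f:
            continue
        try:
            float(f)
            return False
        except ValueError:
            pass
        # a datetime-ish first field is data, not a header
        try:
            pd.Timestamp(f)
            return False
        except (ValueError, TypeError):
            return True
    return False


def read_sensor_csv(
    path,
    dialect: str,
    sensor_id: str | None = None,
    nominal_rate: float = 60.0,
) -> SensorStream:
    """Read one sensor's CSV file into a validated :class:`SensorStream`.

    The file must have three columns — timestamp, x, y — either headerless or
    with a header row naming them (any casing; ``time`` accepted for the
    timestamp). Timestamps may be numeric seconds or ISO datetimes (converted
    to seconds from the first sample). Malformed rows, non-monotone timestamps
    and empty files raise :class:`~trackball.errors.InputDataError` naming the
    offending row.
    """
    path = FilePath(path)
    if not path.exists():
        raise InputDataError(f"sensor file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise InputDataError(f"sensor file is empty: {path}")

    has_header = _looks_like_header(first.split(","))
    df = pd.read_csv(path, header=0 if has_header else None, dtype=str, skip_blank_lines=True)
    if has_header:
        cols = {c.strip().lower(): c for c in df.columns}
        t_col = cols.get("timestamp", cols.get("time"))
        x_col, y_col = cols.get("x"), cols.get("y")
        if t_col is None or x_col is None or y_col is None:
            # fall back to positional interpretation of a headered file
            t_col, x_col, y_col = df.columns[:3]
        df = df[[t_col, x_col, y_col]]
    else:
        if df.shape[1] < 3:
            raise InputDataError(f"{path}: expected 3 columns (timestamp, x, y)")
        df = df.iloc[:, :3]
    df.columns = ["timestamp", "x", "y"]
    if df.empty:
        raise InputDataError(f"sensor file has a header but no data rows: {path}")

    ts = pd.to_numeric(df["timestamp"], errors="coerce")
    if ts.isna().any():
        ts_dt = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
        if ts_dt.isna().any():
            bad = int(np.nonzero(ts_dt.isna().to_numpy())[0][0])
            raise InputDataError(f"{path}: garbled timestamp at row {bad + 2}")
        ts = (ts_dt - ts_dt.iloc[0]).dt.total_seconds()

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise InputDataError(f"{path}: garbled {col} value at row {bad + 2}")
        return vals.to_numpy()

    sensor_id = sensor_id if sensor_id is not None else path.stem
    try:
        return SensorStream(
            sensor_id=sensor_id,
            timestamps=ts.to_numpy(dtype=float),
            x_raw=numeric("x"),
            y_raw=numeric("y"),
            dialect=dialect,
            nominal_rate=nominal_rate,
        )
    except InputDataError as exc:
        raise InputDataError(f"{path}: {exc}") from None


def write_sensor_csv(stream: SensorStream, path) -> None:
    """Write a stream back to the three-column CSV format read by :func:`read_sensor_csv`."""
    df = pd.DataFrame(
        {"timestamp": stream.timestamps, "x": stream.x_raw, "y": stream.y_raw}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stream algebra


def to_increments(stream: SensorStream) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (dx, dy) in dots.

    Cumulative streams are first-differenced (length ``n - 1``); delta streams
    pass through unchanged (length ``n``).
    """
    if stream.dialect == "cumulative":
        return np.diff(stream.x_raw), np.diff(stream.y_raw)
    return stream.x_raw.copy(), stream.y_raw.copy()


def trim_to_common_length(
    a: SensorStream, b: SensorStream, length: int | None = None
) -> tuple[SensorStream, SensorStream]:
    """Truncate both streams to their common (or a given) length, keeping the
    earliest samples.

    The two acquisition boards stop independently, so the files of one trial
    differ slightly in length; alignment is by sample index.
    """
    if a.n == 0 or b.n == 0:
        raise InputDataError("cannot trim: at least one stream is empty")
    m = min(a.n, b.n) if length is None else int(length)
    if m < 1 or m > min(a.n, b.n):
        raise InputDataError(f"trim length {m} out of range 1..{min(a.n, b.n)}")

    def cut(s: SensorStream) -> SensorStream:
        if s.n == m:
            return s
        return replace(
            s,
            timestamps=s.timestamps[:m],
            x_raw=s.x_raw[:m],
            y_raw=s.y_raw[:m],
        )

    return cut(a), cut(b)


def global_min_length(trials: Iterable[TrialRecord]) -> int:
    """Minimum sample count over both streams of every trial in a batch."""
    lengths = [min(t.stream_a.n, t.stream_b.n) for t in trials]
    if not lengths:
        raise InputDataError("empty trial batch")
    return min(lengths)


def combine_sensors(
    a: SensorStream,
    b: SensorStream,
    axis_map: AxisMap | None = None,
) -> DisplacementSeries:
    """Merge two trimmed streams into the fictive path's displacement series.

    The axis map selects which channel of which sensor supplies the forward
    (y) and lateral (x) component, with optional sign flips. Output is in
    dots; the effective sampling rate is estimated from sensor A's timestamps
    (nominal fallback) and time steps are taken uniform at its reciprocal.
    """
    axis_map = axis_map or DEFAULT_AXIS_MAP
    incr = {"a": to_increments(a), "b": to_increments(b)}

    def channel(entry: tuple[str, str, int]) -> np.ndarray:
        stream, axis, sign = entry
        dx, dy = incr[stream]
        return sign * (dx if axis == "x" else dy)

    fwd = channel(axis_map.forward)
    lat = channel(axis_map.lateral)
    if fwd.shape[0] != lat.shape[0]:
        raise InputDataError(
            f"cannot combine: unequal increment counts ({fwd.shape[0]} vs {lat.shape[0]}); "
            "trim streams to a common length first"
        )
    rate = a.effective_rate
    n = fwd.shape[0]
    return DisplacementSeries(
        dt=np.full(n, 1.0 / rate),
        dx=lat.astype(float),
        dy=fwd.astype(float),
        units="dots",
        effective_rate=rate,
    )


def calibration_check(
    a: SensorStream, b: SensorStream, axis_map: AxisMap | None = None
) -> dict:
    """Diagnostic for axis-map verification.

    With the ball pushed purely forward, virtually all displacement should
    appear in the forward channel. Returns the RMS of each mapped channel and
    the lateral/forward RMS ratio (near 0 for a correct map on a pure-forward
    push).
    """
    series = combine_sensors(a, b, axis_map)
    rms_fwd = float(np.sqrt(np.mean(series.dy**2))) if series.n else 0.0
    rms_lat = float(np.sqrt(np.mean(series.dx**2))) if series.n else 0.0
    ratio = rms_lat / rms_fwd if rms_fwd > 0 else np.inf if rms_lat > 0 else 0.0
    return {"rms_forward": rms_fwd, "rms_lateral": rms_lat, "lateral_to_forward": ratio}


# ---------------------------------------------------------------------------
# Manifests and trial loading


def read_manifest(path) -> pd.DataFrame:
    """Read a trial manifest (YAML list or CSV) into a DataFrame.

    Required fields per trial: ``individual_id``, ``trial_number``,
    ``file_a``, ``file_b``. Relative file paths are resolved against the
    manifest's directory.
    """
    path = FilePath(path)
    if not path.exists():
        raise InputDataError(f"manifest not found: {path}")
    if path.suffix.lower() in (".yml", ".yaml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        if isinstance(entries, dict) and "trials" in entries:
            entries = entries["trials"]
        if not isinstance(entries, list):
            raise InputDataError(f"{path}: manifest must be a list of trial entries")
        df = pd.DataFrame(entries)
    else:
        df = pd.read_csv(path, comment="#")
    required = {"individual_id", "trial_number", "file_a", "file_b"}
    missing = required - set(df.columns)
    if missing:
        raise InputDataError(f"{path}: manifest missing columns {sorted(missing)}")
    base = path.parent
    for col in ("file_a", "file_b"):
        df[col] = [str((base / p)) if not FilePath(p).is_absolute() else str(p) for p in df[col]]
    df["individual_id"] = df["individual_id"].astype(str)
    df["trial_number"] = df["trial_number"].astype(int)
    return df


def load_trials(manifest_path, dialect: str, nominal_rate: float = 60.0) -> list[TrialRecord]:
    """Load every trial listed in a manifest into :class:`TrialRecord` objects."""
    manifest = read_manifest(manifest_path)
    trials = []
    for row in manifest.itertuples(index=False):
        trials.append(
            TrialRecord(
                individual_id=row.individual_id,
                trial_number=int(row.trial_number),
                stream_a=read_sensor_csv(row.file_a, dialect, sensor_id="a", nominal_rate=nominal_rate),
                stream_b=read_sensor_csv(row.file_b, dialect, sensor_id="b", nominal_rate=nominal_rate),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Tidy metric tables


def write_metrics_table(metrics, path, metadata: dict | None = None) -> None:
    """Write per-trial metrics as a tidy CSV, one row per trial.

    ``metrics`` is a DataFrame or a list of objects with an ``as_row()``
    method (:class:`~trackball.kinematics.MovementMetrics`). Provenance
    metadata is embedded as ``#``-prefixed comment lines, preserved by
    :func:`read_metrics_table`.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
    else:
        rows = [m.as_row() for m in metrics]
        df = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    for col in METRIC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(METRIC_COLUMNS)]
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {json.dumps(value) if isinstance(value, (dict, list)) else value}\n")
        df.to_csv(fh, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    """Read a tidy metrics table; embedded metadata lands in ``df.attrs['metadata']``."""
    path = FilePath(path)
    if not path.exists():
        raise InputDataError(f"metrics table not found: {path}")
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    if "individual_id" in df.columns:
        df["individual_id"] = df["individual_id"].astype(str)
    df.attrs["metadata"] = meta
    return df
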