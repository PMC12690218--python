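"""Fictive-path kinematics: smoothing, calibration and the six movement metrics.

Given the merged displacement series of a trial, the processing chain is

    trim -> combine -> smooth (centred rolling mean) -> calibrate (dots -> cm)
         -> metrics

and the six per-trial movement variables are

(a) total distance (cm)               — sum of incremental Pythagorean distances
(b) mean translational velocity (cm/s)— mean moving-increment distance x rate
(c) total rotation (rad)              — sum of unsigned heading changes,
                                        each wrapped into [0, pi]
(d) mean rotational velocity (rad/s)  — mean incremental rotation x rate
(e) sinuosity (0-1)                   — straight-line start-to-end distance
                                        divided by total distance
(f) path straightness (cm/rad)        — total distance / total rotation

Increments whose 2-D displacement magnitude does not exceed a small
zero-tolerance (default half a sensor dot) count as non-movement: they are
excluded from the velocity mean, carry the previous heading forward and
contribute no rotation. Degenerate trials (no movement, or zero total
rotation) report the affected metrics as NaN with machine-readable flags
rather than infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ComputationError, InputDataError
from . import io as tio

#: The six movement variables, in tidy-table column order.
METRIC_NAMES = (
    "total_distance",
    "translational_velocity",
    "total_rotation",
    "rotational_velocity",
    "sinuosity",
    "straightness",
)


@dataclass
class KinematicsConfig:
    """Processing parameters.

    Parameters
    ----------
    smoothing_window
        Width (samples) of the centred rolling mean applied to the cumulative
        coordinates before differencing; default 30 (half a second at 60 Hz).
        1 disables smoothing.
    smoothing_mode
        ``"valid"`` drops the incomplete window edges (output shorter by
        ``window - 1``); ``"shrink"`` averages over the available samples at
        the edges, preserving length.
    smooth_on
        Apply the rolling mean to the ``"cumulative"`` coordinates (then
        difference) or directly to the ``"increments"``.
    dots_per_cm
        Sensor calibration constant; default 394 dots/cm.
    zero_tolerance
        Displacement magnitude (cm) below which an increment counts as
        non-movement; ``None`` resolves to half a dot, ``0.5 / dots_per_cm``.
    rate_source
        ``"empirical"`` uses the rate estimated from timestamps,
        ``"nominal"`` the stream's nominal rate (~60 Hz).
    axis_map
        Sensor-channel routing; ``None`` uses the package default.
    """

    smoothing_window: int = 30
    smoothing_mode: str = "valid"
    smooth_on: str = "cumulative"
    dots_per_cm: float = 394.0
    zero_tolerance: float | None = None
    rate_source: str = "empirical"
    axis_map: tio.AxisMap | None = None

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise InputDataError("smoothing_window must be >= 1")
        if self.smoothing_mode not in ("valid", "shrink"):
            raise InputDataError("smoothing_mode must be 'valid' or 'shrink'")
        if self.smooth_on not in ("cumulative", "increments"):
            raise InputDataError("smooth_on must be 'cumulative' or 'increments'")
        if not (self.dots_per_cm > 0):
            raise InputDataError("dots_per_cm must be > 0")
        if self.zero_tolerance is not None and self.zero_tolerance < 0:
            raise InputDataError("zero_tolerance must be >= 0")
        if self.rate_source not in ("empirical", "nominal"):
            raise InputDataError("rate_source must be 'empirical' or 'nominal'")

    @property
    def resolved_zero_tolerance(self) -> float:
        if self.zero_tolerance is not None:
            return self.zero_tolerance
        return 0.5 / self.dots_per_cm

    def as_dict(self) -> dict:
        d = {
            "smoothing_window": self.smoothing_window,
            "smoothing_mode": self.smoothing_mode,
            "smooth_on": self.smooth_on,
            "dots_per_cm": self.dots_per_cm,
            "zero_tolerance": self.resolved_zero_tolerance,
            "rate_source": self.rate_source,
        }
        d["axis_map"] = (self.axis_map or tio.DEFAULT_AXIS_MAP).to_spec()
        return d


@dataclass
class Path:
    """A reconstructed fictive path in cm, with per-moving-increment headings."""

    x: np.ndarray  # cumulative coordinates, length n_increments + 1 (origin first)
    y: np.ndarray
    headings: np.ndarray  # rad, one per moving increment

    @property
    def start(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.y[0])

    @property
    def end(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])

    def plot(self, ax=None, **kwargs):
        """Quick-look plot of the path (equal aspect; start marked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, **kwargs)
        ax.plot([self.x[0]], [self.y[0]], "ko", ms=4)
        ax.set_aspect("equal")
        ax.set_xlabel("x (cm)")
        ax.set_ylabel("y (cm)")
        return ax


@dataclass
class MovementMetrics:
    """The six per-trial movement variables plus bookkeeping.

    Undefined metrics are NaN and the reason is recorded in ``flags``
    (``"no_movement"``, ``"too_few_moving"``, ``"zero_rotation"``).
    """

    total_distance: float
    translational_velocity: float
    total_rotation: float
    rotational_velocity: float
    sinuosity: float
    straightness: float
    n_samples: int
    duration_s: float
    n_moving: int
    flags: tuple[str, ...] = ()
    individual_id: str | None = None
    trial_number: int | None = None
    config: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "trial_number": self.trial_number,
            **{name: getattr(self, name) for name in METRIC_NAMES},
            "n_samples": self.n_samples,
            "duration_s": self.duration_s,
            "n_moving": self.n_moving,
            "flags": ";".join(self.flags),
        }


# ---------------------------------------------------------------------------
# Elementary operations


def rolling_mean(series: Sequence[float], window: int, mode: str = "valid") -> np.ndarray:
    """Centred moving average.

    For an even window ``w`` the window at index ``i`` covers
    ``i - (w-1)//2 .. i + w//2``. ``mode="valid"`` drops incomplete edges
    (output length ``n - w + 1``); ``mode="shrink"`` averages over the
    samples actually available at the edges (output length ``n``).
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if window < 1:
        raise InputDataError("window must be >= 1")
    if window > n:
        raise InputDataError(f"window {window} exceeds series length {n}")
    if mode not in ("valid", "shrink"):
        raise InputDataError("mode must be 'valid' or 'shrink'")
    if window == 1:
        return x.copy()
    if mode == "valid":
        return np.convolve(x, np.full(window, 1.0 / window), mode="valid")
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def calibrate(series, dots_per_cm: float = 394.0) -> np.ndarray:
    """Convert dots to cm by dividing by the calibration constant."""
    if not (dots_per_cm > 0):
        raise InputDataError("dots_per_cm must be > 0")
    return np.asarray(series, dtype=float) / dots_per_cm


def incremental_distances(dx, dy) -> np.ndarray:
    """Per-increment Pythagorean distance, same units as the inputs."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise InputDataError("dx and dy must have equal length")
    return np.hypot(dx, dy)


def total_distance(distances) -> float:
    """Sum of incremental distances."""
    return float(np.sum(np.asarray(distances, dtype=float)))


def mean_translational_velocity(distances, rate: float, zero_tolerance: float = 0.0) -> float:
    """Mean moving-increment distance times the sampling rate.

    Non-movements (distance <= ``zero_tolerance``) are excluded from the
    mean; with no moving increments the velocity is 0 (callers flag it).
    """
    if not (rate > 0):
        raise InputDataError("rate must be > 0")
    d = np.asarray(distances, dtype=float)
    moving = d > zero_tolerance
    if not moving.any():
        return 0.0
    return float(d[moving].mean() * rate)


def headings_and_rotations(
    dx, dy, zero_tolerance: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-moving-increment headings and unsigned per-step rotations.

    Headings are the full-quadrant arctangent ``atan2(dy, dx)`` of increments
    whose displacement magnitude exceeds ``zero_tolerance`` (headings are
    scale-invariant, so calibrated or raw increments give the same result).
    The rotation between consecutive defined headings is ``|dtheta|``,
    replaced by ``2*pi - |dtheta|`` when ``|dtheta| > pi`` so a turn always
    takes the short way round and lies in [0, pi]. Pauses carry the previous
    heading forward and contribute no rotation. Fewer than two moving
    increments yield an empty rotation sequence.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise InputDataError("dx and dy must have equal length")
    mag = np.hypot(dx, dy)
    moving = mag > zero_tolerance
    theta = np.arctan2(dy[moving], dx[moving])
    if theta.shape[0] < 2:
        return theta, np.empty(0)
    delta = np.abs(np.diff(theta))
    rotations = np.where(delta > np.pi, 2.0 * np.pi - delta, delta)
    return theta, rotations


def total_rotation(rotations) -> float:
    """Sum of unsigned per-step rotations (rad)."""
    return float(np.sum(np.asarray(rotations, dtype=float)))


def mean_rotational_velocity(rotations, rate: float) -> float:
    """Mean per-step rotation times the sampling rate (rad/s)."""
    if not (rate > 0):
        raise InputDataError("rate must be > 0")
    r = np.asarray(rotations, dtype=float)
    if r.size == 0:
        return float("nan")
    return float(r.mean() * rate)


def sinuosity(straight_line_distance: float, total_dist: float) -> float:
    """Start-to-end straight-line distance over total distance, in [0, 1].

    NaN when the total distance is zero (no movement).
    """
    if total_dist < 0:
        raise InputDataError("total distance must be >= 0")
    if total_dist == 0:
        return float("nan")
    return float(min(straight_line_distance / total_dist, 1.0))


def straightness(total_dist: float, total_rot: float) -> float:
    """Total distance over total rotation (cm/rad); NaN when rotation is zero."""
    if total_rot == 0:
        return float("nan")
    return float(total_dist / total_rot)


def path_from_displacements(dx, dy, zero_tolerance: float = 0.0) -> Path:
    """Integrate calibrated increments into a :class:`Path` starting at the origin."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    theta, _ = headings_and_rotations(dx, dy, zero_tolerance)
    return Path(
        x=np.concatenate(([0.0], np.cumsum(dx))),
        y=np.concatenate(([0.0], np.cumsum(dy))),
        headings=theta,
    )


# ---------------------------------------------------------------------------
# Per-trial driver


def metrics_from_displacements(
    dx,
    dy,
    rate: float,
    zero_tolerance: float = 0.0,
    individual_id: str | None = None,
    trial_number: int | None = None,
    config: dict | None = None,
) -> MovementMetrics:
    """Compute all six movement variables from calibrated (cm) increments."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise InputDataError("dx and dy must have equal length")
    if not (rate > 0):
        raise InputDataError("rate must be > 0")
    flags: list[str] = []

    d = incremental_distances(dx, dy)
    dist = total_distance(d)
    moving = d > zero_tolerance
    n_moving = int(moving.sum())

    if n_moving == 0:
        flags.append("no_movement")
    v_trans = mean_translational_velocity(d, rate, zero_tolerance)

    _, rotations = headings_and_rotations(dx, dy, zero_tolerance)
    if rotations.size == 0:
        if n_moving > 0:
            flags.append("too_few_moving")
        rot = 0.0
        v_rot = float("nan")
    else:
        rot = total_rotation(rotations)
        v_rot = mean_rotational_velocity(rotations, rate)

    net = float(np.hypot(dx.sum(), dy.sum()))
    sinu = sinuosity(net, dist)
    if rot == 0.0:
        flags.append("zero_rotation")
    straight = straightness(dist, rot)

    n = int(dx.shape[0])
    return MovementMetrics(
        total_distance=dist,
        translational_velocity=v_trans,
        total_rotation=rot,
        rotational_velocity=v_rot,
        sinuosity=sinu,
        straightness=straight,
        n_samples=n,
        duration_s=n / rate,
        n_moving=n_moving,
        flags=tuple(flags),
        individual_id=individual_id,
        trial_number=trial_number,
        config=config or {},
    )


def _smooth_increments(dx: np.ndarray, dy: np.ndarray, config: KinematicsConfig):
    w = config.smoothing_window
    if w <= 1:
        return dx, dy
    if config.smooth_on == "cumulative":
        cx = np.concatenate(([0.0], np.cumsum(dx)))
        cy = np.concatenate(([0.0], np.cumsum(dy)))
        return (
            np.diff(rolling_mean(cx, w, config.smoothing_mode)),
            np.diff(rolling_mean(cy, w, config.smoothing_mode)),
        )
    return (
        rolling_mean(dx, w, config.smoothing_mode),
        rolling_mean(dy, w, config.smoothing_mode),
    )


def compute_metrics(
    trial: tio.TrialRecord, config: KinematicsConfig | None = None, trim_length: int | None = None
) -> MovementMetrics:
    """Run the full per-trial chain: trim, combine, smooth, calibrate, measure.

    ``trim_length`` overrides per-trial trimming with a batch-wide (global
    minimum) length. Stage failures are re-raised as
    :class:`~trackball.errors.ComputationError` naming the stage.
    """
    config = config or KinematicsConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise ComputationError(
                f"trial {trial.individual_id}/{trial.trial_number}, stage '{name}': {exc}"
            ) from exc

    a, b = stage("trim", trim_to_common, trial, trim_length)
    series = stage("combine", tio.combine_sensors, a, b, config.axis_map)
    dx, dy = stage("smooth", _smooth_increments, series.dx, series.dy, config)
    dx_cm = stage("calibrate", calibrate, dx, config.dots_per_cm)
    dy_cm = stage("calibrate", calibrate, dy, config.dots_per_cm)
    rate = series.effective_rate if config.rate_source == "empirical" else trial.stream_a.nominal_rate
    return stage(
        "metrics",
        metrics_from_displacements,
        dx_cm,
        dy_cm,
        rate,
        config.resolved_zero_tolerance,
        individual_id=trial.individual_id,
        trial_number=trial.trial_number,
        config=config.as_dict(),
    )


def trim_to_common(trial: tio.TrialRecord, trim_length: int | None = None):
    return tio.trim_to_common_length(trial.stream_a, trial.stream_b, length=trim_length)


def compute_metrics_table(
    trials: Sequence[tio.TrialRecord],
    config: KinematicsConfig | None = None,
    trim: str = "per-trial",
):
    """Metrics for a batch of trials, as a tidy DataFrame (one row per trial).

    ``trim="global"`` trims every trial to the batch-wide minimum sample
    count before processing (otherwise each trial is trimmed to its own
    shorter stream).
    """
    import pandas as pd

    if trim not in ("per-trial", "global"):
        raise InputDataError("trim must be 'per-trial' or 'global'")
    trim_length = tio.global_min_length(trials) if trim == "global" else None
    rows = [compute_metrics(t, config, trim_length=trim_length).as_row() for t in trials]
    return pd.DataFrame(rows, columns=list(tio.METRIC_COLUMNS))
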