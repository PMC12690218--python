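"""Ground-truthed synthetic trackball data.

Three generation levels, each seed-deterministic:

1. **Paths** — a discrete-time correlated random walk emulating a tethered
   walker: per 1/60-s step the animal pauses with probability ``pause_prob``;
   otherwise it draws a gamma step length (mean ``mean_speed/step_rate``,
   sd ``speed_sd/step_rate``) and turns by a zero-centred von Mises angle
   with concentration ``turn_concentration``. The exact path and its exact
   movement metrics form the :class:`SyntheticTruth` oracle.
2. **Sensor streams** — the path's forward/lateral increments are converted
   to sensor dots (394 dots/cm by default), optionally perturbed by Gaussian
   sensor noise, and quantized to integers by rounding the *cumulative* dot
   count (carrying the rounding residue forward, so integrated error never
   exceeds half a dot per axis). Both CSV dialects can be emitted, with
   optional uniform timestamp jitter.
3. **Populations** — individuals receive Gaussian deviations of a latent
   walking parameter (log mean speed by default) with specified among- and
   within-individual standard deviations, reproducing exactly the
   variance structure the repeatability estimators assume; the true
   repeatability ``R = among_sd^2 / (among_sd^2 + within_sd^2)`` and all
   latent values are recorded.

Defaults mirror the study conditions the package targets: 10-min trials at
60 Hz, 394 dots/cm, 30 individuals x 2 trials, walking speeds that put the
expected per-trial distance near 1680 cm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np
import pandas as pd
import yaml

from .errors import InputDataError
from .io import SensorStream, TrialRecord, write_sensor_csv
from .kinematics import MovementMetrics, metrics_from_displacements

#: Latent parameters a population can vary.
LATENT_PARAMETERS = ("log_mean_speed", "log_turn_concentration", "logit_pause_prob")


@dataclass(frozen=True)
class WalkerParams:
    """Correlated-random-walk parameters of one simulated trial.

    ``turn_concentration`` is a von Mises kappa: large values mean nearly
    straight walking, 0 means uniformly random turning, and ``math.inf`` is
    the zero-dispersion (perfectly straight) limit.
    """

    mean_speed: float = 3.5  # cm/s while moving
    speed_sd: float = 1.5  # cm/s
    turn_concentration: float = 4.0
    pause_prob: float = 0.2
    step_rate: float = 60.0  # steps/s

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise InputDataError("mean_speed and speed_sd must be >= 0")
        if not (0.0 <= self.pause_prob <= 1.0):
            raise InputDataError("pause_prob must be in [0, 1]")
        if self.turn_concentration < 0:
            raise InputDataError("turn_concentration must be >= 0")
        if not (self.step_rate > 0):
            raise InputDataError("step_rate must be > 0")


@dataclass
class SyntheticTruth:
    """Exact path and exact metrics of one simulated trial."""

    dx: np.ndarray  # cm, per step (zeros at pauses)
    dy: np.ndarray
    params: WalkerParams
    seed: int | None
    metrics: MovementMetrics

    @property
    def x(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.dx)))

    @property
    def y(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.dy)))


@dataclass(frozen=True)
class PopulationSpec:
    """Population design: who varies, by how much, on which latent scale."""

    n_individuals: int = 30
    n_trials: int = 2
    among_sd: float = 0.2
    within_sd: float = 0.2
    parameter: str = "log_mean_speed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise InputDataError("n_individuals must be >= 2")
        if self.n_trials < 1:
            raise InputDataError("n_trials must be >= 1")
        if self.among_sd < 0 or self.within_sd < 0:
            raise InputDataError("among_sd and within_sd must be >= 0")
        if self.parameter not in LATENT_PARAMETERS:
            raise InputDataError(f"parameter must be one of {LATENT_PARAMETERS}")

    @property
    def true_R(self) -> float:
        denom = self.among_sd**2 + self.within_sd**2
        return self.among_sd**2 / denom if denom > 0 else 0.0


@dataclass
class SimulatedTrial:
    individual_id: str
    trial_number: int
    truth: SyntheticTruth
    stream_a: SensorStream | None = None
    stream_b: SensorStream | None = None

    def to_trial_record(self) -> TrialRecord:
        if self.stream_a is None or self.stream_b is None:
            raise InputDataError("trial was simulated without rendered sensor streams")
        return TrialRecord(
            individual_id=self.individual_id,
            trial_number=self.trial_number,
            stream_a=self.stream_a,
            stream_b=self.stream_b,
        )


@dataclass
class PopulationSample:
    """A simulated multi-individual repeated-trial dataset with full truth."""

    spec: PopulationSpec
    base: WalkerParams
    duration_s: float
    trials: list[SimulatedTrial]
    latents: pd.DataFrame  # individual_id, trial_number, individual_latent, trial_latent

    @property
    def true_R(self) -> float:
        return self.spec.true_R

    def trial_records(self) -> list[TrialRecord]:
        return [t.to_trial_record() for t in self.trials]


# ---------------------------------------------------------------------------


def simulate_path(
    params: WalkerParams,
    duration_s: float = 600.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Simulate one correlated-random-walk trial and its exact metrics.

    The stored metrics are recomputable bit-identically from the stored
    increments with :func:`~trackball.kinematics.metrics_from_displacements`
    at zero tolerance.
    """
    if not (duration_s > 0):
        raise InputDataError("duration_s must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * params.step_rate))
    moving = rng.random(n) >= params.pause_prob

    mean_step = params.mean_speed / params.step_rate
    sd_step = params.speed_sd / params.step_rate
    if mean_step == 0:
        steps = np.zeros(n)
    elif sd_step == 0:
        steps = np.full(n, mean_step)
    else:
        shape = (mean_step / sd_step) ** 2
        scale = sd_step**2 / mean_step
        steps = rng.gamma(shape, scale, size=n)

    if math.isinf(params.turn_concentration):
        turns = np.zeros(n)
    elif params.turn_concentration == 0:
        turns = rng.uniform(-np.pi, np.pi, size=n)
    else:
        turns = rng.vonmises(0.0, params.turn_concentration, size=n)

    heading0 = rng.uniform(-np.pi, np.pi)
    # heading advances and a step is taken only on moving increments
    headings = heading0 + np.cumsum(np.where(moving, turns, 0.0))
    dx = np.where(moving, steps * np.cos(headings), 0.0)
    dy = np.where(moving, steps * np.sin(headings), 0.0)
    metrics = metrics_from_displacements(dx, dy, params.step_rate, zero_tolerance=0.0)
    return SyntheticTruth(dx=dx, dy=dy, params=params, seed=seed, metrics=metrics)


def _quantize_residue_carrying(increments_dots: np.ndarray) -> np.ndarray:
    """Integer increments whose running sum stays within 0.5 dots of the input's."""
    csum = np.cumsum(increments_dots)
    q = np.rint(csum)
    return np.diff(np.concatenate(([0.0], q))).astype(np.int64)


def render_sensor_streams(
    truth: SyntheticTruth,
    dots_per_cm: float = 394.0,
    dialect: str = "cumulative",
    noise_sd_dots: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    timestamp_jitter_s: float = 0.0,
) -> tuple[SensorStream, SensorStream]:
    """Render a simulated path as the two per-sensor integer dot streams.

    Matches the package's default axis map: sensor A's x channel carries the
    forward (y) path component, sensor B's x channel the lateral (x)
    component; the unused y channels read zero. Gaussian sensor noise (in
    dots) is added to the float increments before residue-carrying integer
    quantization, so integrated drift is bounded by the rounding residue.
    """
    if not (dots_per_cm > 0):
        raise InputDataError("dots_per_cm must be > 0")
    rate = truth.params.step_rate
    if rng is None:
        rng = np.random.default_rng(seed)
    n = truth.dx.shape[0]

    fwd = truth.dy * dots_per_cm
    lat = truth.dx * dots_per_cm
    if noise_sd_dots > 0:
        fwd = fwd + rng.normal(0.0, noise_sd_dots, size=n)
        lat = lat + rng.normal(0.0, noise_sd_dots, size=n)
    fwd_q = _quantize_residue_carrying(fwd)
    lat_q = _quantize_residue_carrying(lat)

    def timestamps(k: int) -> np.ndarray:
        t = np.arange(k, dtype=float) / rate
        if timestamp_jitter_s > 0 and k:
            if timestamp_jitter_s >= 0.5 / rate:
                raise InputDataError("timestamp jitter must stay below half a sample period")
            t = t + rng.uniform(-timestamp_jitter_s, timestamp_jitter_s, size=k)
            t[0] = max(t[0], 0.0)
        return t

    def stream(sensor_id: str, x_incr: np.ndarray) -> SensorStream:
        if dialect == "cumulative":
            x = np.concatenate(([0], np.cumsum(x_incr))) if n else np.zeros(0, dtype=np.int64)
            t = timestamps(x.shape[0])
        elif dialect == "delta":
            x = x_incr
            t = timestamps(n)
        else:
            raise InputDataError(f"dialect must be 'cumulative' or 'delta', got {dialect!r}")
        return SensorStream(
            sensor_id=sensor_id,
            timestamps=t,
            x_raw=x,
            y_raw=np.zeros_like(x),
            dialect=dialect,
            nominal_rate=rate,
        )

    return stream("a", fwd_q), stream("b", lat_q)


# ---------------------------------------------------------------------------
# Populations


def _apply_latent(base: WalkerParams, parameter: str, latent: float) -> WalkerParams:
    from dataclasses import replace

    if parameter == "log_mean_speed":
        return replace(base, mean_speed=float(np.exp(latent)))
    if parameter == "log_turn_concentration":
        return replace(base, turn_concentration=float(np.exp(latent)))
    if parameter == "logit_pause_prob":
        return replace(base, pause_prob=float(1.0 / (1.0 + np.exp(-latent))))
    raise InputDataError(f"unknown latent parameter {parameter!r}")


def _base_latent(base: WalkerParams, parameter: str) -> float:
    if parameter == "log_mean_speed":
        if base.mean_speed <= 0:
            raise InputDataError("log_mean_speed requires mean_speed > 0")
        return math.log(base.mean_speed)
    if parameter == "log_turn_concentration":
        if not (0 < base.turn_concentration < math.inf):
            raise InputDataError("log_turn_concentration requires finite positive kappa")
        return math.log(base.turn_concentration)
    if parameter == "logit_pause_prob":
        p = base.pause_prob
        if not (0 < p < 1):
            raise InputDataError("logit_pause_prob requires pause_prob in (0, 1)")
        return math.log(p / (1 - p))
    raise InputDataError(f"unknown latent parameter {parameter!r}")


def draw_latent_values(
    spec: PopulationSpec, base: WalkerParams | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the Gaussian latent structure of a population (no paths).

    One row per trial: the individual's latent mean (``individual_latent``,
    ~ N(base, among_sd^2)) and the trial's realised latent
    (``trial_latent`` ~ N(individual, within_sd^2)). This is the exact
    random-intercept structure the repeatability estimators assume, so it
    doubles as a direct estimator test bed.
    """
    base = base or WalkerParams()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mu = _base_latent(base, spec.parameter)
    ind = mu + rng.normal(0.0, spec.among_sd, size=spec.n_individuals)
    rows = []
    width = len(str(spec.n_individuals))
    for i in range(spec.n_individuals):
        for t in range(1, spec.n_trials + 1):
            rows.append(
                {
                    "individual_id": f"ind{i + 1:0{width}d}",
                    "trial_number": t,
                    "individual_latent": ind[i],
                    "trial_latent": ind[i] + rng.normal(0.0, spec.within_sd),
                }
            )
    return pd.DataFrame(rows)


def simulate_population(
    spec: PopulationSpec,
    base: WalkerParams | None = None,
    duration_s: float = 600.0,
    render: bool = True,
    dialect: str = "cumulative",
    noise_sd_dots: float = 0.0,
    dots_per_cm: float = 394.0,
    timestamp_jitter_s: float = 0.0,
) -> PopulationSample:
    """Simulate (and optionally render) every trial of a population.

    Per-trial randomness is spawned deterministically from ``spec.seed``, so
    the same spec always yields the same dataset.
    """
    base = base or WalkerParams()
    ss = np.random.SeedSequence(spec.seed)
    latent_rng = np.random.default_rng(ss.spawn(1)[0])
    latents = draw_latent_values(spec, base, rng=latent_rng)
    trial_streams = ss.spawn(len(latents))
    trials = []
    for row, child in zip(latents.itertuples(index=False), trial_streams):
        rng = np.random.default_rng(child)
        params = _apply_latent(base, spec.parameter, row.trial_latent)
        truth = simulate_path(params, duration_s=duration_s, rng=rng)
        trial = SimulatedTrial(row.individual_id, int(row.trial_number), truth)
        if render:
            trial.stream_a, trial.stream_b = render_sensor_streams(
                truth,
                dots_per_cm=dots_per_cm,
                dialect=dialect,
                noise_sd_dots=noise_sd_dots,
                rng=rng,
                timestamp_jitter_s=timestamp_jitter_s,
            )
        trials.append(trial)
    return PopulationSample(spec=spec, base=base, duration_s=duration_s, trials=trials, latents=latents)


def write_dataset(sample: PopulationSample, outdir, dialect: str | None = None) -> FilePath:
    """Write a rendered population to disk in the formats ``trackball.io`` reads.

    Creates one CSV per sensor per trial, a ``manifest.yaml`` and a
    ``truth.json`` holding the spec, the true repeatability, all latent
    values and every trial's exact metrics. Returns the manifest path.
    """
    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    truth_trials = []
    for trial in sample.trials:
        rec = trial.to_trial_record()
        stem = f"{trial.individual_id}_t{trial.trial_number}"
        fa, fb = f"{stem}_a.csv", f"{stem}_b.csv"
        write_sensor_csv(rec.stream_a, outdir / fa)
        write_sensor_csv(rec.stream_b, outdir / fb)
        entries.append(
            {
                "individual_id": trial.individual_id,
                "trial_number": trial.trial_number,
                "file_a": fa,
                "file_b": fb,
            }
        )
        truth_trials.append(
            {
                "individual_id": trial.individual_id,
                "trial_number": trial.trial_number,
                **{k: v for k, v in trial.truth.metrics.as_row().items()
                   if k not in ("individual_id", "trial_number")},
            }
        )
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(
            {
                "dialect": dialect or sample.trials[0].stream_a.dialect,
                "seed": sample.spec.seed,
                "trials": entries,
            },
            fh,
            sort_keys=False,
        )
    truth = {
        "spec": {
            "n_individuals": sample.spec.n_individuals,
            "n_trials": sample.spec.n_trials,
            "among_sd": sample.spec.among_sd,
            "within_sd": sample.spec.within_sd,
            "parameter": sample.spec.parameter,
            "seed": sample.spec.seed,
            "true_R": sample.spec.true_R,
        },
        "base_params": {
            "mean_speed": sample.base.mean_speed,
            "speed_sd": sample.base.speed_sd,
            "turn_concentration": sample.base.turn_concentration,
            "pause_prob": sample.base.pause_prob,
            "step_rate": sample.base.step_rate,
        },
        "duration_s": sample.duration_s,
        "latents": sample.latents.to_dict(orient="records"),
        "trial_metrics": truth_trials,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return manifest_path
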