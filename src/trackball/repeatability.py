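"""Among-individual repeatability and cross-metric correlations.

Repeatability (intraclass correlation) is the fraction of total phenotypic
variance attributable to differences among individuals,

    r = V_among / (V_among + V_within),

estimated under the one-random-intercept Gaussian model

    y_ij = mu + a_i + e_ij,   a_i ~ N(0, V_among),  e_ij ~ N(0, V_within),

with individual as the grouping factor. Two estimators are provided:

``anova``
    one-way random-effects ANOVA moments: s2_A = (MS_among - MS_within)/n0
    with the standard unbalanced correction n0 = (N - sum n_i^2 / N)/(g - 1),
    negative s2_A truncated to 0;
``reml``
    restricted maximum likelihood, fitted by profiling the restricted
    log-likelihood down to the single variance ratio lam = V_among/V_within
    and minimising it on a log grid by golden-section search. For balanced
    data the REML solution coincides with the truncated ANOVA estimator.

Uncertainty comes from a parametric bootstrap: datasets are simulated from
the fitted Gaussian model, re-estimated, and the 2.5/97.5 percentiles of the
bootstrap r distribution form the 95% CI. Cross-metric association uses
Spearman rank correlations with nonparametric pairs-bootstrap percentile
CIs; an effect is flagged significant when its 95% CI excludes zero.

The module is organised statsmodels-style: build a
:class:`RepeatabilityModel` from a tidy DataFrame, call :meth:`fit`, and the
returned :class:`RepeatabilityResults` carries estimates, bootstrap CIs and
a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputDataError
from .kinematics import METRIC_NAMES

TRANSFORMS = ("none", "sqrt", "ln", "arcsine_sqrt")

#: Default response transformations per movement variable (chosen to meet the
#: Gaussian-model assumptions for right-skewed distances / rates and the
#: [0, 1]-bounded sinuosity).
DEFAULT_TRANSFORMS = {
    "total_distance": "sqrt",
    "rotational_velocity": "ln",
    "sinuosity": "arcsine_sqrt",
}

_PHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden ratio step
_LOG_LAM_LO, _LOG_LAM_HI = -35.0, 35.0


def transform(values, kind: str) -> np.ndarray:
    """Element-wise response transformation with domain checking.

    ``sqrt`` requires values >= 0, ``ln`` values > 0, ``arcsine_sqrt``
    (``arcsin(sqrt(x))``) values in [0, 1]. Violations raise naming the
    offending value.
    """
    v = np.asarray(values, dtype=float)
    if kind == "none":
        return v.copy()
    if kind == "sqrt":
        if np.any(v < 0):
            bad = v[v < 0][0]
            raise InputDataError(f"sqrt transform requires values >= 0; got {bad}")
        return np.sqrt(v)
    if kind == "ln":
        if np.any(v <= 0):
            bad = v[v <= 0][0]
            raise InputDataError(f"ln transform requires values > 0; got {bad}")
        return np.log(v)
    if kind == "arcsine_sqrt":
        if np.any((v < 0) | (v > 1)):
            bad = v[(v < 0) | (v > 1)][0]
            raise InputDataError(f"arcsine_sqrt transform requires values in [0, 1]; got {bad}")
        return np.arcsin(np.sqrt(v))
    raise InputDataError(f"unknown transformation {kind!r}; choose from {TRANSFORMS}")


# ---------------------------------------------------------------------------
# Sufficient statistics and estimator cores (vectorised over a leading batch
# axis so the parametric bootstrap refits thousands of datasets at once).


def _suffstats(y: np.ndarray, group_idx: np.ndarray, g: int):
    """Group sizes, group means and within-group sum of squares.

    ``y`` may be ``(N,)`` or ``(B, N)``; groups are integer codes ``0..g-1``.
    """
    n_i = np.bincount(group_idx, minlength=g).astype(float)
    if y.ndim == 1:
        sums = np.bincount(group_idx, weights=y, minlength=g)
        ybar = sums / n_i
        ssw = float(np.sum((y - ybar[group_idx]) ** 2))
    else:
        order = np.argsort(group_idx, kind="stable")
        starts = np.concatenate(([0], np.cumsum(n_i.astype(int))))[:-1]
        ys = y[:, order]
        sums = np.add.reduceat(ys, starts, axis=1)
        ybar = sums / n_i
        resid = ys - np.repeat(ybar, n_i.astype(int), axis=1)
        ssw = np.sum(resid**2, axis=1)
    return n_i, ybar, ssw


def _anova_components(n_i, ybar, ssw, N: float):
    """Truncated one-way ANOVA variance components (batch-aware)."""
    g = n_i.shape[0]
    grand = (ybar * n_i).sum(axis=-1) / N
    ssa = ((ybar - grand[..., None]) ** 2 * n_i).sum(axis=-1)
    ms_a = ssa / (g - 1)
    ms_w = ssw / (N - g)
    n0 = (N - (n_i**2).sum() / N) / (g - 1)
    v_a = np.maximum((ms_a - ms_w) / n0, 0.0)
    return v_a, ms_w


def _reml_objective(log_lam, n_i, ybar, ssw, N: float):
    """Profiled restricted -2 log-likelihood at lam = exp(log_lam) (batch-aware).

    f(lam) = (N-1) log Q(lam) + sum_i log(1 + n_i lam) + log sum_i w_i,
    with w_i = n_i/(1 + n_i lam), mu-hat the w-weighted mean of group means
    and Q = SSW + sum_i w_i (ybar_i - mu-hat)^2.
    """
    lam = np.exp(np.asarray(log_lam, dtype=float))[..., None]
    w = n_i / (1.0 + n_i * lam)
    wsum = w.sum(axis=-1)
    mu = (w * ybar).sum(axis=-1) / wsum
    q = ssw + (w * (ybar - mu[..., None]) ** 2).sum(axis=-1)
    return (N - 1) * np.log(q) + np.log1p(n_i * lam).sum(axis=-1) + np.log(wsum)


def _reml_components(n_i, ybar, ssw, N: float, tol: float = 1e-12):
    """REML variance components via golden-section search on log lam.

    Batch-aware: ``ybar`` may be ``(B, g)`` with ``ssw`` ``(B,)``. The
    boundary lam = 0 (V_among = 0) is checked explicitly against the
    interior optimum.
    """
    ybar = np.atleast_2d(ybar)
    ssw_b = np.atleast_1d(np.asarray(ssw, dtype=float))
    B = ybar.shape[0]
    lo = np.full(B, _LOG_LAM_LO)
    hi = np.full(B, _LOG_LAM_HI)
    c = hi - _PHI * (hi - lo)
    d = lo + _PHI * (hi - lo)
    fc = _reml_objective(c, n_i, ybar, ssw_b, N)
    fd = _reml_objective(d, n_i, ybar, ssw_b, N)
    # ~90 iterations shrink the bracket far below the requested tolerance.
    n_iter = int(np.ceil(np.log(tol / (_LOG_LAM_HI - _LOG_LAM_LO)) / np.log(_PHI)))
    for _ in range(n_iter):
        take_c = fc < fd  # minimum lies in [lo, d]
        new_hi = np.where(take_c, d, hi)
        new_lo = np.where(take_c, lo, c)
        new_c = np.where(take_c, new_hi - _PHI * (new_hi - new_lo), d)
        new_d = np.where(take_c, c, new_lo + _PHI * (new_hi - new_lo))
        x_eval = np.where(take_c, new_c, new_d)
        f_eval = _reml_objective(x_eval, n_i, ybar, ssw_b, N)
        new_fc = np.where(take_c, f_eval, fd)
        new_fd = np.where(take_c, fc, f_eval)
        lo, hi, c, d, fc, fd = new_lo, new_hi, new_c, new_d, new_fc, new_fd
    log_lam = (lo + hi) / 2.0
    lam = np.exp(log_lam)
    f_int = _reml_objective(log_lam, n_i, ybar, ssw_b, N)
    f_zero = _reml_objective(np.full(B, -745.0), n_i, ybar, ssw_b, N)  # lam ~ 5e-324
    lam = np.where(f_zero <= f_int, 0.0, lam)

    w = n_i / (1.0 + n_i * lam[:, None])
    mu = (w * ybar).sum(axis=1) / w.sum(axis=1)
    q = ssw_b + (w * (ybar - mu[:, None]) ** 2).sum(axis=1)
    v_w = q / (N - 1)
    v_a = lam * v_w
    return v_a, v_w


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation with a pairs-bootstrap percentile 95% CI."""

    rho: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n_pairs: int
    significant: bool
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_pairs": self.n_pairs,
            "significant": self.significant,
            "flags": list(self.flags),
        }


class RepeatabilityModel:
    """Random-intercept Gaussian model of one metric measured in repeated trials.

    Parameters
    ----------
    values
        One observation per trial.
    groups
        Individual identifier per observation.
    transformation
        Applied to ``values`` before fitting (``none``, ``sqrt``, ``ln``,
        ``arcsine_sqrt``).

    At least two individuals, and at least one individual with two or more
    trials, are required.
    """

    def __init__(self, values, groups, transformation: str = "none"):
        raw = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        if raw.shape[0] != groups.shape[0]:
            raise InputDataError("values and groups must have equal length")
        keep = np.isfinite(raw)
        raw, groups = raw[keep], groups[keep]
        if raw.shape[0] == 0:
            raise InputDataError("no finite observations")
        self.transformation = transformation
        self.endog = transform(raw, transformation)
        labels, idx = np.unique(groups, return_inverse=True)
        self.group_labels = labels
        self.group_idx = idx
        self.n_groups = labels.shape[0]
        self.nobs = raw.shape[0]
        if self.n_groups < 2:
            raise InputDataError("repeatability requires at least 2 individuals")
        counts = np.bincount(idx)
        if counts.max() < 2:
            raise InputDataError("at least one individual needs >= 2 trials")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value: str,
        group: str = "individual_id",
        transformation: str = "none",
    ) -> "RepeatabilityModel":
        for col in (value, group):
            if col not in data.columns:
                raise InputDataError(f"column {col!r} not in data")
        return cls(data[value].to_numpy(), data[group].to_numpy(), transformation)

    def _stats(self):
        return _suffstats(self.endog, self.group_idx, self.n_groups)

    def fit(self, method: str = "reml") -> "RepeatabilityResults":
        """Estimate the variance components; ``method`` is ``"reml"`` or ``"anova"``."""
        if method not in ("reml", "anova"):
            raise InputDataError("method must be 'reml' or 'anova'")
        n_i, ybar, ssw = self._stats()
        flags: tuple[str, ...] = ()
        scale = float(np.var(self.endog))
        if scale == 0.0:
            return RepeatabilityResults(
                self, method, float("nan"), 0.0, 0.0, flags=("constant_response",)
            )
        if ssw <= scale * 1e-14:
            # every individual perfectly consistent, individuals differ
            v_a = float(_anova_components(n_i, ybar, 0.0, self.nobs)[0])
            return RepeatabilityResults(self, method, 1.0, v_a, 0.0, flags=("zero_within_variance",))
        if method == "anova":
            v_a, v_w = _anova_components(n_i, ybar, ssw, self.nobs)
            v_a, v_w = float(v_a), float(v_w)
        else:
            v_a_arr, v_w_arr = _reml_components(n_i, ybar, ssw, self.nobs)
            v_a, v_w = float(v_a_arr[0]), float(v_w_arr[0])
        if v_a == 0.0:
            flags = ("boundary_v_among",)
        r = v_a / (v_a + v_w)
        return RepeatabilityResults(self, method, r, v_a, v_w, flags=flags)


@dataclass
class RepeatabilityResults:
    """Fitted repeatability with variance components and bootstrap CI.

    Produced by :meth:`RepeatabilityModel.fit`; call :meth:`bootstrap_ci`
    to attach a parametric-bootstrap 95% interval, and :meth:`summary` for a
    readable report.
    """

    model: RepeatabilityModel
    method: str
    r: float
    v_among: float
    v_within: float
    flags: tuple[str, ...] = ()
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    def bootstrap_ci(self, seed: int, n_boot: int = 1000) -> tuple[float, float]:
        """Parametric-bootstrap percentile 95% CI for r.

        ``n_boot`` datasets are simulated from the fitted model (individual
        effects ~ N(0, V_among), residuals ~ N(0, V_within), the observed
        group structure) and re-estimated with the same method. Deterministic
        under a fixed seed.
        """
        if n_boot < 2:
            raise InputDataError("n_boot must be >= 2")
        if not np.isfinite(self.r):
            raise ComputationError("cannot bootstrap an undefined repeatability")
        rng = np.random.default_rng(seed)
        m = self.model
        g, N = m.n_groups, m.nobs
        a = rng.normal(0.0, np.sqrt(self.v_among), size=(n_boot, g))
        e = rng.normal(0.0, np.sqrt(self.v_within), size=(n_boot, N))
        y = a[:, m.group_idx] + e
        n_i, ybar, ssw = _suffstats(y, m.group_idx, g)
        if self.v_within == 0.0:
            r_boot = np.ones(n_boot)
        elif self.method == "anova":
            v_a, v_w = _anova_components(n_i, ybar, ssw, N)
            r_boot = v_a / (v_a + v_w)
        else:
            v_a, v_w = _reml_components(n_i, ybar, ssw, N)
            r_boot = v_a / (v_a + v_w)
        lo, hi = np.quantile(r_boot, [0.025, 0.975])
        self.ci_low, self.ci_high = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
        self.n_boot, self.seed = n_boot, seed
        return self.ci_low, self.ci_high

    def to_dict(self) -> dict:
        return {
            "estimator": self.method,
            "transformation": self.model.transformation,
            "r": self.r,
            "v_among": self.v_among,
            "v_within": self.v_within,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_individuals": self.model.n_groups,
            "n_observations": self.model.nobs,
            "flags": list(self.flags),
        }

    def summary(self) -> str:
        lines = [
            "      Repeatability (random-intercept Gaussian model)",
            "=" * 58,
            f"Individuals: {self.model.n_groups}    Observations: {self.model.nobs}"
            f"    Method: {self.method.upper()}",
            f"Transformation: {self.model.transformation}",
            f"V_among:  {self.v_among:.6g}",
            f"V_within: {self.v_within:.6g}",
            f"r = {self.r:.4f}",
        ]
        if self.ci_low is not None:
            lines.append(
                f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]"
                f"  (parametric bootstrap, n_boot={self.n_boot}, seed={self.seed})"
            )
        if self.flags:
            lines.append(f"Flags: {', '.join(self.flags)}")
        lines.append("=" * 58)
        return "\n".join(lines)


def anova_repeatability(values, groups, transformation: str = "none") -> RepeatabilityResults:
    """One-way random-effects ANOVA repeatability (convenience wrapper)."""
    return RepeatabilityModel(values, groups, transformation).fit("anova")


def reml_repeatability(values, groups, transformation: str = "none") -> RepeatabilityResults:
    """REML repeatability (convenience wrapper)."""
    return RepeatabilityModel(values, groups, transformation).fit("reml")


# ---------------------------------------------------------------------------
# Spearman rank correlations


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average", axis=-1)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    NaN when either vector is constant (ranks undefined up to ties only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputDataError("x and y must be equal-length 1-D vectors")
    if x.shape[0] < 3:
        raise InputDataError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _rowwise_spearman(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman per row of two (B, n) arrays (vectorised for the bootstrap)."""
    rx = _midranks(X)
    ry = _midranks(Y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (rx * ry).sum(axis=1) / denom, np.nan)


def spearman_bootstrap_ci(x, y, seed: int, n_boot: int = 1000) -> CorrelationResult:
    """Spearman correlation with nonparametric pairs-bootstrap percentile 95% CI.

    Pairs are resampled with replacement; resamples whose ranks degenerate to
    a constant vector are dropped from the percentile computation. The result
    is flagged significant when the CI excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman(x, y)
    n = x.shape[0]
    if not np.isfinite(rho):
        return CorrelationResult(rho, float("nan"), float("nan"), n_boot, seed, n, False, ("constant_input",))
    if n_boot < 2:
        raise InputDataError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    r_boot = _rowwise_spearman(x[idx], y[idx])
    r_boot = r_boot[np.isfinite(r_boot)]
    if r_boot.size < 2:
        return CorrelationResult(rho, float("nan"), float("nan"), n_boot, seed, n, False, ("degenerate_bootstrap",))
    lo, hi = np.quantile(r_boot, [0.025, 0.975])
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    return CorrelationResult(rho, lo, hi, n_boot, seed, n, bool(lo > 0 or hi < 0))


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations among metrics, one trial series."""

    metrics: tuple[str, ...]
    results: dict  # (metric_a, metric_b) -> CorrelationResult

    @property
    def rho(self) -> pd.DataFrame:
        k = len(self.metrics)
        mat = np.ones((k, k))
        for i, a in enumerate(self.metrics):
            for j, b in enumerate(self.metrics):
                if i != j:
                    mat[i, j] = self.results[(a, b)].rho
        return pd.DataFrame(mat, index=self.metrics, columns=self.metrics)

    def to_dict(self) -> dict:
        return {f"{a}~{b}": res.to_dict() for (a, b), res in self.results.items()}

    def summary(self) -> str:
        lines = ["Spearman rank correlation matrix (rho; * = 95% CI excludes 0)"]
        frame = self.rho
        width = max(len(m) for m in self.metrics) + 2
        lines.append(" " * width + "".join(f"{m[:12]:>14}" for m in self.metrics))
        for a in self.metrics:
            cells = []
            for b in self.metrics:
                if a == b:
                    cells.append(f"{'1.00':>14}")
                else:
                    res = self.results[(a, b)]
                    mark = "*" if res.significant else " "
                    cells.append(f"{res.rho:>12.2f}{mark} ")
            lines.append(f"{a:<{width}}" + "".join(cells))
        return "\n".join(lines)


def correlation_matrix(
    metrics_table: pd.DataFrame,
    trial_number: int,
    metrics: Sequence[str] = METRIC_NAMES,
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations among metrics within one trial series.

    The table is filtered to the chosen trial (one row per individual);
    each off-diagonal cell gets its own bootstrap CI from a seed spawned
    deterministically from ``seed``. The matrix is symmetric by construction.
    """
    sub = metrics_table[metrics_table["trial_number"] == trial_number]
    if sub["individual_id"].duplicated().any():
        raise InputDataError(f"multiple rows per individual for trial {trial_number}")
    if len(sub) < 3:
        raise InputDataError(f"need >= 3 individuals for trial {trial_number}")
    metrics = tuple(metrics)
    ss = np.random.SeedSequence(seed)
    results: dict = {}
    pairs = [(a, b) for i, a in enumerate(metrics) for b in metrics[i + 1 :]]
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(pairs))]
    for (a, b), child in zip(pairs, child_seeds):
        xa = sub[a].to_numpy(dtype=float)
        xb = sub[b].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        res = spearman_bootstrap_ci(xa[ok], xb[ok], seed=child, n_boot=n_boot)
        results[(a, b)] = res
        results[(b, a)] = res
    return CorrelationMatrix(metrics=metrics, results=results)


def between_trial_correlation(
    metrics_table: pd.DataFrame,
    metric: str,
    trials: tuple[int, int] = (1, 2),
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation of one metric between two trials across individuals.

    A rank-based consistency check complementing the variance-component
    repeatability (useful when no transformation meets the LMM assumptions).
    """
    t1 = metrics_table[metrics_table["trial_number"] == trials[0]].set_index("individual_id")[metric]
    t2 = metrics_table[metrics_table["trial_number"] == trials[1]].set_index("individual_id")[metric]
    common = t1.index.intersection(t2.index)
    x = t1.loc[common].to_numpy(dtype=float)
    y = t2.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return spearman_bootstrap_ci(x[ok], y[ok], seed=seed, n_boot=n_boot)


def repeatability_report(
    metrics_table: pd.DataFrame,
    estimator: str = "reml",
    n_boot: int = 1000,
    seed: int = 0,
    transforms: dict | None = None,
    metrics: Sequence[str] = METRIC_NAMES,
) -> dict:
    """Per-metric repeatability (with CI) plus between-trial Spearman, as a dict.

    The JSON-ready structure mirrors a per-variable results table: for each
    movement variable, the estimator, transformation, point estimate, 95%
    bootstrap CI and the rank-based between-trial correlation.
    """
    transforms = {**DEFAULT_TRANSFORMS, **(transforms or {})}
    ss = np.random.SeedSequence(seed)
    children = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(tuple(metrics)))]
    report: dict = {"estimator": estimator, "n_boot": n_boot, "seed": seed, "metrics": {}}
    for i, metric in enumerate(metrics):
        sub = metrics_table[np.isfinite(metrics_table[metric].to_numpy(dtype=float))]
        kind = transforms.get(metric, "none")
        model = RepeatabilityModel.from_dataframe(sub, value=metric, transformation=kind)
        res = model.fit(estimator)
        if np.isfinite(res.r):
            res.bootstrap_ci(seed=children[2 * i], n_boot=n_boot)
        entry = res.to_dict()
        trial_numbers = sorted(metrics_table["trial_number"].unique())
        if len(trial_numbers) >= 2:
            rs = between_trial_correlation(
                metrics_table, metric, trials=(trial_numbers[0], trial_numbers[1]),
                n_boot=n_boot, seed=children[2 * i + 1],
            )
            entry["between_trial_spearman"] = rs.to_dict()
        report["metrics"][metric] = entry
    return report
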