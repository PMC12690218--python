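"""Variance-component repeatability, bootstrap CIs and Spearman correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trackball import (
    InputDataError,
    RepeatabilityModel,
    anova_repeatability,
    between_trial_correlation,
    correlation_matrix,
    reml_repeatability,
    repeatability_report,
    spearman,
    spearman_bootstrap_ci,
    transform,
)

TOY_VALUES = [1.0, 2.0, 4.0, 5.0, 7.0, 8.0]
TOY_GROUPS = ["A", "A", "B", "B", "C", "C"]


# ---------------------------------------------------------------------------
# oracles


def anova_oracle(values, groups):
    """Brute-force one-way random-effects ANOVA repeatability."""
    values = np.asarray(values, float)
    labels = sorted(set(groups))
    by = {g: values[[i for i, gg in enumerate(groups) if gg == g]] for g in labels}
    N, g = len(values), len(labels)
    grand = values.mean() if all(len(v) == len(by[labels[0]]) for v in by.values()) else None
    # general computation (works balanced or not)
    grand = sum(v.sum() for v in by.values()) / N
    ssa = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    ms_a, ms_w = ssa / (g - 1), ssw / (N - g)
    n0 = (N - sum(len(v) ** 2 for v in by.values()) / N) / (g - 1)
    s2a = max((ms_a - ms_w) / n0, 0.0)
    return {"ms_a": ms_a, "ms_w": ms_w, "s2a": s2a, "r": s2a / (s2a + ms_w)}


def midrank_oracle(v):
    v = np.asarray(v, float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        eq = np.sum(v == x)
        out[i] = less + (eq + 1) / 2.0
    return out


def spearman_oracle(x, y):
    rx, ry = midrank_oracle(x), midrank_oracle(y)
    return np.corrcoef(rx, ry)[0, 1]


# ---------------------------------------------------------------------------
# transformations


def test_transform_boundaries():
    np.testing.assert_allclose(transform([0.0, 1.0], "arcsine_sqrt"), [0.0, np.pi / 2])
    assert transform([4.0], "sqrt")[0] == 2.0
    assert transform([np.e], "ln")[0] == pytest.approx(1.0)
    np.testing.assert_array_equal(transform([1.0, 2.0], "none"), [1.0, 2.0])


@pytest.mark.parametrize(
    "kind,bad",
    [("sqrt", [-1.0]), ("ln", [-2.0]), ("ln", [0.0]), ("arcsine_sqrt", [1.5])],
)
def test_transform_domain_errors_name_value(kind, bad):
    with pytest.raises(InputDataError, match=str(bad[0])):
        transform(bad, kind)


def test_unknown_transform():
    with pytest.raises(InputDataError, match="unknown"):
        transform([1.0], "log10")


# ---------------------------------------------------------------------------
# ANOVA estimator


def test_toy_anova_matches_brute_force_oracle():
    oracle = anova_oracle(TOY_VALUES, TOY_GROUPS)
    assert oracle["ms_a"] == pytest.approx(18.0)
    assert oracle["ms_w"] == pytest.approx(0.5)
    assert oracle["s2a"] == pytest.approx(8.75)
    res = anova_repeatability(TOY_VALUES, TOY_GROUPS)
    assert res.v_among == pytest.approx(oracle["s2a"])
    assert res.v_within == pytest.approx(oracle["ms_w"])
    assert res.r == pytest.approx(oracle["r"])
    assert res.r == pytest.approx(8.75 / 9.25)


def test_unbalanced_anova_matches_oracle(rng):
    sizes = [3, 2, 4, 1, 2, 3]
    groups = np.repeat([f"g{i}" for i in range(6)], sizes)
    values = rng.normal(0, 1, len(groups)) + np.repeat(rng.normal(0, 1, 6), sizes)
    res = anova_repeatability(values, groups)
    oracle = anova_oracle(values, list(groups))
    assert res.r == pytest.approx(oracle["r"], abs=1e-12)


def test_perfect_consistency_r_is_one():
    res = anova_repeatability([2.0, 2.0, 5.0, 5.0, 9.0, 9.0], TOY_GROUPS)
    assert res.r == 1.0
    assert res.v_within == 0.0


def test_identical_group_means_truncate_to_zero(rng):
    values = [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]  # all means 1.5, only within noise
    res = anova_repeatability(values, TOY_GROUPS)
    assert res.r == 0.0
    assert res.v_among == 0.0
    assert "boundary_v_among" in res.flags


def test_constant_response_flagged():
    res = anova_repeatability([3.0] * 6, TOY_GROUPS)
    assert np.isnan(res.r)
    assert "constant_response" in res.flags


def test_single_individual_errors():
    with pytest.raises(InputDataError, match="2 individuals"):
        anova_repeatability([1.0, 2.0], ["A", "A"])


def test_no_repeats_errors():
    with pytest.raises(InputDataError, match=">= 2 trials"):
        anova_repeatability([1.0, 2.0, 3.0], ["A", "B", "C"])


# ---------------------------------------------------------------------------
# REML estimator


def test_reml_matches_anova_on_balanced_toy():
    res = reml_repeatability(TOY_VALUES, TOY_GROUPS)
    assert res.r == pytest.approx(8.75 / 9.25, abs=1e-6)


def test_reml_boundary_when_no_among_variance(rng):
    groups = np.repeat(np.arange(20), 3)
    values = rng.normal(0.0, 1.0, 60)  # true V_among = 0
    res = reml_repeatability(values, groups)
    assert res.v_among >= 0.0
    assert 0.0 <= res.r < 0.5


def test_reml_unbalanced_matches_mixedlm(rng):
    """Independent cross-check against a general mixed-model REML fitter."""
    import statsmodels.api as sm

    sizes = [2, 3, 2, 4, 2, 2, 3, 1, 2, 2, 3, 2]
    groups = np.repeat(np.arange(12), sizes)
    values = rng.normal(0, 1, len(groups)) + np.repeat(rng.normal(0, 0.8, 12), sizes)
    mine = reml_repeatability(values, groups)
    ref = sm.MixedLM(values, np.ones((len(values), 1)), groups=groups).fit(reml=True)
    assert mine.v_among == pytest.approx(float(np.asarray(ref.cov_re).ravel()[0]), rel=1e-3)
    assert mine.v_within == pytest.approx(float(ref.scale), rel=1e-3)


@given(st.integers(0, 2**31 - 1))
def test_affine_invariance_of_r(seed):
    """r is unchanged by y -> a*y + b (a != 0), untransformed response."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(8), 2)
    values = rng.normal(0, 1, 16) + np.repeat(rng.normal(0, 1, 8), 2)
    a, b = rng.uniform(0.5, 3.0), rng.uniform(-5, 5)
    for fit in (anova_repeatability, reml_repeatability):
        r1 = fit(values, groups).r
        r2 = fit(a * values + b, groups).r
        assert r2 == pytest.approx(r1, abs=1e-7)


def test_model_from_dataframe_applies_transformation():
    df = pd.DataFrame({"individual_id": TOY_GROUPS, "v": np.square(TOY_VALUES)})
    res = RepeatabilityModel.from_dataframe(df, value="v", transformation="sqrt").fit("anova")
    assert res.r == pytest.approx(8.75 / 9.25)
    assert "sqrt" in res.summary()


# ---------------------------------------------------------------------------
# bootstrap CI


def test_bootstrap_deterministic_under_seed():
    res1 = reml_repeatability(TOY_VALUES, TOY_GROUPS)
    res2 = reml_repeatability(TOY_VALUES, TOY_GROUPS)
    assert res1.bootstrap_ci(seed=5, n_boot=200) == res2.bootstrap_ci(seed=5, n_boot=200)
    assert res1.bootstrap_ci(seed=6, n_boot=200) != res1.bootstrap_ci(seed=5, n_boot=200)


def test_bootstrap_collapses_at_r_one():
    res = anova_repeatability([2.0, 2.0, 5.0, 5.0, 9.0, 9.0], TOY_GROUPS)
    lo, hi = res.bootstrap_ci(seed=1, n_boot=100)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_ci_bounds_ordered_and_in_unit_interval():
    res = reml_repeatability(TOY_VALUES, TOY_GROUPS)
    lo, hi = res.bootstrap_ci(seed=2, n_boot=500)
    assert 0.0 <= lo <= hi <= 1.0
    assert res.n_boot == 500 and res.seed == 2


def test_bootstrap_rejects_tiny_n_boot():
    res = reml_repeatability(TOY_VALUES, TOY_GROUPS)
    with pytest.raises(InputDataError):
        res.bootstrap_ci(seed=1, n_boot=1)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_and_reversed():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert spearman(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman(x, -x) == pytest.approx(-1.0)


def test_spearman_hand_example():
    assert spearman([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)


def test_spearman_constant_vector_is_nan():
    assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def test_spearman_exhaustive_permutations():
    """Matches the brute-force mid-rank oracle on every permutation, n <= 5."""
    for n in (3, 4, 5):
        x = np.arange(n, dtype=float)
        for perm in itertools.permutations(range(n)):
            y = np.array(perm, dtype=float)
            assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)


def test_spearman_with_ties_matches_oracle(rng):
    for n in (6, 7, 8):
        for _ in range(200):
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)


def test_spearman_ci_monotone_data_upper_is_one():
    x = np.arange(10.0)
    res = spearman_bootstrap_ci(x, x**3, seed=0, n_boot=200)
    assert res.rho == pytest.approx(1.0)
    assert res.ci_high == pytest.approx(1.0)
    assert res.significant


def test_spearman_ci_deterministic(rng):
    x, y = rng.normal(size=20), rng.normal(size=20)
    r1 = spearman_bootstrap_ci(x, y, seed=9, n_boot=300)
    r2 = spearman_bootstrap_ci(x, y, seed=9, n_boot=300)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


def test_spearman_ci_coverage_bivariate_normal():
    """Pairs-bootstrap 95% CI covers the true rank correlation ~95% of the
    time for bivariate-normal samples (n = 30 pairs)."""
    rho_pearson = 0.5
    true_spearman = 6.0 / np.pi * np.arcsin(rho_pearson / 2.0)
    rng = np.random.default_rng(2024)
    cov = [[1.0, rho_pearson], [rho_pearson, 1.0]]
    hits = 0
    reps = 200
    for _ in range(reps):
        xy = rng.multivariate_normal([0, 0], cov, size=30)
        seed = int(rng.integers(2**31))
        res = spearman_bootstrap_ci(xy[:, 0], xy[:, 1], seed=seed, n_boot=500)
        hits += res.ci_low <= true_spearman <= res.ci_high
    assert hits / reps == pytest.approx(0.95, abs=0.05)


# ---------------------------------------------------------------------------
# correlation matrix and report


def _toy_metrics_table(rng, n_ind=12):
    ids = [f"i{k}" for k in range(n_ind)]
    rows = []
    for trial in (1, 2):
        speed = rng.lognormal(1.0, 0.3, n_ind)
        rows += [
            {
                "individual_id": ids[k],
                "trial_number": trial,
                "total_distance": speed[k] * 600,
                "translational_velocity": speed[k],
                "total_rotation": rng.normal(1000, 50),
                "rotational_velocity": rng.lognormal(0.0, 0.1),
                "sinuosity": rng.uniform(0.01, 0.2),
                "straightness": speed[k] * 0.2 + rng.normal(0, 0.01),
            }
            for k in range(n_ind)
        ]
    return pd.DataFrame(rows)


def test_correlation_matrix_symmetry_and_diagonal(rng):
    table = _toy_metrics_table(rng)
    mat = correlation_matrix(table, trial_number=1, n_boot=100, seed=3)
    frame = mat.rho
    np.testing.assert_allclose(frame.to_numpy(), frame.to_numpy().T)
    np.testing.assert_allclose(np.diag(frame.to_numpy()), 1.0)
    # straightness is constructed from velocity: strongly monotone dependence
    assert abs(mat.results[("translational_velocity", "straightness")].rho) > 0.8
    assert "Spearman" in mat.summary()


def test_between_trial_correlation_alignment(rng):
    table = _toy_metrics_table(rng)
    res = between_trial_correlation(table, "total_rotation", n_boot=100, seed=4)
    assert res.n_pairs == 12
    assert -1.0 <= res.rho <= 1.0


def test_repeatability_report_structure(rng):
    table = _toy_metrics_table(rng)
    report = repeatability_report(table, estimator="anova", n_boot=100, seed=5)
    assert set(report["metrics"]) == {
        "total_distance",
        "translational_velocity",
        "total_rotation",
        "rotational_velocity",
        "sinuosity",
        "straightness",
    }
    entry = report["metrics"]["total_distance"]
    assert entry["transformation"] == "sqrt"
    assert 0.0 <= entry["r"] <= 1.0
    assert entry["ci_low"] <= entry["r"] + 1e-9
    assert "between_trial_spearman" in entry
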