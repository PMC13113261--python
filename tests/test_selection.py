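"""Effect sizes, rank tests, unit aggregation and the threshold sweep."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import facesym as fs
from facesym.errors import (
    AggregationError,
    IntegrityError,
    SelectionError,
    UndefinedStatisticError,
)
from facesym.selection import eta_squared_matrix


# ---------------------------------------------------------------------------
# eta-squared
# ---------------------------------------------------------------------------


def test_eta_squared_hand_case():
    # SS_between = 4, SS_total = 5 -> 0.8
    assert fs.eta_squared([1, 2, 3, 4], ["a", "a", "b", "b"]) == pytest.approx(
        0.8, abs=1e-12
    )


def test_eta_squared_edge_cases():
    assert fs.eta_squared([2, 4, 2, 4], ["a", "a", "b", "b"]) == 0.0  # equal means
    assert fs.eta_squared([1, 1, 5, 5], ["a", "a", "b", "b"]) == 1.0  # pure between
    assert fs.eta_squared([3, 3, 3, 3], ["a", "a", "b", "b"]) == 0.0  # SS_total = 0
    with pytest.raises(UndefinedStatisticError):
        fs.eta_squared([1, 2, 3], ["a", "a", "a"])


def _brute_force_eta2(values, groups):
    values = np.asarray(values, float)
    grand = values.mean()
    ss_total = sum((v - grand) ** 2 for v in values)
    ss_between = 0.0
    for lab in set(groups):
        sub = [v for v, g in zip(values, groups) if g == lab]
        ss_between += len(sub) * (np.mean(sub) - grand) ** 2
    return ss_between / ss_total


def test_eta_squared_equals_brute_force_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(4, 50))
        k = int(rng.integers(2, 6))
        groups = rng.integers(0, k, n)
        if len(np.unique(groups)) < 2:
            continue
        values = rng.normal(0, 1, n) + 0.5 * groups
        expected = _brute_force_eta2(values, groups)
        assert fs.eta_squared(values, groups) == pytest.approx(expected, abs=1e-12)
        # vectorised path agrees with the scalar one
        X = np.column_stack([values, values * 2 + 1])
        mat = eta_squared_matrix(X, groups)
        assert mat[0] == pytest.approx(expected, abs=1e-12)


def test_eta_squared_matches_pingouin_anova(rng):
    pingouin = pytest.importorskip("pingouin")
    for _ in range(5):
        n = 40
        groups = rng.integers(0, 4, n)
        values = rng.normal(0, 1, n) + 0.7 * groups
        df = pd.DataFrame({"y": values, "g": groups})
        np2 = pingouin.anova(data=df, dv="y", between="g")["np2"].iloc[0]
        assert fs.eta_squared(values, groups) == pytest.approx(np2, abs=1e-10)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_kruskal_wallis_hand_case_no_ties():
    res = fs.kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
    assert res.statistic == pytest.approx(2.4, abs=1e-12)
    assert res.df == 1


def _brute_force_kw(values, groups):
    """Rank-formula H with tie correction, written independently."""
    values = np.asarray(values, float)
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = values[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    h = 0.0
    for lab in set(groups):
        sel = np.asarray([g == lab for g in groups])
        h += sel.sum() * (ranks[sel].mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def test_kruskal_wallis_equals_rank_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(6, 40))
        k = int(rng.integers(2, 5))
        groups = rng.integers(0, k, n)
        if len(np.unique(groups)) < 2:
            continue
        values = rng.integers(0, 8, n).astype(float)  # ties are frequent
        if np.ptp(values) == 0:
            continue
        res = fs.kruskal_wallis(values, groups)
        assert res.statistic == pytest.approx(_brute_force_kw(values, groups), abs=1e-12)
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, res.df), abs=1e-12
        )


def test_kruskal_wallis_invariant_under_monotone_transform(rng):
    values = rng.normal(0, 1, 30)
    groups = rng.integers(0, 3, 30)
    h1 = fs.kruskal_wallis(values, groups).statistic
    h2 = fs.kruskal_wallis(np.exp(values), groups).statistic
    h3 = fs.kruskal_wallis(values**3, groups).statistic
    assert h1 == pytest.approx(h2, abs=1e-12)
    assert h1 == pytest.approx(h3, abs=1e-12)


def test_kruskal_wallis_degenerate_and_separated():
    res = fs.kruskal_wallis([2.0] * 6, ["a", "a", "a", "b", "b", "b"])
    assert res.statistic == 0.0 and res.p_value == 1.0
    values = np.concatenate([np.linspace(0, 1, 12), np.linspace(100, 101, 12)])
    sep = fs.kruskal_wallis(values, ["a"] * 12 + ["b"] * 12)
    assert sep.p_value < 0.001


def test_kruskal_wallis_null_calibration_quick():
    """Type-I error near alpha on a small seeded null (full 10k-rep check
    lives in the acceptance suite)."""
    rng = np.random.default_rng(11)
    rejections = 0
    reps = 1500
    groups = np.repeat([0, 1, 2], 8)
    for _ in range(reps):
        values = rng.normal(0, 1, groups.size)
        if fs.kruskal_wallis(values, groups).p_value < 0.05:
            rejections += 1
    assert abs(rejections / reps - 0.05) < 0.02


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_spearman_perfect_monotone():
    assert fs.spearman([1, 2, 3], [4, 5, 6]).statistic == pytest.approx(1.0)
    assert fs.spearman([1, 2, 3], [6, 5, 4]).statistic == pytest.approx(-1.0)


def test_spearman_equals_pearson_of_ranks(rng):
    for _ in range(100):
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 10, n).astype(float)
        y = rng.integers(0, 10, n).astype(float) + 0.3 * x
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho = fs.spearman(x, y).statistic
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(expected, abs=1e-12)


def test_spearman_undefined_for_constant_input():
    with pytest.raises(UndefinedStatisticError):
        fs.spearman([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# unit aggregation
# ---------------------------------------------------------------------------


def _angle_df(datasets):
    """datasets: dict dataset_id -> (patient_id, dict expr -> theta list)."""
    rows = []
    for ds, (pid, by_expr) in datasets.items():
        for expr, theta in by_expr.items():
            rows.append([pid, ds, 1, expr, 0.0, 0.0, *theta])
    n_pairs = len(next(iter(next(iter(datasets.values()))[1].values())))
    cols = ["patient_id", "dataset_id", "session_order", "expression_id",
            "rotation_deg", "midline_slope"] + [f"theta_{i}" for i in range(n_pairs)]
    return pd.DataFrame(rows, columns=cols)


def _grades(rows):
    return pd.DataFrame(rows, columns=["dataset_id", "patient_id",
                                       "stennert_rest", "stennert_move"])


def test_session_unit_is_mean_absolute_over_nine_expressions():
    adf = _angle_df({"D0": ("P0", {e: [float(e)] for e in range(1, 10)})})
    grades = _grades([("D0", "P0", 1, 2)])
    U, ug = fs.unit_deviations(adf, grades, unit="session")
    assert U.iloc[0, 0] == pytest.approx(5.0)  # mean of 1..9
    assert list(ug["stennert_move"]) == [2]


def test_patient_unit_pools_sessions_with_equal_grades():
    adf = pd.concat([
        _angle_df({"D0": ("P0", {e: [2.0] for e in range(1, 10)})}),
        _angle_df({"D1": ("P0", {e: [4.0] for e in range(1, 10)})}),
    ], ignore_index=True)
    grades = _grades([("D0", "P0", 1, 2), ("D1", "P0", 1, 2)])
    U, ug = fs.unit_deviations(adf, grades, unit="patient")
    assert len(U) == 1
    assert U.iloc[0, 0] == pytest.approx(3.0)


def test_patient_unit_rejects_conflicting_grades():
    adf = pd.concat([
        _angle_df({"D0": ("P0", {e: [2.0] for e in range(1, 10)})}),
        _angle_df({"D1": ("P0", {e: [4.0] for e in range(1, 10)})}),
    ], ignore_index=True)
    grades = _grades([("D0", "P0", 1, 2), ("D1", "P0", 3, 5)])
    with pytest.raises(AggregationError, match="session"):
        fs.unit_deviations(adf, grades, unit="patient")


def test_ungraded_datasets_are_excluded_with_logged_count(caplog):
    datasets = {f"D{i}": (f"P{i}", {e: [1.0] for e in range(1, 10)}) for i in range(5)}
    adf = _angle_df(datasets)
    grades = _grades([(f"D{i}", f"P{i}", 1, 2) for i in range(3)])
    with caplog.at_level(logging.INFO):
        U, ug = fs.unit_deviations(adf, grades)
    assert len(U) == 3
    assert any("2 of 5" in m for m in caplog.messages)


def test_grade_file_validation(tmp_path):
    bad = tmp_path / "grades.csv"
    _grades([("D0", "P0", 9, 2)]).to_csv(bad, index=False)
    with pytest.raises(IntegrityError):
        fs.read_grades(bad)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def benchmark_sweep():
    import facesym.synthetic as syn

    cfg = syn.recovery_benchmark_config(rng_seed=1)
    records, grades, truth = fs.generate_cohort(cfg)
    reg = fs.load_registry("dense-225")
    adf = fs.angle_table(records, reg)
    gdf = pd.DataFrame([g.__dict__ for g in grades])
    U, ug = fs.unit_deviations(adf, gdf)
    return fs.threshold_sweep(U, ug), truth


def test_subset_size_is_non_increasing_and_nested(benchmark_sweep):
    sweep, truth = benchmark_sweep
    sizes = sweep.table["n_pairs"].to_numpy()
    assert np.all(np.diff(sizes) <= 0)
    # nestedness: S(t2) subset of S(t1) for t2 > t1
    er, em = sweep.eta2_rest, sweep.eta2_move
    s1 = set(np.flatnonzero((er > 0.05) & (em > 0.05)))
    s2 = set(np.flatnonzero((er > 0.2) & (em > 0.2)))
    assert s2 <= s1


def test_planted_subset_is_recovered(benchmark_sweep):
    sweep, truth = benchmark_sweep
    planted = set(truth.informative_pairs)
    chosen = set(sweep.chosen_subset)
    precision = len(planted & chosen) / len(chosen)
    recall = len(planted & chosen) / len(planted)
    assert precision >= 0.9
    assert recall >= 0.9
    assert sweep.min_eta2 >= sweep.chosen_threshold
    assert sweep.discriminative


def test_null_cohort_is_flagged_non_discriminative(rng):
    # deviations independent of grades: selection must not claim signal
    n_units, n_pairs = 40, 30
    X = np.abs(rng.normal(1.0, 0.3, (n_units, n_pairs)))
    y = np.column_stack([rng.integers(0, 5, n_units), rng.integers(0, 7, n_units)])
    sel = fs.EtaThresholdPairSelector()
    sel.fit(X, y)
    assert not sel.sweep_.discriminative or min(
        sel.sweep_.table.dropna()["p_rest"].min(),
        sel.sweep_.table.dropna()["p_move"].min(),
    ) >= 0.001  # at most a marginal fluke, never strong separation


def test_sweep_with_no_nonempty_subset_raises():
    X = np.ones((10, 4))  # SS_total = 0 -> eta2 = 0 everywhere, strict > fails
    y = np.column_stack([np.arange(10) % 5, np.arange(10) % 7])
    with pytest.raises(SelectionError):
        fs.EtaThresholdPairSelector().fit(X, y)


def test_selector_follows_sklearn_conventions(rng):
    X = np.abs(rng.normal(1.0, 0.3, (30, 12)))
    X[:, :4] += 0.5 * np.repeat(np.arange(5), 6)[:, None]
    y = np.column_stack([np.repeat(np.arange(5), 6) % 5,
                         np.repeat(np.arange(5), 6)])
    sel = fs.EtaThresholdPairSelector(objective="min")
    assert clone(sel).get_params()["objective"] == "min"
    sel.fit(X, y)
    assert sel.support_.shape == (12,)
    Xt = sel.transform(X)
    assert Xt.shape == (30, int(sel.support_.sum()))
    assert sel.get_support(indices=True).tolist() == sel.sweep_.chosen_subset


# ---------------------------------------------------------------------------
# correlation report
# ---------------------------------------------------------------------------


def test_region_correlations_follow_generator_ordering(default_cohort, default_angles,
                                                       dense_registry):
    """Mouth asymmetry is amplified for mouth expressions, so the mouth
    subset must correlate more strongly than the eye subset there."""
    _, grades_df, _ = default_cohort
    sdf = fs.score_table(default_angles, dense_registry)
    rep = fs.correlation_report(sdf, grades_df)

    def rho(subset, expr):
        cell = rep[(rep.subset == subset) & (rep.condition == "move")
                   & (rep.expression == expr)]
        return cell["rho"].iloc[0]

    for expr in ("6", "7"):
        assert rho("mouth", expr) > rho("eye", expr)
    assert rho("91", "all") > 0.5


def test_shuffled_grades_kill_correlations(default_cohort, default_angles,
                                           dense_registry):
    records, grades_df, _ = default_cohort
    sdf = fs.score_table(default_angles, dense_registry)
    scores = sdf[(sdf.subset_name == "91") & (sdf.expression_id == "all")]
    scores = scores.set_index("dataset_id")["score_deg"]
    merged = grades_df.set_index("dataset_id").join(scores).dropna()
    rng = np.random.default_rng(2)
    pvals = []
    rhos = []
    for _ in range(300):
        perm = rng.permutation(merged["stennert_move"].to_numpy())
        res = fs.spearman(merged["score_deg"], perm)
        pvals.append(res.p_value)
        rhos.append(abs(res.statistic))
    frac = np.mean(np.asarray(pvals) < 0.05)
    assert abs(frac - 0.05) < 0.05
    assert np.median(rhos) < 0.2


def test_constant_scores_yield_na_cells_not_errors(default_cohort):
    _, grades_df, _ = default_cohort
    sdf = pd.DataFrame({
        "patient_id": grades_df["patient_id"],
        "dataset_id": grades_df["dataset_id"],
        "session_order": 1,
        "expression_id": "all",
        "subset_name": "91",
        "n_pairs": 91,
        "score_deg": 1.0,  # constant
        "rotation_deg": 0.0,
        "midline_slope": 0.0,
    })
    rep = fs.correlation_report(sdf, grades_df, subsets=("91",))
    cell = rep[(rep.subset == "91") & (rep.expression == "all")
               & (rep.condition == "move")]
    assert np.isnan(cell["rho"].iloc[0])
    assert "undefined" in cell["note"].iloc[0]
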