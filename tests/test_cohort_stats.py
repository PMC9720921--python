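import itertools

import numpy as np
import pandas as pd
import pytest

from hiikit import (
    CohortParams,
    fit_logistic,
    hosmer_lemeshow,
    icc_oneway,
    roc_youden,
    select_for_multivariate,
    simulate_cohort,
    summarize_baseline,
)
from hiikit.cohort_stats import SeparationError


# --- simulator --------------------------------------------------------------

def test_simulator_is_deterministic():
    a = simulate_cohort(50, seed=42)
    b = simulate_cohort(50, seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_simulator_null_model_rate():
    """With only an intercept, prevalence matches logistic(intercept)."""
    params = CohortParams(coefficients={"intercept": -1.0})
    df = simulate_cohort(5000, params, seed=0)
    target = 1 / (1 + np.exp(1.0))
    se = np.sqrt(target * (1 - target) / 5000)
    assert abs(df["expansion"].mean() - target) < 4 * se


def test_simulator_ranges():
    df = simulate_cohort(500, seed=1)
    assert df["gcs"].between(3, 15).all()
    assert (df["baseline_volume_mL"] > 0).all()
    assert (df["hii"] > 100).all()
    assert set(df["expansion"].unique()) <= {0, 1}


def test_simulator_rejects_bad_params():
    with pytest.raises(ValueError):
        simulate_cohort(0)
    with pytest.raises(ValueError):
        CohortParams(p_female=1.5)
    with pytest.raises(ValueError):
        CohortParams(coefficients={"hii": 0.2})  # no intercept
    with pytest.raises(ValueError):
        simulate_cohort(10, CohortParams(coefficients={"intercept": 0, "nonexistent": 1.0}))


# --- baseline summary -------------------------------------------------------

def _mini_table(values0, values1, var="hii"):
    n0, n1 = len(values0), len(values1)
    return pd.DataFrame(
        {var: list(values0) + list(values1), "expansion": [0] * n0 + [1] * n1}
    )


def test_mann_whitney_exact_third():
    """{1,2} vs {3,4}: exact two-sided p = 1/3 by enumerating all C(4,2) splits."""
    # oracle: of the 6 equally likely label assignments, 2 give U as extreme
    ranks = [1, 2, 3, 4]
    u_observed = 0  # all of group 0 below group 1
    extreme = sum(
        1
        for combo in itertools.combinations(ranks, 2)
        if min(sum(a < b for a in combo for b in set(ranks) - set(combo)),
               sum(a > b for a in combo for b in set(ranks) - set(combo))) <= u_observed
    )
    assert extreme / 6 == pytest.approx(1 / 3)

    table = summarize_baseline(_mini_table([1.0, 2.0], [3.0, 4.0]))
    row = table[table.variable == "hii"].iloc[0]
    assert row.test == "Mann-Whitney U"
    assert row.p_value == pytest.approx(1 / 3)


def test_identical_groups_p_one():
    table = summarize_baseline(_mini_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
    assert table.iloc[0].p_value == pytest.approx(1.0)


def test_balanced_binary_flag_chi_square_p_one():
    df = pd.DataFrame(
        {"female": [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5,
         "expansion": [0] * 10 + [1] * 10}
    )
    table = summarize_baseline(df)
    row = table[table.variable == "female"].iloc[0]
    assert row.p_value == pytest.approx(1.0)


def test_normality_gate_selects_presentation():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "age": np.concatenate([rng.normal(60, 10, 40), rng.normal(65, 10, 40)]),
            "baseline_volume_mL": np.concatenate(
                [rng.lognormal(2, 1, 40), rng.lognormal(2.5, 1, 40)]
            ),
            "expansion": [0] * 40 + [1] * 40,
        }
    )
    table = summarize_baseline(df).set_index("variable")
    assert table.loc["age"].test == "t-test"
    assert table.loc["baseline_volume_mL"].test == "Mann-Whitney U"


def test_zero_variance_group_flagged():
    table = summarize_baseline(_mini_table([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]))
    assert table.iloc[0].flag != ""


# --- logistic regression ----------------------------------------------------

def _two_by_two(a, b, c, d):
    """x=1: a events, b non-events; x=0: c events, d non-events."""
    x = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"x": x, "expansion": y})


def test_logistic_or_equals_cross_product_ratio():
    df = _two_by_two(10, 5, 5, 10)
    res = fit_logistic(df, predictors=["x"])
    o, lo, hi = res.odds_ratios["x"]
    assert o == pytest.approx(4.0, abs=1e-6)  # ad/bc = 10*10/(5*5)
    assert lo <= o <= hi


@pytest.mark.parametrize("a,b,c,d", [(7, 13, 9, 21), (3, 17, 12, 18), (25, 5, 10, 10)])
def test_logistic_2x2_reducible_property(a, b, c, d):
    res = fit_logistic(_two_by_two(a, b, c, d), predictors=["x"])
    assert res.odds_ratios["x"][0] == pytest.approx(a * d / (b * c), abs=1e-6)


def test_logistic_duplicate_predictor_rejected():
    df = _two_by_two(10, 5, 5, 10)
    df["x_copy"] = df["x"]
    with pytest.raises(ValueError, match="collinear"):
        fit_logistic(df, predictors=["x", "x_copy"])


def test_logistic_single_class_rejected():
    df = _two_by_two(10, 5, 5, 10)
    df["expansion"] = 1
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(df, predictors=["x"])


@pytest.mark.filterwarnings("ignore::RuntimeWarning")  # overflow inside the diverging fit
def test_logistic_complete_separation_rejected():
    df = pd.DataFrame({"x": np.arange(20.0), "expansion": [0] * 10 + [1] * 10})
    with pytest.raises(SeparationError):
        fit_logistic(df, predictors=["x"])


def test_parameter_recovery_bias_shrinks_with_n():
    """simulate → fit recovers the generating coefficient, bias shrinking with n."""
    errors = {}
    for n in (500, 2000):
        errs = []
        for seed in range(10):
            df = simulate_cohort(n, seed=seed)
            res = fit_logistic(df, predictors=["hii"])
            errs.append(res.coefficients["hii"] - 0.18)
        errors[n] = np.abs(np.mean(errs))
    assert errors[2000] < 0.02
    assert errors[2000] <= errors[500] + 0.005


# --- variable selection -----------------------------------------------------

def test_selection_threshold_and_order():
    pvals = {"age": 0.072, "volume": 0.008, "gcs": 0.023, "hii": 0.0005}
    assert select_for_multivariate(pvals) == ["age", "volume", "gcs", "hii"]
    assert select_for_multivariate({"a": 0.10}) == []  # strict <
    assert select_for_multivariate({}) == []


# --- Hosmer-Lemeshow --------------------------------------------------------

def test_hosmer_lemeshow_perfect_calibration():
    """Observed equals expected in every decile → statistic 0, p = 1."""
    pis = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.5, 0.6, 0.7, 0.8, 0.9])
    p = np.repeat(pis, 10)
    y = np.concatenate([
        np.r_[np.ones(int(round(pi * 10))), np.zeros(10 - int(round(pi * 10)))]
        for pi in pis
    ])
    stat, pval, groups = hosmer_lemeshow(p, y, g=10)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert pval == pytest.approx(1.0)
    assert groups == 10


def test_hosmer_lemeshow_preconditions():
    with pytest.raises(ValueError):
        hosmer_lemeshow([0.5] * 5, [1, 0, 1, 0, 1], g=10)  # g > n
    with pytest.raises(ValueError):
        hosmer_lemeshow([0.5] * 5, [1, 0, 1, 0, 1], g=1)


def test_hosmer_lemeshow_detects_gross_miscalibration():
    rng = np.random.default_rng(3)
    p = np.full(400, 0.1)
    y = rng.random(400) < 0.9  # wildly miscalibrated
    stat, pval, _ = hosmer_lemeshow(p, y)
    assert pval < 1e-6


# --- ROC / Youden -----------------------------------------------------------

def brute_force_auc(scores, labels):
    """Pair counting over all positive-negative pairs, ties counted half."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(0.5 for p in pos for q in neg if p == q)
    return (wins + ties) / (len(pos) * len(neg))


def test_roc_perfect_separation():
    res = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
    assert res.auc == pytest.approx(1.0)
    assert 2 < res.youden_cutoff <= 3
    assert res.sensitivity_at_cutoff == 1.0 and res.specificity_at_cutoff == 1.0


def test_roc_pair_counting_example():
    assert brute_force_auc([3, 1, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert roc_youden([3, 1, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)


def test_roc_trapezoid_equals_pair_counting_exhaustively():
    """Trapezoidal AUC = pair-counting AUC on random tied instances, n <= 50."""
    rng = np.random.default_rng(0)
    for _ in range(60):
        n = rng.integers(4, 51)
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert roc_youden(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_roc_permutation_null():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=200)
    aucs = []
    for _ in range(100):
        labels = rng.permutation([0] * 100 + [1] * 100)
        aucs.append(roc_youden(scores, labels).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_youden([1, 2, 3], [1, 1, 1])


def test_roc_youden_tie_breaks_to_lowest_cutoff():
    # two cutoffs reach J = 0.5; the lower one must be reported
    scores = [1, 2, 3, 4]
    labels = [0, 1, 0, 1]
    res = roc_youden(scores, labels)
    j = res.tpr - res.fpr
    best = j.max()
    qualifying = res.thresholds[np.isfinite(res.thresholds) & np.isclose(j, best)]
    assert res.youden_cutoff == qualifying.min()


# --- ICC --------------------------------------------------------------------

def test_icc_perfect_agreement():
    grid = np.tile(np.arange(5.0)[:, None], (1, 2))
    assert icc_oneway(grid).icc == pytest.approx(1.0)


def test_icc_hand_anova_grid():
    res = icc_oneway([[1, 2], [2, 3], [3, 4]])
    assert res.ms_between == pytest.approx(2.0)
    assert res.ms_within == pytest.approx(0.5)
    assert res.icc == pytest.approx(0.6)


def test_icc_matches_pingouin_icc1():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    grid = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
    res = icc_oneway(grid)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": grid.ravel(),
        }
    )
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    icc1 = ref.loc[ref.Type == "ICC(1,1)", "ICC"].iloc[0]
    assert res.icc == pytest.approx(icc1, abs=1e-9)


def test_icc_shift_invariance_and_noise_monotonicity():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(50, 1)) * 3
    grid = np.hstack([base, base + 1.0])  # constant rater offset
    shifted = icc_oneway(grid + 10.0).icc
    assert icc_oneway(grid).icc == pytest.approx(shifted)
    iccs = []
    for noise in (0.5, 1.5, 3.0):
        noisy = np.hstack([base, base + rng.normal(0, noise, size=base.shape)])
        iccs.append(icc_oneway(noisy).icc)
    assert iccs[0] > iccs[1] > iccs[2]


def test_icc_permutation_null():
    rng = np.random.default_rng(6)
    vals = []
    for _ in range(100):
        col = rng.normal(size=50)
        grid = np.column_stack([rng.permutation(col), rng.permutation(col)])
        vals.append(icc_oneway(grid).icc)
    assert abs(np.mean(vals)) < 0.1


def test_icc_constant_grid_rejected():
    with pytest.raises(ValueError):
        icc_oneway(np.ones((5, 2)))
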