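"""Grouping, sub-scores, group comparisons, correlation, regression, ROC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from posturekit import (
    assign_groups,
    auc_band,
    compare_groups,
    correlation_band,
    roc_youden,
    simple_regression,
    spearman,
    updrs_subscores,
)

# ---------------------------------------------------------------------------
# grouping and sub-scores


@pytest.mark.parametrize("item,expected", [(0, "PwtPA"), (1, "PwtPA"), (2, "PwPA"), (4, "PwPA")])
def test_posture_item_grouping_boundary_at_two(item, expected):
    df = pd.DataFrame(
        [{"subject_id": "p1", "group": "PD", "updrs_3_13": item},
         {"subject_id": "h1", "group": "HC", "updrs_3_13": np.nan}]
    )
    out = assign_groups(df)
    assert out.loc[out.subject_id == "p1", "group"].item() == expected
    assert out.loc[out.subject_id == "h1", "group"].item() == "HC"  # unchanged


def test_assign_groups_missing_item_lists_subjects():
    df = pd.DataFrame(
        [{"subject_id": "p1", "group": "PD", "updrs_3_13": 2},
         {"subject_id": "p2", "group": "PD", "updrs_3_13": np.nan}]
    )
    with pytest.raises(ValueError, match="p2"):
        assign_groups(df)


def test_subscores_sum_their_items():
    items = {k: 0.0 for k in
             ("3.4", "3.5", "3.6", "3.7", "3.8", "3.9", "3.14",
              "3.10", "3.11", "3.15", "3.16", "3.17", "3.18")}
    assert updrs_subscores(items) == {"tremor": 0, "bradykinesia": 0, "gait": 0}
    items.update({"3.15": 1, "3.16": 2, "3.17": 0, "3.18": 1})
    assert updrs_subscores(items)["tremor"] == 4
    items.update({"3.10": 2, "3.11": 1})
    assert updrs_subscores(items)["gait"] == 3


def test_subscores_missing_item_named():
    complete = {k: 0 for k in
                ("3.4", "3.5", "3.6", "3.7", "3.8", "3.9", "3.14",
                 "3.10", "3.11", "3.15", "3.16", "3.17", "3.18")}
    del complete["3.14"]
    with pytest.raises(ValueError, match=r"3\.14"):
        updrs_subscores(complete)


# ---------------------------------------------------------------------------
# group comparisons


def _table(a, b, groups=("A", "B"), variable="y"):
    return pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(len(a) + len(b))],
         "group": [groups[0]] * len(a) + [groups[1]] * len(b),
         variable: list(a) + list(b)}
    )


def test_identical_groups_never_significant():
    df = _table([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    result = compare_groups(df, "y", ("A", "B"))
    assert result.p == pytest.approx(1.0, abs=1e-9)
    assert not result.significant


def test_mann_whitney_matches_exact_enumeration_oracle():
    """Separated ranks: two-tailed exact p equals full enumeration over rank splits."""
    df = _table([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
    result = compare_groups(df, "y", ("A", "B"), test="mann-whitney")
    assert result.test == "mann-whitney"
    # enumerate all C(10,5) assignments of ranks to group A, count U <= observed
    observed_u = 0.0  # no group-A value exceeds a group-B value
    ranks = range(1, 11)
    count_le = sum(
        1
        for combo in itertools.combinations(ranks, 5)
        if sum(combo) - 5 * 6 / 2 <= observed_u
    )
    exact_one_sided = count_le / math.comb(10, 5)
    assert exact_one_sided == pytest.approx(1 / 252)
    assert result.p == pytest.approx(2 * exact_one_sided)


def test_normal_groups_take_t_test(rng):
    df = _table(rng.normal(0, 1, 40), rng.normal(0.2, 1, 40))
    result = compare_groups(df, "y", ("A", "B"))
    assert result.test == "t"
    assert result.normal == (True, True)


def test_skewed_groups_routed_to_mann_whitney(rng):
    df = _table(rng.exponential(1, 60) ** 2, rng.exponential(1.5, 60) ** 2)
    result = compare_groups(df, "y", ("A", "B"))
    assert result.test == "mann-whitney"
    assert result.normal != (True, True)


def test_gender_contingency_chi_square():
    # 48/22 male/female in PD vs 13/17 in HC: Pearson chi-square p = 0.018.
    rows = (
        [{"group": "PD", "gender": "M"}] * 48 + [{"group": "PD", "gender": "F"}] * 22
        + [{"group": "HC", "gender": "M"}] * 13 + [{"group": "HC", "gender": "F"}] * 17
    )
    df = pd.DataFrame(rows)
    df["subject_id"] = [f"s{i}" for i in range(len(df))]
    result = compare_groups(df, "gender", ("PD", "HC"))
    assert result.test == "chi-square"
    assert result.significant
    assert round(result.p, 3) == 0.018


def test_comparison_p_invariant_under_affine_transform(rng):
    a, b = rng.normal(0, 1, 15), rng.normal(1, 2, 15)
    p0 = compare_groups(_table(a, b), "y", ("A", "B")).p
    p1 = compare_groups(_table(3 * a + 7, 3 * b + 7), "y", ("A", "B")).p
    assert p1 == pytest.approx(p0, rel=1e-6)


def test_compare_groups_requires_observations():
    df = _table([1.0], [2.0, 3.0])
    with pytest.raises(ValueError, match=">= 2 observations"):
        compare_groups(df, "y", ("A", "B"))


# ---------------------------------------------------------------------------
# Spearman correlation


def test_perfect_monotone_correlation():
    r = spearman([1, 2, 3, 4, 5], [10, 100, 1000, 10000, 100000])
    assert r.rs == pytest.approx(1.0)
    assert r.band == "very strong"


def test_spearman_matches_rank_pearson_oracle():
    x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
    oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
    assert oracle == pytest.approx(0.8)
    assert spearman(x, y).rs == pytest.approx(oracle)


def test_spearman_random_data_matches_rank_pearson(rng):
    x = rng.normal(size=60)
    y = rng.normal(size=60) + 0.5 * x
    oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
    assert spearman(x, y).rs == pytest.approx(oracle, abs=1e-12)


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = spearman(x, y).rs
    assert spearman(np.exp(x), y).rs == pytest.approx(base)
    assert spearman(x, y**3).rs == pytest.approx(base)


def test_spearman_pairwise_complete(rng):
    x = np.array([1.0, 2, 3, 4, np.nan, 6])
    y = np.array([2.0, 4, 6, 8, 10, np.nan])
    r = spearman(x, y)
    assert r.n == 4
    assert r.rs == pytest.approx(1.0)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError, match="undefined correlation"):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


@pytest.mark.parametrize(
    "rs,band",
    [(0.05, "negligible"), (0.25, "weak"), (0.573, "moderate"), (-0.573, "moderate"),
     (0.75, "strong"), (0.95, "very strong"), (0.10, "weak"), (0.40, "moderate")],
)
def test_correlation_bands(rs, band):
    assert correlation_band(rs) == band


# ---------------------------------------------------------------------------
# regression


def test_perfect_fit():
    m = simple_regression([2, 4, 6, 8], [1, 2, 3, 4])
    assert m.r2 == pytest.approx(1.0)
    assert m.adj_r2 == pytest.approx(1.0)
    assert m.std_beta == pytest.approx(1.0)
    assert m.slope == pytest.approx(2.0)


def test_null_model_adjusted_r2_can_be_negative(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    m = simple_regression(y, x)
    assert m.adj_r2 < 0.1  # about zero, possibly below
    assert m.adj_r2 == pytest.approx(1 - (1 - m.r2) * 39 / 38)


def test_adjusted_r2_closed_form_and_std_beta(rng):
    x = rng.normal(size=25)
    y = 1.5 * x + rng.normal(size=25)
    m = simple_regression(y, x)
    assert m.adj_r2 == pytest.approx(1 - (1 - m.r2) * 24 / 23, abs=1e-12)
    # in simple regression the standardized slope is the Pearson r
    assert m.std_beta == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)
    assert abs(m.std_beta) == pytest.approx(math.sqrt(m.r2), abs=1e-12)


def test_regression_constant_predictor_errors():
    with pytest.raises(ValueError, match="constant predictor"):
        simple_regression([1, 2, 3], [5, 5, 5])


# ---------------------------------------------------------------------------
# ROC / Youden


def test_perfectly_separated_scores():
    r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert r.auc == 1.0
    assert r.sensitivity == 100.0 and r.specificity == 100.0
    assert 3 < r.cutoff < 10
    assert r.youden == pytest.approx(1.0)
    assert r.band == "high"


def test_small_separable_case():
    r = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
    assert r.auc == 1.0
    assert 2 < r.cutoff < 3


def _brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _brute_force_best_j(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = -np.inf
    for thr in np.concatenate([scores - 1e-9, scores + 1e-9, [scores.min() - 1, scores.max() + 1]]):
        j = (pos >= thr).mean() + (neg < thr).mean() - 1
        best = max(best, j)
    return best


def test_roc_matches_brute_force_oracles(rng):
    scores = np.round(rng.normal(size=200), 1)  # rounding forces ties
    labels = (rng.uniform(size=200) < 0.4).astype(int)
    r = roc_youden(scores, labels)
    assert r.auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)
    assert r.youden == pytest.approx(_brute_force_best_j(scores, labels), abs=1e-12)
    # and the cut-off itself achieves that J
    pos, neg = scores[labels == 1], scores[labels == 0]
    j_at_cut = (pos >= r.cutoff).mean() + (neg < r.cutoff).mean() - 1
    assert j_at_cut == pytest.approx(r.youden)


def test_auc_equals_normalized_mann_whitney_u(rng):
    scores = rng.normal(size=150)
    labels = (rng.uniform(size=150) < 0.5).astype(int)
    u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    n1, n0 = (labels == 1).sum(), (labels == 0).sum()
    assert roc_youden(scores, labels).auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_auc_matches_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    scores = rng.normal(size=120)
    labels = (scores + rng.normal(size=120) > 0).astype(int)
    assert roc_youden(scores, labels).auc == pytest.approx(
        sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
    )


def test_label_flip_symmetry(rng):
    scores = rng.normal(size=80)
    labels = (rng.uniform(size=80) < 0.5).astype(int)
    a = roc_youden(scores, labels).auc
    b = roc_youden(-scores, 1 - labels).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_delong_interval_matches_slow_placement_computation(rng):
    scores = rng.normal(size=100) + 0.8 * (rng.uniform(size=100) < 0.5)
    labels = np.zeros(100, int)
    labels[:50] = 1
    rng.shuffle(labels)
    r = roc_youden(scores, labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
    v01 = np.array([np.mean((pos > y) + 0.5 * (pos == y)) for y in neg])
    se = math.sqrt(v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg))
    assert r.ci[0] == pytest.approx(r.auc - 1.96 * se, abs=1e-4)
    assert r.ci[1] == pytest.approx(r.auc + 1.96 * se, abs=1e-4)
    assert r.ci[0] < r.auc < r.ci[1]


def test_youden_tie_breaks_toward_higher_specificity():
    # J = 0.5 at several thresholds; the winner must not sacrifice specificity.
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0, 1, 0, 1])
    r = roc_youden(scores, labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    for thr in [0.5, 1.5, 2.5, 3.5, 4.5]:
        j = (pos >= thr).mean() + (neg < thr).mean() - 1
        if j == pytest.approx(r.youden):
            assert (neg < r.cutoff).mean() >= (neg < thr).mean() - 1e-12


def test_single_class_labels_error():
    with pytest.raises(ValueError, match="single-class labels"):
        roc_youden([1, 2, 3], [1, 1, 1])


@pytest.mark.parametrize("auc,band", [(0.65, "low"), (0.817, "moderate"), (0.95, "high"), (0.9, "moderate"), (0.7, "moderate")])
def test_auc_bands(auc, band):
    assert auc_band(auc) == band
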