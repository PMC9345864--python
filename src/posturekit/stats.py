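"""Cohort-level validation statistics.

Reproduces the clinical validation workflow around the posture index:
grouping by the MDS-UPDRS-III 3.13 posture item, motor sub-scores, group
comparisons behind a Kolmogorov-Smirnov (Lilliefors) normality gate,
Spearman correlations with conventional interpretation bands, simple
linear regression, and ROC analysis with a Youden-optimal cut-off and
DeLong confidence interval.

All tests are two-tailed with significance at p < 0.05; p-values are
reported raw (no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS, add_constant
from statsmodels.stats.diagnostic import lilliefors

ALPHA = 0.05

GROUPS = ("HC", "PwtPA", "PwPA", "PD")

#: MDS-UPDRS-III items feeding each motor sub-score.
TREMOR_ITEMS = ("3.15", "3.16", "3.17", "3.18")
BRADYKINESIA_ITEMS = ("3.4", "3.5", "3.6", "3.7", "3.8", "3.9", "3.14")
GAIT_ITEMS = ("3.10", "3.11")

#: Spearman |r_s| interpretation bands (lower edges).
CORRELATION_BANDS = (
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.40, "moderate"),
    (0.10, "weak"),
    (0.00, "negligible"),
)

#: AUC diagnostic-accuracy bands.
AUC_BANDS = ((0.9, "high"), (0.7, "moderate"), (0.0, "low"))


def correlation_band(rs: float) -> str:
    """Interpretation band for a Spearman coefficient, from |r_s|."""
    a = abs(rs)
    if not a <= 1.0:
        raise ValueError(f"|r_s| must be <= 1, got {rs}")
    for edge, name in CORRELATION_BANDS:
        if a >= edge:
            return name
    return "negligible"


def auc_band(auc: float) -> str:
    """Diagnostic-accuracy band: < 0.7 low, 0.7-0.9 moderate, > 0.9 high."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc > 0.9:
        return "high"
    if auc >= 0.7:
        return "moderate"
    return "low"


# ---------------------------------------------------------------------------
# grouping and sub-scores


def assign_groups(table: pd.DataFrame, item_col: str = "updrs_3_13") -> pd.DataFrame:
    """Split PD rows into PwPA / PwtPA by the posture item.

    Rows not labelled ``HC`` are PD rows; those with item 3.13 >= 2 become
    ``PwPA``, the rest ``PwtPA``.  HC rows pass through unchanged.
    """
    df = table.copy()
    pd_rows = df["group"] != "HC"
    missing = df.loc[pd_rows & df[item_col].isna(), "subject_id"].tolist() \
        if item_col in df.columns else df.loc[pd_rows, "subject_id"].tolist()
    if missing:
        raise ValueError(
            f"PD rows missing MDS-UPDRS-III 3.13 ({item_col}): {missing}"
        )
    item = df.loc[pd_rows, item_col].astype(float)
    bad = item[(item < 0) | (item > 4)].index
    if len(bad):
        raise ValueError(f"MDS-UPDRS-III 3.13 must be in 0..4; bad rows {list(bad)}")
    df.loc[pd_rows, "group"] = np.where(item >= 2, "PwPA", "PwtPA")
    return df


def updrs_subscores(items) -> dict[str, float]:
    """Tremor / bradykinesia / gait sub-scores as sums of their MDS-UPDRS-III items.

    ``items`` maps item ids like ``"3.15"`` to scores (laterality sub-items
    already summed per numbered item, as provided by the rater).
    """
    out = {}
    for name, ids in (
        ("tremor", TREMOR_ITEMS),
        ("bradykinesia", BRADYKINESIA_ITEMS),
        ("gait", GAIT_ITEMS),
    ):
        total = 0.0
        for item in ids:
            if item not in items:
                raise ValueError(f"missing MDS-UPDRS-III item {item}")
            total += float(items[item])
        out[name] = total
    return out


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    test: str  # "t", "mann-whitney", or "chi-square"
    statistic: float
    p: float
    significant: bool
    normal: tuple[bool, bool] | None = None


def _is_normal(x: np.ndarray) -> bool:
    """Lilliefors-corrected Kolmogorov-Smirnov normality gate at alpha = 0.05."""
    if len(x) < 4 or np.ptp(x) == 0.0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p >= ALPHA


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    groups: tuple[str, str],
    categorical: bool | None = None,
    test: str = "auto",
) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Each group passes a Kolmogorov-Smirnov (Lilliefors) normality test at
    alpha = 0.05; if both pass, Student's t test is used, otherwise the
    Mann-Whitney U test (exact p when both groups have <= 12 tie-free
    observations, normal approximation with continuity correction
    otherwise).  Categorical variables use the Pearson chi-square test on
    the contingency table, without continuity correction.  Two-tailed.
    ``test`` overrides the gate with ``"t"`` or ``"mann-whitney"``.
    """
    if test not in ("auto", "t", "mann-whitney"):
        raise ValueError(f"unknown test {test!r}")
    if variable not in table.columns:
        raise ValueError(f"variable {variable!r} not in table")
    a = table.loc[table["group"] == groups[0], variable].dropna()
    b = table.loc[table["group"] == groups[1], variable].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"variable {variable!r}: need >= 2 observations per group "
            f"(got {len(a)} vs {len(b)})"
        )
    if categorical is None:
        categorical = not (
            pd.api.types.is_numeric_dtype(a) and pd.api.types.is_numeric_dtype(b)
        )
    if categorical:
        sub = table[table["group"].isin(groups)]
        contingency = pd.crosstab(sub["group"], sub[variable])
        chi2, p, _, _ = sps.chi2_contingency(contingency, correction=False)
        return GroupComparison(
            variable, tuple(groups), "chi-square", float(chi2), float(p), p < ALPHA
        )

    x, y = a.to_numpy(float), b.to_numpy(float)
    normal = (_is_normal(x), _is_normal(y))
    chosen = test if test != "auto" else ("t" if all(normal) else "mann-whitney")
    if chosen == "t":
        stat, p = sps.ttest_ind(x, y)
    else:
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 12 and tie_free) else "asymptotic"
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        variable, tuple(groups), chosen, float(stat), float(p), p < ALPHA, normal
    )


# ---------------------------------------------------------------------------
# correlation and regression


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p: float
    n: int
    band: str


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("undefined correlation: constant vector")
    rs, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rs), float(p), len(x), correlation_band(rs))


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float  # unstandardized beta
    intercept: float
    std_beta: float  # beta on z-scored variables
    r2: float
    adj_r2: float
    p: float


def simple_regression(y, x) -> RegressionResult:
    """Ordinary least squares of y on a single predictor x.

    Standardized beta is the slope after z-scoring both variables (equal
    to the Pearson r in the one-predictor case); adjusted R-squared uses
    the one-predictor formula 1 - (1 - R^2)(n - 1)/(n - 2).  p is the
    two-tailed slope test.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    y, x = y[keep], x[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("constant predictor")
    fit = OLS(y, add_constant(x)).fit()
    r2 = float(fit.rsquared)
    slope = float(fit.params[1])
    std_beta = slope * float(np.std(x, ddof=1) / np.std(y, ddof=1)) if np.ptp(y) else 0.0
    return RegressionResult(
        n=n,
        slope=slope,
        intercept=float(fit.params[0]),
        std_beta=std_beta,
        r2=r2,
        adj_r2=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        p=float(fit.pvalues[1]),
    )


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci: tuple[float, float]  # 95% DeLong CI (normal approximation, unclipped)
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    youden: float  # sensitivity + specificity - 1, as a fraction
    band: str
    se: float = field(default=float("nan"), repr=False)
    p: float = field(default=float("nan"), repr=False)


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the empirical AUC via placement values."""
    diff = pos[:, None] - neg[None, :]
    win = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = win.mean(axis=1)  # one placement per positive
    v01 = win.mean(axis=0)  # one placement per negative
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(np.sqrt(s10 / len(pos) + s01 / len(neg)))


def roc_youden(scores, labels) -> ROCResult:
    """Empirical ROC analysis with a Youden-optimal cut-off.

    The AUC is the normalized Mann-Whitney statistic (ties counted 1/2).
    Candidate thresholds are the midpoints between adjacent distinct
    scores, plus one below the minimum and one above the maximum; a score
    equal to the threshold classifies positive.  The cut-off maximizes
    Youden's J = sensitivity + specificity - 1, ties broken toward higher
    specificity.  The 95% CI is the DeLong normal-approximation interval
    (deliberately not clipped to [0, 1]).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be paired")
    labels = labels.astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("single-class labels")

    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = float(u / (len(pos) * len(neg)))

    distinct = np.unique(scores)
    thresholds = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    sens = (pos[:, None] >= thresholds[None, :]).mean(axis=0)
    spec = (neg[:, None] < thresholds[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j == best_j)
    best = candidates[np.lexsort((thresholds[candidates], -spec[candidates]))][0]

    se = _delong_se(pos, neg)
    ci = (auc - 1.959963984540054 * se, auc + 1.959963984540054 * se)
    if se > 0:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return ROCResult(
        auc=auc,
        ci=ci,
        cutoff=float(thresholds[best]),
        sensitivity=float(100.0 * sens[best]),
        specificity=float(100.0 * spec[best]),
        youden=float(j[best]),
        band=auc_band(auc),
        se=se,
        p=p,
    )


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Theoretical AUC of two normal score distributions: Phi(dm / sqrt(s1^2+s0^2))."""
    return float(sps.norm.cdf((mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)))
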