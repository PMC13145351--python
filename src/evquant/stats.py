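"""Group comparison, ROC construction and t-test power.

The comparison follows the published test-selection rule: Shapiro-Wilk
normality per group and median-centered Levene variance homogeneity at
alpha = 0.05 gate the choice between a pooled two-sample t test and the
Mann-Whitney U test.  ROC curves sweep every observed value as a
threshold with strict-inequality classification, and the area is the
trapezoid sum  sum((FPR2 - FPR1) * (TPR2 + TPR1) / 2)  over consecutive
points — which equals the tie-adjusted rank statistic / (n_pos * n_neg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

ALPHA_ASSUMPTIONS = 0.05


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    variance_p: float
    test_used: str            # t_test | mann_whitney_u
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a, "sd_a": self.sd_a,
            "mean_b": self.mean_b, "sd_b": self.sd_b,
            "normality_p_a": self.normality_p_a,
            "normality_p_b": self.normality_p_b,
            "variance_p": self.variance_p,
            "test_used": self.test_used,
            "statistic": self.statistic, "p_value": self.p_value,
        }


def _shapiro_p(values: np.ndarray) -> float:
    if np.ptp(values) == 0:
        return 0.0  # constant sample: normality untestable, fail the gate
    return float(sps.shapiro(values).pvalue)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = ALPHA_ASSUMPTIONS,
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison with assumption-gated test selection.

    A two-sided pooled t test is used only when both groups pass
    Shapiro-Wilk normality and the groups pass median-centered Levene
    at ``alpha``; otherwise the Mann-Whitney U test.  ``welch=True``
    switches the parametric branch to the unpooled-variance t test.
    """
    va = np.asarray(list(a), dtype=float)
    vb = np.asarray(list(b), dtype=float)
    if va.size < 3 or vb.size < 3:
        raise ValueError("each group needs n >= 3 (normality untestable)")
    p_norm_a = _shapiro_p(va)
    p_norm_b = _shapiro_p(vb)
    if np.ptp(va) == 0 and np.ptp(vb) == 0:
        p_lev = 1.0 if np.array_equal(np.sort(va), np.sort(vb)) else 0.0
    else:
        p_lev = float(sps.levene(va, vb, center="median").pvalue)
    parametric = min(p_norm_a, p_norm_b) > alpha and p_lev > alpha
    if parametric:
        res = sps.ttest_ind(va, vb, equal_var=not welch)
        test_used = "t_test"
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        test_used = "mann_whitney_u"
        if np.ptp(np.concatenate([va, vb])) == 0:
            # every observation tied: no evidence either way
            statistic, p_value = va.size * vb.size / 2.0, 1.0
        else:
            res = sps.mannwhitneyu(va, vb, alternative="two-sided")
            statistic, p_value = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        mean_a=float(va.mean()), sd_a=float(va.std(ddof=1)),
        mean_b=float(vb.mean()), sd_b=float(vb.std(ddof=1)),
        normality_p_a=p_norm_a, normality_p_b=p_norm_b,
        variance_p=p_lev, test_used=test_used,
        statistic=statistic, p_value=p_value,
    )


def antibody_vs_isotype(
    antibody_vals: Sequence[float],
    isotype_vals: Sequence[float],
    alpha: float = 0.05,
) -> tuple[GroupComparison, bool]:
    """Compare a test antibody against its isotype control.

    Labelling is called *specific* only when the antibody mean exceeds
    the isotype mean AND the two-sided comparison rejects at ``alpha``
    (a directional rule: signal below background is never specific).
    """
    comparison = compare_groups(antibody_vals, isotype_vals)
    specific = comparison.mean_a > comparison.mean_b and comparison.p_value < alpha
    return comparison, specific


# ---------------------------------------------------------------------------
# ROC


POSITIVE_IF_ABOVE = "positive_if_above"
POSITIVE_IF_BELOW = "positive_if_below"


def choose_direction(mean_pos: float, mean_neg: float) -> str:
    """Pick the classification side from the group means.

    A biomarker elevated in the positive condition classifies positive
    above the threshold; a reduced biomarker classifies positive below
    it.  An exact tie carries no direction and errors.
    """
    if not (math.isfinite(mean_pos) and math.isfinite(mean_neg)):
        raise ValueError("group means must be finite")
    if mean_pos == mean_neg:
        raise ValueError("group means are tied: direction undefined")
    return POSITIVE_IF_ABOVE if mean_pos > mean_neg else POSITIVE_IF_BELOW


@dataclass(frozen=True)
class RocCurve:
    thresholds: tuple[float, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    direction: str
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        t, f = np.asarray(self.tpr), np.asarray(self.fpr)
        if np.any((t < 0) | (t > 1)) or np.any((f < 0) | (f > 1)):
            raise ValueError("rates must lie in [0, 1]")
        if (f[0], t[0]) != (0.0, 0.0) or (f[-1], t[-1]) != (1.0, 1.0):
            raise ValueError("curve must span (0,0) to (1,1)")

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))

    def to_dict(self) -> dict:
        return {
            "thresholds": [None if math.isinf(t) else t for t in self.thresholds],
            "tpr": list(self.tpr), "fpr": list(self.fpr),
            "direction": self.direction,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def _rates_at(
    threshold: float, pos: np.ndarray, neg: np.ndarray, direction: str
) -> tuple[float, float]:
    if direction == POSITIVE_IF_ABOVE:
        tp = int(np.count_nonzero(pos > threshold))
        fp = int(np.count_nonzero(neg > threshold))
    elif direction == POSITIVE_IF_BELOW:
        tp = int(np.count_nonzero(pos < threshold))
        fp = int(np.count_nonzero(neg < threshold))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return tp / pos.size, fp / neg.size


def roc_points(
    pos_vals: Sequence[float], neg_vals: Sequence[float], direction: str
) -> RocCurve:
    """Threshold sweep over all unique pooled values plus ±inf sentinels.

    Classification is strict inequality on the chosen side; the curve is
    sorted by (FPR, TPR) so the sweep runs from (0,0) to (1,1).
    """
    pos = np.asarray(list(pos_vals), dtype=float)
    neg = np.asarray(list(neg_vals), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    cuts = np.unique(np.concatenate([pos, neg, [-np.inf, np.inf]]))
    records = []
    for thr in cuts:
        tpr, fpr = _rates_at(float(thr), pos, neg, direction)
        records.append((fpr, tpr, float(thr)))
    records.sort(key=lambda r: (r[0], r[1]))
    return RocCurve(
        thresholds=tuple(r[2] for r in records),
        tpr=tuple(r[1] for r in records),
        fpr=tuple(r[0] for r in records),
        direction=direction, n_pos=pos.size, n_neg=neg.size,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoid area: sum((FPR2 - FPR1) * (TPR2 + TPR1) / 2)."""
    fpr = np.asarray(curve.fpr)
    tpr = np.asarray(curve.tpr)
    if np.any(np.diff(fpr) < 0):
        raise ValueError("curve points must be sorted by FPR")
    return float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))


def sens_spec_at(
    threshold: float,
    pos_vals: Sequence[float],
    neg_vals: Sequence[float],
    direction: str,
) -> tuple[float, float]:
    """(sensitivity, specificity) at one threshold; specificity = 1 - FPR."""
    pos = np.asarray(list(pos_vals), dtype=float)
    neg = np.asarray(list(neg_vals), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    tpr, fpr = _rates_at(threshold, pos, neg, direction)
    return tpr, 1.0 - fpr


def optimal_threshold(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden J = TPR - FPR.

    Ties break toward higher specificity (lower FPR).  Returns
    ``(threshold, sensitivity, specificity)``.
    """
    best = None
    for thr, tpr, fpr in zip(curve.thresholds, curve.tpr, curve.fpr):
        j = tpr - fpr
        key = (j, -fpr)
        if best is None or key > best[0]:
            best = (key, thr, tpr, fpr)
    _, thr, tpr, fpr = best
    return float(thr), float(tpr), float(1.0 - fpr)


# ---------------------------------------------------------------------------
# power


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs for the two-sample t-test power computation.

    ``sd_to_diff_ratio`` expresses the common within-group SD as a
    fraction of the between-group mean difference, so the standardized
    effect size is its reciprocal.
    """

    n_per_group: int
    sd_to_diff_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sd_to_diff_ratio <= 0:
            raise ValueError("sd_to_diff_ratio must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def ttest_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample pooled t test.

    Effect size d = 1 / sd_to_diff_ratio; the test statistic under the
    alternative is noncentral t with 2n - 2 degrees of freedom and
    noncentrality d * sqrt(n/2).
    """
    n = spec.n_per_group
    d = 1.0 / spec.sd_to_diff_ratio
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    t_crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    power = (1.0 - sps.nct.cdf(t_crit, df, nc)) + sps.nct.cdf(-t_crit, df, nc)
    return float(power)
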