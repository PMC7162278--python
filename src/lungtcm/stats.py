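"""Error metrics, ROC analysis, Bland-Altman agreement and t tests.

The phantom experiments report signed percent errors against ground
truth; the cohort experiments report per-biomarker ROC curves (AUC via
the Mann-Whitney statistic, operating point by Youden's J), Bland-Altman
limits of agreement between calibration pairs, and paired / Welch
two-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "AgreementResult",
    "percent_error",
    "roc_auc",
    "bland_altman",
    "t_tests",
    "SIGNIFICANCE_LEVEL",
]

#: Two-sided significance threshold used throughout.
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class RocResult:
    """AUC with the Youden-optimal operating point.

    ``orientation`` records which direction of the biomarker indicates
    disease: "higher" means cases tend to larger values.
    """

    auc: float
    sensitivity: float
    specificity: float
    cutpoint: float
    orientation: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must be in [0, 1]")


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman mean difference and 95% limits of agreement."""

    mean_difference: float
    loa_lower: float
    loa_upper: float

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.mean_difference <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean difference")


def percent_error(estimate: float, truth: float, *, absolute: bool = False) -> float:
    """Signed percent error 100 x (estimate - truth) / truth.

    Negative values are underestimation; ``absolute=True`` returns the
    magnitude.
    """
    if truth == 0:
        raise ValueError("truth must be nonzero")
    err = 100.0 * (estimate - truth) / truth
    return abs(err) if absolute else err


def roc_auc(values, labels, positive_label: str = "copd") -> RocResult:
    """ROC analysis of one scalar biomarker against binary group labels.

    AUC is the Mann-Whitney probability that a random case exceeds a
    random control (ties count 1/2), computed from rank sums.  The
    orientation is auto-selected so AUC >= 0.5 and recorded.  The
    reported cutpoint maximises Youden's J = sensitivity + specificity - 1
    over midpoints between adjacent distinct values (a case is called
    positive when the oriented value is >= the cutpoint); sensitivity
    and specificity are returned in percent.
    """
    v = np.asarray(values, dtype=np.float64)
    y = np.asarray([lab == positive_label for lab in labels], dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be matching 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = sps.rankdata(v)  # average ranks: ties count 1/2 in the U statistic
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    orientation = "higher"
    oriented = v
    if auc < 0.5:
        auc = 1.0 - auc
        orientation = "lower"
        oriented = -v

    # candidate cutpoints: midpoints between adjacent distinct oriented values,
    # plus sentinels calling everything / nothing positive
    u = np.unique(oriented)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0 if u.size > 1 else [], [u[-1] + 1.0]])
    best = None
    for c in candidates:
        called = oriented >= c
        sens = np.count_nonzero(called & y) / n_pos
        spec = np.count_nonzero(~called & ~y) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cut, sens, spec = best
    if orientation == "lower":
        cut = -cut  # report on the original scale (called positive when value <= cut)
    return RocResult(float(auc), 100.0 * sens, 100.0 * spec, float(cut), orientation)


def bland_altman(a, b) -> AgreementResult:
    """Agreement between paired measurements: differences a - b, their
    mean, and mean +/- 1.96 x SD (95% limits of agreement)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples of size >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(mean, mean - 1.96 * sd, mean + 1.96 * sd)


def t_tests(x, y, paired: bool) -> tuple[float, float]:
    """Paired or Welch two-sample t test; returns (t, two-sided p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        if np.all(x == y):  # zero-variance differences: no effect, not undefined
            return 0.0, 1.0
        res = sps.ttest_rel(x, y)
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)
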