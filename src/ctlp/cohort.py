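"""Cohort-level statistics: frequencies, exact tests, ROC calibration.

Standard tests are delegated to scipy/statsmodels; the joint two-threshold
ROC sweep used to calibrate the CTLP operating point (switch count AND
log10 likelihood ratio) is package-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: canonical CTLP operating point: >= 20 status switches AND log10 LR >= 8.
DEFAULT_THRESHOLDS = (20, 8.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows are groups, columns condition present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class RocPoint:
    switches_threshold: float
    lr_threshold: float
    tpr: float
    fpr: float


@dataclass
class RocResult:
    points: list[RocPoint]
    auc: float
    suggested: tuple[float, float]
    default_thresholds: tuple[float, float] = DEFAULT_THRESHOLDS


def frequency_ci(
    k: int, n: int, method: str = "wilson"
) -> tuple[float, float, float]:
    """Percent frequency with 95% CI: ``(point, lower, upper)``.

    The point estimate is ``100*k/n`` rounded to one decimal; the interval
    is Wilson (default) or Clopper-Pearson (``method="clopper-pearson"``).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=0.05, method=sm_method)
    return round(100.0 * k / n, 1), 100.0 * lo, 100.0 * hi


def fisher_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-tailed Fisher's exact test: ``(p_value, odds_ratio)``."""
    arr = [[table.a, table.b], [table.c, table.d]]
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p), float(odds)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test: ``(D, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi_square_table(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: ``(statistic, df, p)``."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero row or column")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _dominance_score(switches: np.ndarray, lrs: np.ndarray) -> np.ndarray:
    """Combined score: how many records each record weakly dominates.

    Invariant to monotone transformation of either predictor; it is the
    natural scalarization of the AND-threshold classifier family.
    """
    n = len(switches)
    score = np.empty(n, dtype=float)
    for i in range(n):
        score[i] = np.sum((switches <= switches[i]) & (lrs <= lrs[i]))
    return score


def roc_curve(records) -> RocResult:
    """ROC analysis of the joint (switches, log10 LR) AND-classifier.

    ``records`` is an iterable of ``(switches, log10_lr, label)`` with a
    truthy label marking chromothriptic chromosomes. Candidate operating
    points sweep the grid of observed values of each predictor; each
    classifies positive iff both predictors meet their thresholds. The
    suggested operating point maximizes Youden's J; the AUC is the rank
    (Mann-Whitney) AUC of the dominance-count combined score.
    """
    recs = [(float(s), float(t), bool(l)) for s, t, l in records]
    labels = np.array([r[2] for r in recs])
    if labels.all() or not labels.any():
        raise ValueError("need both positive and negative labels")
    switches = np.array([r[0] for r in recs])
    lrs = np.array([r[1] for r in recs])
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos

    # joint sweep over the grid of observed values of each predictor:
    # count records with switches >= s_i and lr >= t_j by a 2-D histogram
    # followed by suffix sums over both axes
    uniq_s = np.unique(switches)
    uniq_t = np.unique(lrs)
    si = np.searchsorted(uniq_s, switches)
    ti = np.searchsorted(uniq_t, lrs)
    pos_hist = np.zeros((len(uniq_s), len(uniq_t)))
    neg_hist = np.zeros_like(pos_hist)
    np.add.at(pos_hist, (si[labels], ti[labels]), 1)
    np.add.at(neg_hist, (si[~labels], ti[~labels]), 1)
    pos_ge = pos_hist[::-1, ::-1].cumsum(0).cumsum(1)[::-1, ::-1]
    neg_ge = neg_hist[::-1, ::-1].cumsum(0).cumsum(1)[::-1, ::-1]
    tpr_grid = pos_ge / n_pos
    fpr_grid = neg_ge / n_neg

    points: list[RocPoint] = []
    best = None
    for i, s0 in enumerate(uniq_s):
        for j, t0 in enumerate(uniq_t):
            tpr = float(tpr_grid[i, j])
            fpr = float(fpr_grid[i, j])
            points.append(RocPoint(float(s0), float(t0), tpr, fpr))
            key = (tpr - fpr, -fpr, s0, t0)
            if best is None or key > best[0]:
                best = (key, (float(s0), float(t0)))

    score = _dominance_score(switches, lrs)
    ranks = stats.rankdata(score)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return RocResult(points=points, auc=float(auc), suggested=best[1])
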