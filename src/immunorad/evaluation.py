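"""Evaluation arithmetic: ROC/AUC, Youden cutoffs, 2x2 association tests.

Conventions (fixed, documented):

* the positive class is CR; a positive call is ``score >= cutoff``
  (high-score group);
* the Pearson chi-square test is uncorrected by default (Yates available
  behind a flag);
* AUC confidence intervals use DeLong's method by default;
* Youden ties break toward the higher threshold;
* percentages are rounded half-up for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC over all distinct score thresholds."""

    thresholds: np.ndarray  # descending; positive call is score >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of group (low/high) by outcome (PR/CR)."""

    low_pr: int
    low_cr: int
    high_pr: int
    high_cr: int

    def __post_init__(self) -> None:
        for name in ("low_pr", "low_cr", "high_pr", "high_cr"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.low_pr + self.low_cr + self.high_pr + self.high_cr

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.low_pr, self.low_cr], [self.high_pr, self.high_cr]])


@dataclass(frozen=True)
class StratificationReport:
    cutoff: float
    table: TwoByTwoTable
    chi2: float
    p: float
    sensitivity: float
    specificity: float
    cr_rate_low: float
    cr_rate_high: float


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have matching shape")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    y = labels.astype(np.float64)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0 (PR) / 1 (CR)")
    return scores, y.astype(bool)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI from placement values."""
    n, m = len(pos), len(neg)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / m for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / n for x in neg])
    var = v10.var(ddof=1) / n + v01.var(ddof=1) / m if n > 1 and m > 1 else 0.0
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC; AUC by the Mann-Whitney statistic (ties count half)."""
    scores, is_pos = _validate_scores_labels(scores, labels)
    pos, neg = scores[is_pos], scores[~is_pos]
    thresholds = np.unique(scores)[::-1]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (len(pos) * len(neg)))
    return ROCCurve(thresholds, sens, spec, auc, _delong_ci(pos, neg, auc))


def youden_cutoff(roc: ROCCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1 (ties -> higher)."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # thresholds descend: first = highest
    if j[best] <= 0:
        warnings.warn(
            f"anti-predictive scores: maximal Youden index {j[best]:.3f} <= 0",
            stacklevel=2,
        )
    return float(roc.thresholds[best])


def chi_square_2x2(
    table: TwoByTwoTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Uncorrected Pearson chi-square with df=1 (Yates behind the flag)."""
    obs = table.counts.astype(np.float64)
    rows, cols, n = obs.sum(axis=1), obs.sum(axis=0), obs.sum()
    if n <= 0 or np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-square undefined: zero margin in 2x2 table")
    expected = np.outer(rows, cols) / n
    delta = np.abs(obs - expected)
    if continuity_correction:
        delta = np.maximum(delta - 0.5, 0.0)
    stat = float(np.sum(delta**2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


def stratify_and_test(
    scores, labels, cutoff: float, continuity_correction: bool = False
) -> StratificationReport:
    """Split at ``score >= cutoff`` and test the 2x2 association."""
    scores, is_cr = _validate_scores_labels(scores, labels)
    high = scores >= cutoff
    table = TwoByTwoTable(
        low_pr=int(np.sum(~high & ~is_cr)),
        low_cr=int(np.sum(~high & is_cr)),
        high_pr=int(np.sum(high & ~is_cr)),
        high_cr=int(np.sum(high & is_cr)),
    )
    return stratification_report_from_table(table, cutoff, continuity_correction)


def stratification_report_from_table(
    table: TwoByTwoTable, cutoff: float = math.nan, continuity_correction: bool = False
) -> StratificationReport:
    n_cr = table.low_cr + table.high_cr
    n_pr = table.low_pr + table.high_pr
    n_low = table.low_cr + table.low_pr
    n_high = table.high_cr + table.high_pr
    try:
        chi2, p = chi_square_2x2(table, continuity_correction)
    except ValueError:
        chi2, p = math.nan, math.nan  # empty group/outcome: test undefined
    return StratificationReport(
        cutoff=cutoff,
        table=table,
        chi2=chi2,
        p=p,
        sensitivity=table.high_cr / n_cr if n_cr else math.nan,
        specificity=table.low_pr / n_pr if n_pr else math.nan,
        cr_rate_low=table.low_cr / n_low if n_low else math.nan,
        cr_rate_high=table.high_cr / n_high if n_high else math.nan,
    )


def percent_display(fraction: float) -> int:
    """Half-up integer percent, matching printed style (0.8333 -> 83)."""
    return int(math.floor(fraction * 100 + 0.5))


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum.

    Policy: exact null distribution when both samples are tie-free and have
    at most 25 observations each; normal approximation with tie correction
    otherwise.
    """
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and max(x.size, y.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hematological_ratios(record, timepoint: str) -> dict[str, float]:
    """NLR=ANC/ALC, PNR=PLT/ANC, PLR=PLT/ALC, LMR=ALC/AMC at a timepoint.

    Ratios with a zero denominator are returned as NaN (flagged undefined).
    """
    if timepoint not in ("baseline", "10f"):
        raise ValueError("timepoint must be 'baseline' or '10f'")
    plt = getattr(record, f"plt_{timepoint}")
    anc = getattr(record, f"anc_{timepoint}")
    amc = getattr(record, f"amc_{timepoint}")
    alc = getattr(record, f"alc_{timepoint}")

    def safe(num, den):
        return num / den if den > 0 else math.nan

    return {
        "NLR": safe(anc, alc),
        "PNR": safe(plt, anc),
        "PLR": safe(plt, alc),
        "LMR": safe(alc, amc),
    }


@dataclass(frozen=True)
class Dichotomization:
    cutoff: float
    high: np.ndarray  # boolean: value >= cutoff


def dichotomize_covariates(
    covariates: dict[str, np.ndarray], labels
) -> dict[str, Dichotomization]:
    """Per covariate: ROC -> Youden cutoff -> low/high split at value >= cutoff."""
    out: dict[str, Dichotomization] = {}
    for name, values in covariates.items():
        values = np.asarray(values, dtype=np.float64)
        if np.unique(values).size < 2:
            warnings.warn(f"constant covariate {name!r} cannot be dichotomized",
                          stacklevel=2)
            continue
        cutoff = youden_cutoff(roc_curve(values, labels))
        out[name] = Dichotomization(cutoff=cutoff, high=values >= cutoff)
    return out


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    separation: bool = False


def logistic_regression(
    design: "np.ndarray | object", labels, univariate: bool = True
) -> dict[str, LogisticResult]:
    """Wald ORs with 95% CI from maximum-likelihood logistic fits.

    With ``univariate=True`` each column is fit alone against the labels;
    otherwise one joint (multivariate) fit is performed.  Separated fits are
    flagged with an unbounded CI.
    """
    import pandas as pd

    X = design if isinstance(design, pd.DataFrame) else pd.DataFrame(np.asarray(design))
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")

    def fit_block(cols: list[str]) -> dict[str, LogisticResult]:
        block = sm.add_constant(X[cols].to_numpy(dtype=np.float64))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, block).fit(disp=0, maxiter=500)
            except Exception:
                return {
                    c: LogisticResult(math.inf, (0.0, math.inf), math.nan, True)
                    for c in cols
                }
        res = {}
        for k, c in enumerate(cols, start=1):
            beta, se = float(fit.params[k]), float(fit.bse[k])
            sep = (not math.isfinite(se)) or se > 1e3
            if sep:
                res[c] = LogisticResult(math.exp(beta), (0.0, math.inf), math.nan, True)
            else:
                half = 1.959963984540054 * se
                res[c] = LogisticResult(
                    math.exp(beta),
                    (math.exp(beta - half), math.exp(beta + half)),
                    float(fit.pvalues[k]),
                )
        return res

    if univariate:
        out: dict[str, LogisticResult] = {}
        for col in X.columns:
            out.update(fit_block([col]))
        return out
    return fit_block(list(X.columns))
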