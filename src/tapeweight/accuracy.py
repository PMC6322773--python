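"""Bias, precision and accuracy statistics for weight-estimation studies.

The field's standard evaluation expresses each estimate as a signed
percentage error PE = 100·(estimated − actual)/actual and summarises a
method's performance by

* bias: the mean percentage error (MPE),
* precision: the Bland–Altman 95% limits of agreement, MPE ± 1.96·SD(PE),
  and the root mean square percentage error RMSPE = sqrt(mean(PE²)),
* overall accuracy: p10 and p20, the percentage of estimates within ±10%
  and ±20% of measured weight.

When only MPE and LOA are published for a method, p10/p20 can be imputed
under a normality assumption by integrating N(μ, σ) over [−t, +t], with σ
recovered from the LOA width (:func:`impute_p_within`).

Paired method comparisons use McNemar's test on within-threshold hits
(exact binomial for small discordant counts, continuity-corrected chi-square
otherwise), the matched-pairs odds ratio b/c, and the paired t-test on
matched percentage errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AccuracySummary",
    "McNemarResult",
    "OddsRatioResult",
    "PairedTResult",
    "DifferenceSummary",
    "PairedComparison",
    "percentage_error",
    "summarize",
    "impute_p_within",
    "mcnemar",
    "paired_odds_ratio",
    "paired_t",
    "difference_summary",
    "compare_within_threshold",
    "LOA_FACTOR",
]

#: the 95% limits-of-agreement multiplier
LOA_FACTOR = 1.96

#: exact McNemar below this many discordant pairs, chi-square at or above
MCNEMAR_EXACT_BELOW = 25


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


def percentage_error(estimated, actual):
    """Signed percentage error, 100·(estimated − actual)/actual.

    Negative values indicate underestimation.  ``actual`` must be > 0.
    """
    estimated = np.asarray(estimated, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if np.any(actual <= 0):
        raise ValueError("actual weight must be strictly positive")
    pe = 100.0 * (estimated - actual) / actual
    return float(pe) if pe.ndim == 0 else pe


@dataclass(frozen=True)
class AccuracySummary:
    """One method's performance on one (sub)population, in percent.

    ``rmspe_companion`` is the SD of |PE|, reported alongside RMSPE as the
    parenthetical spread figure conventional in these report tables.
    """

    mpe: float
    sd: float
    loa_low: float
    loa_high: float
    rmspe: float
    rmspe_companion: float
    p10: float
    p20: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mpe": self.mpe, "sd": self.sd,
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "rmspe": self.rmspe, "rmspe_companion": self.rmspe_companion,
            "p10": self.p10, "p20": self.p20, "n": self.n,
        }


def summarize(pe, *, thresholds=(10.0, 20.0)) -> AccuracySummary:
    """Summarise a sample of percentage errors.

    SD uses the n−1 denominator (Bland–Altman convention); requires n >= 2.
    """
    pe = np.asarray(pe, dtype=float)
    if pe.ndim != 1:
        pe = pe.ravel()
    if not np.all(np.isfinite(pe)):
        raise ValueError("percentage errors must be finite")
    n = pe.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 errors, got {n}")
    mpe = float(np.mean(pe))
    sd = float(np.std(pe, ddof=1))
    t10, t20 = thresholds
    ape = np.abs(pe)
    return AccuracySummary(
        mpe=mpe,
        sd=sd,
        loa_low=mpe - LOA_FACTOR * sd,
        loa_high=mpe + LOA_FACTOR * sd,
        rmspe=float(np.sqrt(np.mean(pe ** 2))),
        rmspe_companion=float(np.std(ape, ddof=1)),
        p10=float(100.0 * np.mean(ape <= t10)),
        p20=float(100.0 * np.mean(ape <= t20)),
        n=int(n),
    )


def impute_p_within(mpe: float, loa_low: float, loa_high: float, threshold: float) -> float:
    """Impute the percentage of estimates within ±threshold% from MPE and LOA.

    Recovers σ = (loa_high − loa_low)/(2·1.96) and integrates the normal
    error distribution N(mpe, σ) over [−threshold, +threshold].  Valid under
    the normality assumption of the published summary.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not loa_low < loa_high:
        raise ValueError("degenerate limits of agreement: loa_low must be < loa_high")
    sigma = (loa_high - loa_low) / (2.0 * LOA_FACTOR)
    return float(100.0 * (
        stats.norm.cdf((threshold - mpe) / sigma)
        - stats.norm.cdf((-threshold - mpe) / sigma)
    ))


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    exact: bool
    b: int
    c: int


def mcnemar(b: int, c: int, *, exact_below: int = MCNEMAR_EXACT_BELOW) -> McNemarResult:
    """McNemar's test from the two discordant counts.

    Exact two-sided binomial(b, b+c, 1/2) when b + c < ``exact_below``,
    continuity-corrected chi-square (|b − c| − 1)²/(b + c) with 1 df
    otherwise.  The statistic reported for the exact branch is min(b, c).
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        raise InsufficientDataError("no discordant pairs: McNemar test undefined")
    if m < exact_below:
        k = min(b, c)
        p = min(1.0, 2.0 * stats.binom.cdf(k, m, 0.5))
        return McNemarResult(statistic=float(k), p_value=float(p), exact=True, b=b, c=c)
    statistic = (abs(b - c) - 1.0) ** 2 / m
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic=float(statistic), p_value=p, exact=False, b=b, c=c)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool


def paired_odds_ratio(b: int, c: int) -> OddsRatioResult:
    """Matched-pairs odds ratio b/c with a 95% log-scale Wald CI.

    With a zero discordant cell the ratio is undefined; ½ is added to both
    cells and the result flagged ``continuity_corrected``.
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b == 0 and c == 0:
        raise InsufficientDataError("no discordant pairs: odds ratio undefined")
    corrected = b == 0 or c == 0
    bb, cc = (b + 0.5, c + 0.5) if corrected else (float(b), float(c))
    log_or = np.log(bb / cc)
    se = np.sqrt(1.0 / bb + 1.0 / cc)
    return OddsRatioResult(
        odds_ratio=float(bb / cc),
        ci_low=float(np.exp(log_or - LOA_FACTOR * se)),
        ci_high=float(np.exp(log_or + LOA_FACTOR * se)),
        continuity_corrected=corrected,
    )


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p_value: float
    mean_difference: float
    degenerate: bool


def paired_t(pe_a, pe_b) -> PairedTResult:
    """Two-sided paired t-test on matched percentage-error lists.

    Zero-variance differences are flagged degenerate: identical samples give
    (t=0, p=1); a constant nonzero shift gives (t=±inf, p=0).
    """
    a = np.asarray(pe_a, dtype=float)
    bvec = np.asarray(pe_b, dtype=float)
    if a.shape != bvec.shape:
        raise ValueError("matched samples must have equal length")
    if a.size < 2:
        raise InsufficientDataError("need at least 2 matched pairs")
    d = a - bvec
    md = float(np.mean(d))
    if np.allclose(np.std(d, ddof=1), 0.0):
        if np.isclose(md, 0.0):
            return PairedTResult(t=0.0, p_value=1.0, mean_difference=md, degenerate=True)
        return PairedTResult(
            t=float(np.inf) if md > 0 else float(-np.inf),
            p_value=0.0, mean_difference=md, degenerate=True,
        )
    res = stats.ttest_rel(a, bvec)
    return PairedTResult(
        t=float(res.statistic), p_value=float(res.pvalue),
        mean_difference=md, degenerate=False,
    )


@dataclass(frozen=True)
class DifferenceSummary:
    """Absolute (percentage-point) and relative (%) difference of two proportions."""

    absolute: float
    relative: Optional[float]

    @property
    def absolute_rounded(self) -> int:
        return int(round(self.absolute))

    @property
    def relative_rounded(self) -> Optional[int]:
        return None if self.relative is None else int(round(self.relative))


def difference_summary(p_a: float, p_b: float) -> DifferenceSummary:
    """Absolute and relative difference of accuracy proportions (A vs B).

    Relative difference is 100·(p_a − p_b)/p_b, undefined (None) at p_b = 0.
    """
    absolute = p_a - p_b
    relative = None if p_b == 0 else 100.0 * (p_a - p_b) / p_b
    return DifferenceSummary(absolute=absolute, relative=relative)


@dataclass(frozen=True)
class PairedComparison:
    """One paired contrast of two methods on one metric in one stratum."""

    metric: str                  # p10 | p20 | mpe
    method_a: str
    method_b: str
    dimension: str = "overall"
    bin: str = "all"
    n: int = 0
    b: int = 0                   # A accurate, B not
    c: int = 0                   # B accurate, A not
    statistic: float = float("nan")
    p_value: float = float("nan")
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    value_a: float = float("nan")
    value_b: float = float("nan")
    significant: bool = False
    clinically_important: bool = False
    degenerate: bool = False


def compare_within_threshold(
    within_a, within_b, *, metric: str, method_a: str, method_b: str,
    dimension: str = "overall", bin: str = "all",
    alpha: float = 0.001, clinical_margin: float = 10.0,
) -> PairedComparison:
    """McNemar + matched odds ratio for paired within-threshold indicators.

    ``within_a``/``within_b`` are matched boolean arrays (|PE| <= threshold).
    Degenerate tables (no discordant pairs) yield a null comparison with
    p = 1 and OR = 1 rather than an error, flagged ``degenerate``.
    """
    wa = np.asarray(within_a, dtype=bool)
    wb = np.asarray(within_b, dtype=bool)
    if wa.shape != wb.shape:
        raise ValueError("matched indicators must have equal length")
    n = wa.size
    b = int(np.sum(wa & ~wb))
    c = int(np.sum(~wa & wb))
    value_a = float(100.0 * np.mean(wa)) if n else float("nan")
    value_b = float(100.0 * np.mean(wb)) if n else float("nan")
    diff = difference_summary(value_a, value_b)
    if b + c == 0:
        return PairedComparison(
            metric=metric, method_a=method_a, method_b=method_b,
            dimension=dimension, bin=bin, n=n, b=b, c=c,
            statistic=0.0, p_value=1.0, odds_ratio=1.0, ci_low=None, ci_high=None,
            value_a=value_a, value_b=value_b,
            significant=False,
            clinically_important=abs(diff.absolute) > clinical_margin,
            degenerate=True,
        )
    mc = mcnemar(b, c)
    orr = paired_odds_ratio(b, c)
    return PairedComparison(
        metric=metric, method_a=method_a, method_b=method_b,
        dimension=dimension, bin=bin, n=n, b=b, c=c,
        statistic=mc.statistic, p_value=mc.p_value,
        odds_ratio=orr.odds_ratio, ci_low=orr.ci_low, ci_high=orr.ci_high,
        value_a=value_a, value_b=value_b,
        significant=mc.p_value < alpha,
        clinically_important=abs(diff.absolute) > clinical_margin,
        degenerate=False,
    )
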