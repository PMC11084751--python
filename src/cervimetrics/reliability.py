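"""Paired-trial agreement statistics for repeated radiographic mensuration.

Given two measurement tables of the same images — two blinded trials by one
human rater, a human trial vs a computer-vision annotator, or a
deterministic annotator against itself — this module computes, per
variable:

* error summaries (mean absolute, mean signed, sample std, RMSE),
* the intraclass correlation coefficient, by default ICC(2,1): two-way
  random effects, absolute agreement, single measures — the standard strict
  choice for test-retest designs — with the consistency variant ICC(3,1)
  available, and an F-based 95% confidence interval,
* the coefficient of determination R^2 of the ordinary least-squares fit of
  trial 2 on trial 1 (identical to the squared Pearson correlation), and
* two qualitative labels: an R^2 reliability band (super-clean / clean /
  semi-clean / unreliable) and a conventional effect-size grade.

The statistics are descriptive; no hypothesis tests are performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import MEASUREMENT_VARIABLES

__all__ = [
    "InsufficientDataError",
    "UndefinedStatisticError",
    "ErrorSeries",
    "AgreementRow",
    "ReliabilityReport",
    "paired_errors",
    "error_summary",
    "icc",
    "r_squared",
    "classify_r2",
    "effect_size_label",
    "reliability_report",
]

logger = logging.getLogger(__name__)

#: R^2 reliability bands, closed on the left.
R2_BANDS: tuple[tuple[float, str], ...] = (
    (0.90, "super-clean"),
    (0.75, "clean"),
    (0.50, "semi-clean"),
    (0.00, "unreliable"),
)

#: Conventional effect-size grades for R^2.
EFFECT_SIZE_BANDS: tuple[tuple[float, str], ...] = (
    (0.7, "strong"),
    (0.5, "moderate"),
    (0.3, "weak"),
    (0.0, "none/very-weak"),
)

REPORT_COLUMNS = (
    "comparison",
    "variable",
    "n_pairs",
    "mean_abs_err",
    "mean_signed_err",
    "std_err",
    "rmse",
    "icc",
    "icc_ci_low",
    "icc_ci_high",
    "r2",
    "r2_class",
    "effect_size",
)


class InsufficientDataError(ValueError):
    """Fewer complete pairs than the statistic requires."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. zero total variance)."""


@dataclass(frozen=True)
class ErrorSeries:
    """Matched pairs of one variable across two trials, with their errors."""

    variable: str
    t1: np.ndarray
    t2: np.ndarray
    n_excluded: int = 0

    @property
    def errors(self) -> np.ndarray:
        return self.t1 - self.t2

    @property
    def n_pairs(self) -> int:
        return int(self.t1.size)


@dataclass(frozen=True)
class AgreementRow:
    variable: str
    n_pairs: int
    mean_abs_err: float
    mean_signed_err: float
    std_err: float
    rmse: float
    icc_estimate: float
    icc_ci_low: float
    icc_ci_high: float
    r2: float
    r2_class: str
    effect_size_label: str


@dataclass
class ReliabilityReport:
    """Per-variable agreement between two trials, one row per variable."""

    comparison: str
    rows: list[AgreementRow] = field(default_factory=list)
    stratum: str | None = None

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "comparison": self.comparison
                if self.stratum is None
                else f"{self.comparison}[{self.stratum}]",
                "variable": r.variable,
                "n_pairs": r.n_pairs,
                "mean_abs_err": r.mean_abs_err,
                "mean_signed_err": r.mean_signed_err,
                "std_err": r.std_err,
                "rmse": r.rmse,
                "icc": r.icc_estimate,
                "icc_ci_low": r.icc_ci_low,
                "icc_ci_high": r.icc_ci_high,
                "r2": r.r2,
                "r2_class": r.r2_class,
                "effect_size": r.effect_size_label,
            }
            for r in self.rows
        ]
        return pd.DataFrame(recs, columns=list(REPORT_COLUMNS))


def paired_errors(t1: pd.DataFrame, t2: pd.DataFrame, variable: str) -> ErrorSeries:
    """Match one variable across two measurement tables on image_id.

    Pairs where either side is missing are excluded and counted; matching is
    by index, so row order is irrelevant.
    """
    if variable not in t1.columns or variable not in t2.columns:
        raise KeyError(f"variable {variable!r} absent from a table")
    joined = pd.concat(
        [t1[variable].rename("t1"), t2[variable].rename("t2")], axis=1, join="inner"
    )
    complete = joined.dropna()
    n_excluded = len(joined) - len(complete)
    if n_excluded:
        logger.info("%s: excluded %d incomplete pairs", variable, n_excluded)
    if len(complete) < 2:
        raise InsufficientDataError(
            f"{variable}: {len(complete)} complete pairs (need >= 2)"
        )
    return ErrorSeries(
        variable=variable,
        t1=complete["t1"].to_numpy(float),
        t2=complete["t2"].to_numpy(float),
        n_excluded=n_excluded,
    )


def error_summary(es: ErrorSeries) -> tuple[float, float, float, float]:
    """(mean absolute, mean signed, sample std, RMSE) of the paired errors.

    The decomposition ``rmse^2 = mean_signed^2 + (n-1)/n * std^2`` holds by
    construction.
    """
    e = es.errors
    n = e.size
    if n < 2:
        raise InsufficientDataError(f"{es.variable}: need >= 2 pairs")
    mean_abs = float(np.mean(np.abs(e)))
    mean_signed = float(np.mean(e))
    std = float(np.std(e, ddof=1))
    rmse = float(np.sqrt(np.mean(e**2)))
    return mean_abs, mean_signed, std, rmse


def _icc_mean_squares(y1: np.ndarray, y2: np.ndarray) -> tuple[float, float, float, int]:
    """Two-way ANOVA mean squares for n subjects x k=2 raters."""
    data = np.column_stack([y1, y2])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((rater_means - grand) ** 2)
    # residual computed directly (not by SS subtraction) for numerical accuracy
    resid = data - subj_means[:, None] - rater_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n


def icc(
    t1: Sequence[float] | np.ndarray,
    t2: Sequence[float] | np.ndarray,
    model: str = "two_way_random_absolute",
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """Intraclass correlation of paired measurements, with CI.

    ``two_way_random_absolute`` is ICC(2,1) in Shrout-Fleiss notation (A,1 in
    McGraw-Wong): systematic offsets between the two trials count against
    agreement. ``two_way_mixed_consistency`` is ICC(3,1) (C,1), which
    ignores a constant shift. Estimates are clamped to [-1, 1]; the CI is the
    standard F-based interval at the requested confidence.
    """
    y1 = np.asarray(t1, dtype=float)
    y2 = np.asarray(t2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("t1 and t2 must be 1-D arrays of equal length")
    if y1.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {y1.size}")
    msr, msc, mse, n = _icc_mean_squares(y1, y2)
    k = 2
    if msr == 0.0 and mse == 0.0:
        raise UndefinedStatisticError("zero between-subject and residual variance")
    if np.array_equal(y1, y2):
        return 1.0, 1.0, 1.0  # identical trials: exactly perfect agreement

    alpha = 1.0 - confidence

    def clamp(v: float) -> float:
        return float(min(1.0, max(-1.0, v)))

    if model == "two_way_mixed_consistency":
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else 1.0
        # CI from F = MSR/MSE with (n-1), (n-1)(k-1) df
        if mse == 0.0:
            lo = hi = clamp(est)
        else:
            f_obs = msr / mse
            fu = stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            fl = stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (f_obs / fu - 1) / (f_obs / fu + k - 1)
            hi = (f_obs * fl - 1) / (f_obs * fl + k - 1)
        return clamp(est), clamp(lo), clamp(hi)

    if model != "two_way_random_absolute":
        raise ValueError(f"unknown ICC model {model!r}")

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom if denom > 0 else 1.0
    est_c = clamp(est)

    if mse == 0.0 and msc == 0.0:
        return est_c, est_c, est_c

    # McGraw & Wong F-based interval with Satterthwaite df (as in the psych
    # and pingouin implementations).
    icc_hat = est_c
    fj = msc / mse if mse > 0 else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        vn = (k - 1) * (n - 1) * (
            k * icc_hat * fj + n * (1 + (k - 1) * icc_hat) - k * icc_hat
        ) ** 2
        vd = (n - 1) * k**2 * icc_hat**2 * fj**2 + (
            n * (1 + (k - 1) * icc_hat) - k * icc_hat
        ) ** 2
        v = vn / vd if vd > 0 else (n - 1) * (k - 1)
    if not np.isfinite(v) or v <= 0:
        v = (n - 1) * (k - 1)
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo_den = f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    hi_den = k * msc + (k * n - k - n) * mse + n * f_lower * msr
    lo = n * (msr - f_upper * mse) / lo_den if lo_den != 0 else est_c
    hi = n * (f_lower * msr - mse) / hi_den if hi_den != 0 else est_c
    return est_c, clamp(lo), clamp(hi)


def r_squared(t1: Sequence[float] | np.ndarray, t2: Sequence[float] | np.ndarray) -> float:
    """Coefficient of determination of the OLS fit t2 = a + b*t1.

    For simple linear regression this equals the squared Pearson correlation,
    hence it is symmetric in its arguments.
    """
    y1 = np.asarray(t1, dtype=float)
    y2 = np.asarray(t2, dtype=float)
    if y1.size != y2.size or y1.ndim != 1:
        raise ValueError("t1 and t2 must be 1-D arrays of equal length")
    if y1.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {y1.size}")
    if np.std(y1) == 0.0 or np.std(y2) == 0.0:
        raise UndefinedStatisticError("zero variance in a series")
    if np.array_equal(y1, y2):
        return 1.0  # identical measurements: exactly perfect, no rounding
    r = float(np.corrcoef(y1, y2)[0, 1])
    return r * r


def _band_label(value: float, bands: tuple[tuple[float, str], ...]) -> str:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"R^2 must lie in [0, 1], got {value}")
    for cut, label in bands:
        if value >= cut:
            return label
    return bands[-1][1]


def classify_r2(r2: float) -> str:
    """Reliability band of an R^2 value.

    ``super-clean`` for R^2 >= 0.90, ``clean`` for [0.75, 0.90),
    ``semi-clean`` for [0.50, 0.75), ``unreliable`` below 0.50.
    """
    return _band_label(r2, R2_BANDS)


def effect_size_label(r2: float) -> str:
    """Conventional effect-size grade of an R^2 value.

    ``none/very-weak`` below 0.3, ``weak`` [0.3, 0.5), ``moderate``
    [0.5, 0.7), ``strong`` [0.7, 1), ``perfect`` at exactly 1.0.
    """
    if r2 == 1.0:
        return "perfect"
    return _band_label(r2, EFFECT_SIZE_BANDS)


def _agreement_row(es: ErrorSeries) -> AgreementRow:
    mean_abs, mean_signed, std, rmse = error_summary(es)
    try:
        est, lo, hi = icc(es.t1, es.t2)
    except (InsufficientDataError, UndefinedStatisticError):
        est = lo = hi = float("nan")
    try:
        r2 = r_squared(es.t1, es.t2)
    except (InsufficientDataError, UndefinedStatisticError):
        r2 = float("nan")
    r2_in_range = math.isfinite(r2) and 0.0 <= r2 <= 1.0
    return AgreementRow(
        variable=es.variable,
        n_pairs=es.n_pairs,
        mean_abs_err=mean_abs,
        mean_signed_err=mean_signed,
        std_err=std,
        rmse=rmse,
        icc_estimate=est,
        icc_ci_low=lo,
        icc_ci_high=hi,
        r2=r2,
        r2_class=classify_r2(r2) if r2_in_range else "undefined",
        effect_size_label=effect_size_label(r2) if r2_in_range else "undefined",
    )


def reliability_report(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    label: str,
    strata: pd.Series | dict | None = None,
    variables: Sequence[str] = MEASUREMENT_VARIABLES,
) -> ReliabilityReport | list[ReliabilityReport]:
    """Build the per-variable agreement report between two trials.

    ``strata``, if given, maps image_id to a stratum label (e.g. sex or a
    degeneration grade); one sub-report per stratum is returned in addition
    to behaving like the pooled analysis when absent.
    """
    shared = t1.index.intersection(t2.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"tables overlap on {len(shared)} images (need >= 3)"
        )

    if strata is not None:
        strata = pd.Series(strata)
        reports = []
        for value in sorted(strata.loc[strata.index.intersection(shared)].unique()):
            ids = strata.index[strata == value].intersection(shared)
            sub = reliability_report(
                t1.loc[ids], t2.loc[ids], label, variables=variables
            )
            sub.stratum = str(value)
            reports.append(sub)
        return reports

    report = ReliabilityReport(comparison=label)
    for variable in variables:
        if variable not in t1.columns or variable not in t2.columns:
            continue
        try:
            es = paired_errors(t1, t2, variable)
        except InsufficientDataError:
            logger.warning("%s: too few complete pairs, row skipped", variable)
            continue
        report.rows.append(_agreement_row(es))
    return report
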