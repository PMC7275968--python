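"""ICH-style validation statistics and prediction figures of merit.

Conventions: sample (n-1) standard deviations throughout; percentages are
plain percent (99.4 means 99.4%); concentrations are ug/mL.  Full precision
is kept internally; report rounding (2 dp for concentrations/statistics,
1 dp for percentages) is the caller's policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FiguresOfMerit",
    "RegressionFOM",
    "ValidationReport",
    "prediction_fom",
    "lod_loq",
    "recovery_stats",
    "rsd_pct",
    "compare_methods",
    "urinary_excretion",
    "validation_report",
]


@dataclass(frozen=True)
class FiguresOfMerit:
    """Prediction quality of predicted vs known concentrations.

    rmsep  root-mean-square error of prediction, sqrt(sum (c - chat)^2 / n)
    bias   mean signed error, sum (c - chat) / n
    sep    bias-corrected standard error, sqrt(sum (c - chat - bias)^2 / (n-1))
    re_pct total relative error, 100 * sqrt(sum (c - chat)^2 / sum c^2)
    slope/intercept/r2 come from the OLS fit of predicted on known.
    """

    rmsep: float
    sep: float
    bias: float
    re_pct: float
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class RegressionFOM:
    """Calibration-line regression summary with ICH detection limits."""

    slope: float
    intercept: float
    r2: float
    s_slope: float
    s_intercept: float
    lod: float
    loq: float


@dataclass(frozen=True)
class ValidationReport:
    """Accuracy/precision summary in the ICH reporting layout."""

    accuracy_mean_pct: float
    accuracy_sd_pct: float
    intraday_rsd_pct: float
    interday_rsd_pct: float
    per_level_recoveries: dict[float, float]  # nominal conc -> mean % recovery


def validation_report(nominal, found_by_day) -> ValidationReport:
    """Summarize an accuracy/precision study for one analyte.

    ``nominal`` is the vector of study concentrations (ug/mL);
    ``found_by_day`` has shape (days, levels, replicates) with the measured
    concentrations.  Accuracy pools all determinations; intraday precision
    is the mean RSD over levels on the first day; interday precision is the
    mean over levels of the RSD of the daily level means.
    """
    nominal = np.asarray(nominal, dtype=float)
    found = np.asarray(found_by_day, dtype=float)
    if found.ndim != 3 or found.shape[1] != len(nominal):
        raise ValueError("found_by_day must be (days, levels, replicates)")
    rec = 100.0 * found / nominal[None, :, None]
    intraday = float(np.mean([rsd_pct(found[0, lv]) for lv in range(len(nominal))]))
    daily_means = found.mean(axis=2)  # days x levels
    interday = float(np.mean([rsd_pct(daily_means[:, lv]) for lv in range(len(nominal))]))
    return ValidationReport(
        accuracy_mean_pct=float(rec.mean()),
        accuracy_sd_pct=float(rec.std(ddof=1)),
        intraday_rsd_pct=intraday,
        interday_rsd_pct=interday,
        per_level_recoveries={
            float(c): float(rec[:, lv, :].mean()) for lv, c in enumerate(nominal)
        },
    )


def prediction_fom(known, predicted) -> FiguresOfMerit:
    c = np.asarray(known, dtype=float)
    chat = np.asarray(predicted, dtype=float)
    if c.shape != chat.shape or c.ndim != 1:
        raise ValueError("known and predicted must be equal-length vectors")
    n = len(c)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.all(c == 0):
        raise ValueError("all-zero known vector: relative error undefined")
    err = c - chat
    rmsep = float(np.sqrt(np.sum(err**2) / n))
    bias = float(np.sum(err) / n)
    sep = float(np.sqrt(np.sum((err - bias) ** 2) / (n - 1)))
    re_pct = float(100.0 * np.sqrt(np.sum(err**2) / np.sum(c**2)))
    if np.ptp(c) == 0:
        # degenerate: all known values identical -> no regression line
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        fit = stats.linregress(c, chat)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return FiguresOfMerit(
        rmsep=rmsep,
        sep=sep,
        bias=bias,
        re_pct=re_pct,
        slope=slope,
        intercept=intercept,
        r2=r2,
        n=n,
    )


def lod_loq(s_intercept: float, slope: float) -> tuple[float, float]:
    """ICH detection and quantitation limits: 3.3*sigma/S and 10*sigma/S."""
    if slope == 0:
        raise ZeroDivisionError("zero slope: LOD/LOQ undefined")
    return 3.3 * s_intercept / abs(slope), 10.0 * s_intercept / abs(slope)


def recovery_stats(nominal, found) -> tuple[np.ndarray, float, float]:
    """Per-sample % recovery (100*found/nominal) with mean and sample SD."""
    nom = np.asarray(nominal, dtype=float)
    fnd = np.asarray(found, dtype=float)
    if nom.shape != fnd.shape:
        raise ValueError("nominal and found must have equal length")
    if np.any(nom <= 0):
        raise ValueError("nominal concentrations must be positive")
    rec = 100.0 * fnd / nom
    return rec, float(np.mean(rec)), float(np.std(rec, ddof=1)) if len(rec) > 1 else 0.0


def rsd_pct(values) -> float:
    """Relative standard deviation in percent (sample SD over mean)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    m = np.mean(x)
    if m == 0:
        raise ZeroDivisionError("zero mean: RSD undefined")
    return float(100.0 * np.std(x, ddof=1) / m)


def compare_methods(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sample comparison from summary statistics.

    Returns (t, F): pooled-variance unpaired t statistic (absolute value)
    and the variance ratio with the larger variance in the numerator, so
    F >= 1 and the result is invariant to swapping the two methods.  The
    caller compares against tabulated critical values.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per method")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    f = max(sd1, sd2) ** 2 / min(sd1, sd2) ** 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = abs(mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), float(f)


def urinary_excretion(
    conc: float, urine_volume_ml: float, dose_mg: float, dilution_factor: float = 1.0
) -> tuple[float, float]:
    """Cumulative urinary excretion from measured urine concentration.

    ``conc`` (ug/mL) is the analyte concentration in the (possibly diluted)
    measured sample; ``dilution_factor`` maps it back to neat urine.
    Returns (excreted_mg, percent of administered dose).
    """
    if conc < 0 or urine_volume_ml < 0 or dilution_factor < 0:
        raise ValueError("inputs must be non-negative")
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    excreted_mg = conc * dilution_factor * urine_volume_ml / 1000.0
    return excreted_mg, 100.0 * excreted_mg / dose_mg
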