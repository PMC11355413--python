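"""Reliability and agreement statistics for replicate fibrosis measurements.

The replicate layout is a patients x replicates matrix of fibrosis
percentages (rows = patients, columns = repeated measurements of the same
patient).  Per-row summaries follow the reporting convention of the
validation tables:

* the SD column is the *sample* standard deviation (denominator k - 1);
* the CV column is ``100 * sd_pop / mean`` with the *population* standard
  deviation (denominator k).

This estimator mix is unusual but it is the only combination that
reproduces both printed summary columns of the source tables, so it is
mirrored deliberately and documented here.  All reported numbers are
rounded half-up to 2 decimals; full precision is retained internally.

The intraclass correlation uses the two-way model variance decomposition
(rows = subjects, columns = measurement occasions).  The default form is
single-measurement absolute agreement, ICC(A,1):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the rows/columns/error mean squares, a 95% CI by the
F-distribution method, and a p-value from F = MSR/MSE.  The consistency
form ICC(C,1) is also exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "CorrelationResult",
    "aggregate_cv",
    "anova_mean_squares",
    "ecv_fraction",
    "icc",
    "interpret_r",
    "ks_normality",
    "paired_t_test",
    "pearson",
    "read_replicate_csv",
    "replicate_stats",
    "replicate_table_stats",
    "round_half_up",
    "sample_size_correlation",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals (table convention).

    Python's built-in ``round`` rounds half to even; the printed tables use
    conventional half-up rounding.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# replicate summaries


def replicate_stats(values, ndigits: int | None = 2) -> dict:
    """Mean, sample SD and CV of one patient's replicate measurements.

    CV is ``100 * sd_pop / mean`` (population SD, denominator k) while the
    SD entry is the sample SD (denominator k - 1); see the module docstring.
    Results are rounded half-up to ``ndigits`` decimals (``None`` keeps full
    precision).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of at least 2 replicates")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero-mean replicates")
    sd_sample = float(x.std(ddof=1))
    cv = 100.0 * float(x.std(ddof=0)) / mean
    out = {"mean": mean, "sd_sample": sd_sample, "cv_percent": cv}
    if ndigits is not None:
        out = {k: round_half_up(v, ndigits) for k, v in out.items()}
    return out


def replicate_table_stats(values, ndigits: int | None = 2) -> pd.DataFrame:
    """Per-row replicate summaries for a patients x replicates matrix."""
    matrix = np.asarray(values, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 replicate columns")
    if np.isnan(matrix).any():
        raise ValueError("replicate table must have no missing cells")
    rows = [replicate_stats(row, ndigits=ndigits) for row in matrix]
    return pd.DataFrame(rows)


def read_replicate_csv(path) -> np.ndarray:
    """Read a replicate CSV (rows = patients, columns = replicates).

    A first column of non-numeric patient labels is tolerated and dropped.
    """
    frame = pd.read_csv(path)
    first = frame.columns[0]
    if not np.issubdtype(frame[first].dtype, np.number):
        frame = frame.drop(columns=[first])
    matrix = frame.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ValueError(f"missing cells in replicate table: {path}")
    return matrix


def aggregate_cv(cvs, method: str = "arithmetic") -> dict:
    """Aggregate per-patient CVs across a cohort.

    ``arithmetic`` summarises as mean +/- sample SD of the CVs; ``rms`` as
    the root mean square sqrt(mean(cv^2)).  Both are always computed; the
    ``summary`` entry follows ``method``.
    """
    x = np.asarray(cvs, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a non-empty 1-D vector of CVs")
    arithmetic = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    rms = float(np.sqrt(np.mean(x ** 2)))
    if method not in ("arithmetic", "rms"):
        raise ValueError("method must be 'arithmetic' or 'rms'")
    return {
        "summary": arithmetic if method == "arithmetic" else rms,
        "sd_of_cvs": sd,
        "arithmetic_mean": arithmetic,
        "rms": rms,
        "method": method,
    }


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation point estimate, 95% CI, p-value and model."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "two-way mixed, single measurement, absolute agreement"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def anova_mean_squares(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (subjects x occasions, no replication) ANOVA mean squares.

    Returns ``(MSR, MSC, MSE, n, k)`` for rows, columns and residual.
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return float(msr), float(msc), float(mse), n, k


def icc(matrix, model: str = "absolute", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation of a patients x replicates matrix.

    ``model='absolute'`` gives the single-measurement absolute-agreement
    form ICC(A,1) (default); ``model='consistency'`` gives ICC(C,1).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if np.isnan(x).any():
        raise ValueError("replicate table must have no missing cells")
    if np.allclose(x, x.flat[0]):
        raise ValueError("zero total variance; ICC undefined")
    msr, msc, mse, n, k = anova_mean_squares(x)

    if model == "absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        estimate = (msr - mse) / denom if denom != 0 else 1.0
        label = "two-way mixed, single measurement, absolute agreement"
        ci_low, ci_high = _icc_a1_ci(msr, msc, mse, n, k, estimate, alpha)
    elif model == "consistency":
        denom = msr + (k - 1) * mse
        estimate = (msr - mse) / denom if denom != 0 else 1.0
        label = "two-way mixed, single measurement, consistency"
        ci_low, ci_high = _icc_c1_ci(msr, mse, n, k, alpha)
    else:
        raise ValueError("model must be 'absolute' or 'consistency'")

    estimate = float(np.clip(estimate, -1.0, 1.0))
    if mse == 0:
        p = 0.0
    else:
        f_obs = msr / mse
        p = float(sps.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    return ICCResult(
        estimate=estimate,
        ci_low=float(min(ci_low, estimate)),
        ci_high=float(max(ci_high, estimate)),
        p_value=p,
        model=label,
    )


def _icc_a1_ci(msr, msc, mse, n, k, estimate, alpha):
    """F-method CI for ICC(A,1) (Satterthwaite df for the lower bound)."""
    if mse == 0 and msc == 0:
        return 1.0, 1.0
    r = min(estimate, 1 - 1e-12)
    a = k * r / (n * (1 - r))
    b = 1 + k * r * (n - 1) / (n * (1 - r))
    denom_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    if denom_v == 0:
        return 1.0, 1.0
    v = (a * msc + b * mse) ** 2 / denom_v
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(np.clip(lower, -1, 1)), float(np.clip(upper, -1, 1))


def _icc_c1_ci(msr, mse, n, k, alpha):
    if mse == 0:
        return 1.0, 1.0
    f_obs = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    lower = (f_l - 1) / (f_l + k - 1)
    upper = (f_u - 1) / (f_u + k - 1)
    return float(np.clip(lower, -1, 1)), float(np.clip(upper, -1, 1))


# ---------------------------------------------------------------------------
# correlation and classical tests


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with p-value, interpretation band and sign."""

    r: float
    p_value: float
    band: str
    sign: str


def interpret_r(r: float) -> str:
    """Interpretation band for a correlation coefficient.

    Applied to |r|: < 0.1 none, [0.1, 0.3) low, [0.3, 0.5) medium,
    [0.5, 0.7] high, > 0.7 very high.
    """
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    a = abs(r)
    if a > 0.7:
        return "very high"
    if a >= 0.5:
        return "high"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "low"
    return "none"


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided p and interpretation band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r,
        p_value=float(res.pvalue),
        band=interpret_r(r),
        sign="positive" if r >= 0 else "negative",
    )


def paired_t_test(a, b) -> dict:
    """Paired Student t-test on the differences, two-sided.

    Identical inputs return ``t=0, p=1``; non-zero constant differences have
    no within-pair variability and raise instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return {"t": 0.0, "p": 1.0}
        raise ValueError("zero-variance non-zero differences; t undefined")
    res = sps.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def ks_normality(x) -> dict:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    The statistic is the supremum distance between the empirical CDF and the
    fitted normal CDF.  (Parameters are estimated from the data, as in the
    desk-calculator workflow this mirrors; the p-value is therefore mildly
    conservative relative to a Lilliefors correction.)
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D vector with n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; normality test undefined")
    res = sps.kstest(x, "norm", args=(x.mean(), sd))
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# ECV and design helpers


def ecv_fraction(hct: float, nT1m: float, pT1m: float, nT1b: float, pT1b: float) -> float:
    """Extracellular volume fraction, in percent.

    ECV = (1 - haematocrit) * [(1/pT1m - 1/nT1m) / (1/pT1b - 1/nT1b)] * 100,
    with native (n) and post-contrast (p) T1 times of myocardium (m) and
    blood pool (b), all in ms.
    """
    if not (0 < hct < 1):
        raise ValueError("haematocrit must be a fraction in (0, 1)")
    for t1 in (nT1m, pT1m, nT1b, pT1b):
        if t1 <= 0:
            raise ValueError("T1 times must be strictly positive")
    blood = 1.0 / pT1b - 1.0 / nT1b
    if blood == 0:
        raise ValueError("blood-pool T1 change is zero; ECV undefined")
    myo = 1.0 / pT1m - 1.0 / nT1m
    return (1.0 - hct) * (myo / blood) * 100.0


def sample_size_correlation(r: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Minimum n to detect a correlation ``r`` (two-sided) via Fisher's z.

    n = ceil(((z_{1-alpha/2} + z_{power}) / atanh(|r|))^2 + 3).
    """
    if not (0 < abs(r) < 1):
        raise ValueError("r must satisfy 0 < |r| < 1")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    return int(math.ceil(((z_a + z_b) / math.atanh(abs(r))) ** 2 + 3))
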