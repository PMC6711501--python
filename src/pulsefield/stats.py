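"""Exposure-condition statistics: percent changes, two-sided t-tests with
star annotation, and autocorrelation-time thinning for correlated series.

Significance stars follow the thresholds *P<0.05, **P<0.01, ***P<0.005.
Frames from an MD-like series are serially correlated; the integrated
autocorrelation time provides the thinning stride that makes a t-test's
independence assumption defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "ChangeSummary",
    "stars_from_p",
    "ttest_two_sided",
    "percent_change",
    "autocorrelation_time",
    "thin_by_autocorrelation",
    "summary_table",
]

STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    stars: str


@dataclass(frozen=True)
class ChangeSummary:
    """Mean shift of an observable between a reference and an exposed sample."""

    condition: str
    reference_mean: float
    reference_sd: float
    reference_sem: float
    exposed_mean: float
    exposed_sd: float
    exposed_sem: float
    percent_change: float
    ttest: TTestResult


def stars_from_p(p: float) -> str:
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def ttest_two_sided(a, b, variant: str = "student_pooled") -> TTestResult:
    """Two-sided two-sample t-test.

    variant "student_pooled" is the classic equal-variance Student test;
    "welch" drops the equal-variance assumption. Degenerate zero-variance
    samples follow the documented convention: equal means -> p = 1,
    unequal means -> p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if np.isclose(a.mean(), b.mean()):
            t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p, df = 0.0, float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "student_pooled"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return TTestResult(
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        significant=p < 0.05,
        stars=stars_from_p(p),
    )


def percent_change(
    reference,
    exposed,
    condition: str = "",
    variant: str = "student_pooled",
) -> ChangeSummary:
    """Percent mean change of ``exposed`` relative to ``reference``.

    percent_change = 100 (mean_exposed - mean_reference) / mean_reference.
    Means are reported with both sample SD and the standard error of the
    mean. The attached t-test compares the two samples directly.
    """
    reference = np.asarray(reference, dtype=float)
    exposed = np.asarray(exposed, dtype=float)
    if reference.size == 0 or exposed.size == 0:
        raise ValueError("samples must be non-empty")
    ref_mean = reference.mean()
    if ref_mean == 0.0:
        raise ValueError("reference mean is zero; percent change undefined")
    change = 100.0 * (exposed.mean() - ref_mean) / ref_mean
    return ChangeSummary(
        condition=condition,
        reference_mean=float(ref_mean),
        reference_sd=float(reference.std(ddof=1)) if reference.size > 1 else 0.0,
        reference_sem=float(sps.sem(reference)) if reference.size > 1 else 0.0,
        exposed_mean=float(exposed.mean()),
        exposed_sd=float(exposed.std(ddof=1)) if exposed.size > 1 else 0.0,
        exposed_sem=float(sps.sem(exposed)) if exposed.size > 1 else 0.0,
        percent_change=float(change),
        ttest=ttest_two_sided(reference, exposed, variant=variant),
    )


def autocorrelation_time(values, dt: float = 1.0, c: float = 6.0) -> float:
    """Integrated autocorrelation time by self-consistent windowed summation.

    tau = dt * (1 + 2 sum_k rho_k), summed over lags k < c * tau/dt
    (Sokal's adaptive window). White noise gives tau ~ dt; an AR(1)
    process with coefficient phi gives tau ~ dt (1+phi)/(1-phi).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 50:
        raise ValueError("series too short for autocorrelation estimate (< 50)")
    x = values - values.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        raise ValueError("constant series: autocorrelation time undefined")
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, n=m)
    acov = np.fft.irfft(f * np.conj(f), n=m)[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    for window in range(1, n):
        tau = 1.0 + 2.0 * np.sum(rho[1 : window + 1])
        if window >= c * tau:
            break
    return float(max(tau, 1.0) * dt)


def thin_by_autocorrelation(values, dt: float = 1.0) -> np.ndarray:
    """Subsample a correlated series at one integrated autocorrelation time."""
    values = np.asarray(values, dtype=float)
    tau = autocorrelation_time(values, dt=dt)
    stride = max(1, int(np.ceil(tau / dt)))
    return values[::stride]


def summary_table(summaries) -> "pandas.DataFrame":
    """Tabulate ChangeSummary records (Fig-3C / Fig-8 style report)."""
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition,
                "reference_mean": round(s.reference_mean, 3),
                "reference_sd": round(s.reference_sd, 3),
                "reference_sem": round(s.reference_sem, 3),
                "exposed_mean": round(s.exposed_mean, 3),
                "exposed_sd": round(s.exposed_sd, 3),
                "exposed_sem": round(s.exposed_sem, 3),
                "percent_change": round(s.percent_change, 1),
                "t": round(s.ttest.t_statistic, 3),
                "df": s.ttest.degrees_of_freedom,
                "p": s.ttest.p_value,
                "stars": s.ttest.stars,
            }
        )
    return pd.DataFrame(rows)
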