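"""Test-retest reliability statistics.

The central statistic is the single-measure, absolute-agreement intraclass
correlation from a two-way model (subjects random, trials fixed):

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with MSR/MSC/MSE the subject, trial and residual mean squares of the
two-way ANOVA on the n×k trial matrix.  The 95% confidence interval uses
the exact F-based bounds with a Satterthwaite degrees-of-freedom
approximation (McGraw–Wong), and the p-value tests ICC = 0 via
F = MSR/MSE on (n−1, (n−1)(k−1)) degrees of freedom.

Measurement error is summarised by the standard error of measurement
SEM = SD·√(1−ICC) and the minimum detectable change MDC = SEM·1.96·√2
(95% confidence on a difference of two measurements).  The SD entering
the SEM is the SD of all n·k trial values.

Between-limb asymmetry is the limb symmetry index
LSI = non-dominant/dominant·100 (%), physiological between 85 and 115%.

Study planning uses the Walter–Eliasziw–Donner approximation for the
number of subjects needed to distinguish reliability ρ1 from a null ρ0
with k repetitions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (EmptyInputError, InvalidConfigError, UndefinedIccError,
                     UndefinedLsiError)

__all__ = ["ReliabilityResult", "LsiResult", "icc_absolute_agreement",
           "sem_mdc", "lsi", "sample_size_reliability", "trial_matrix",
           "summarize_cohort", "average_icc", "CohortSummary",
           "lower_median"]


@dataclass
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    p: float
    sem: float
    mdc: float
    mean: float
    sd: float
    n: int
    k: int


@dataclass
class LsiResult:
    lsi: float                 # percent
    physiological: bool        # within the symmetry band


def icc_absolute_agreement(m, alpha: float = 0.05,
                           measures: str = "single") -> ReliabilityResult:
    """Absolute-agreement ICC of an n×k trial matrix (no missing cells).

    ``measures="average"`` returns the k-measurement (averaged-trials) form
    via the Spearman–Brown relation applied to the estimate and both
    confidence bounds.
    """
    Y = np.asarray(m, dtype=float)
    if Y.ndim != 2:
        raise InvalidConfigError("trial matrix must be 2-D (subjects × trials)")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise InvalidConfigError(f"need n >= 2 and k >= 2, got {n}×{k}")
    if np.isnan(Y).any():
        raise InvalidConfigError("trial matrix contains missing cells")

    mean = Y.mean()
    ssr = k * np.sum((Y.mean(axis=1) - mean) ** 2)
    ssc = n * np.sum((Y.mean(axis=0) - mean) ** 2)
    sst = np.sum((Y - mean) ** 2)
    sse = sst - ssr - ssc
    if sst <= 0:
        raise UndefinedIccError("zero total variance; ICC undefined")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # exact F-based CI with Satterthwaite df (absolute agreement, single)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        ci_low = ci_high = 1.0
    if mse > 0:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0

    if measures == "average":
        sb = lambda r: k * r / (1.0 + (k - 1) * r)  # noqa: E731
        icc, ci_low, ci_high = sb(icc), sb(ci_low), sb(ci_high)
    elif measures != "single":
        raise InvalidConfigError("measures must be 'single' or 'average'")

    sd = float(Y.std(ddof=1))
    sem, mdc = sem_mdc(sd, max(0.0, min(1.0, icc)))
    return ReliabilityResult(icc=float(icc), ci_low=float(ci_low),
                             ci_high=float(ci_high), p=p, sem=sem, mdc=mdc,
                             mean=float(mean), sd=sd, n=n, k=k)


def sem_mdc(sd: float, icc: float, z: float = 1.96):
    """Standard error of measurement and minimum detectable change."""
    if sd < 0:
        raise InvalidConfigError(f"sd must be >= 0, got {sd}")
    if not 0.0 <= icc <= 1.0:
        raise InvalidConfigError(f"icc must lie in [0, 1], got {icc}")
    sem = sd * np.sqrt(1.0 - icc)
    return float(sem), float(sem * z * np.sqrt(2.0))


def lsi(nondom: float, dom: float, band=(85.0, 115.0)) -> LsiResult:
    """Limb symmetry index: non-dominant over dominant, percent."""
    if dom == 0:
        raise UndefinedLsiError("dominant-limb value is zero; LSI undefined")
    value = nondom / dom * 100.0
    return LsiResult(lsi=float(value),
                     physiological=bool(band[0] <= value <= band[1]))


def sample_size_reliability(rho0: float, rho1: float, alpha: float = 0.05,
                            power: float = 0.8, k: int = 3,
                            sided: str = "two") -> int:
    """Subjects needed to show reliability ρ1 against a null ρ0.

    Walter–Eliasziw–Donner closed form:
    n = 1 + 2k(z_α + z_β)² / ((k−1)·(ln C0)²) with
    C0 = (1 + kρ0/(1−ρ0)) / (1 + kρ1/(1−ρ1)); rounded to the nearest
    integer.  ``sided`` selects a two-sided (z_{α/2}) or one-sided (z_α)
    significance level.
    """
    if not (0.0 <= rho0 < rho1 < 1.0):
        raise InvalidConfigError(
            f"need 0 <= rho0 < rho1 < 1, got rho0={rho0}, rho1={rho1}")
    if k < 2:
        raise InvalidConfigError(f"k must be >= 2, got {k}")
    z_a = stats.norm.ppf(1 - alpha / 2 if sided == "two" else 1 - alpha)
    z_b = stats.norm.ppf(power)
    c0 = (1 + k * rho0 / (1 - rho0)) / (1 + k * rho1 / (1 - rho1))
    n = 1 + 2 * k * (z_a + z_b) ** 2 / ((k - 1) * np.log(c0) ** 2)
    return int(np.floor(n + 0.5))


# --------------------------------------------------------------------------
# cohort-level summaries
# --------------------------------------------------------------------------

def lower_median(values) -> float:
    """Median using the lower of the two middle values for even counts."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise EmptyInputError("median of empty collection")
    return float(v[(len(v) - 1) // 2])


def _records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.extend(r.as_rows())
    if not rows:
        raise EmptyInputError("no feature records")
    return pd.DataFrame(rows)


def trial_matrix(records, parameter: str, limb: str, task: str):
    """n×k matrix of raw trial values for one parameter/limb/task.

    Subjects with missing trials are excluded listwise; returns
    ``(matrix, subjects, n_excluded)``.
    """
    df = _records_frame(records)
    sel = df[(df.parameter == parameter) & (df.limb == limb)
             & (df.task == task)].dropna(subset=["value"])
    if sel.empty:
        raise EmptyInputError(
            f"no records for {parameter}/{limb}/{task}")
    wide = sel.pivot_table(index="subject", columns="trial", values="value")
    complete = wide.dropna()
    return complete.to_numpy(), list(complete.index), len(wide) - len(complete)


@dataclass
class CohortSummary:
    """Cohort tables produced by :func:`summarize_cohort`."""

    medians: pd.DataFrame       # per subject × limb × task × parameter
    summary: pd.DataFrame       # cohort mean ± SD of the medians
    reliability: pd.DataFrame   # ICC / CI / p / SEM / MDC per condition
    lsi: pd.DataFrame           # per-subject LSI of medians + cohort stats


def summarize_cohort(records, alpha: float = 0.05,
                     lsi_band=(85.0, 115.0)) -> CohortSummary:
    """Cohort statistics from per-trial feature records.

    Per subject/limb/task/parameter the median over trials is taken (lower
    median for even trial counts); cohort means and SDs summarise the
    medians.  Reliability (ICC, CI, p, SEM, MDC) is computed per parameter
    and limb from the matrix of raw trial values.  The LSI is computed per
    subject from the medians, then summarised across the cohort.
    """
    df = _records_frame(records)
    med = (df.groupby(["subject", "limb", "task", "parameter"])["value"]
           .apply(lambda v: lower_median(v.dropna()) if v.notna().any()
                  else np.nan)
           .rename("median").reset_index())
    summary = (med.groupby(["task", "parameter", "limb"])["median"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_subjects="count")
               .reset_index())

    rel_rows = []
    for (task, parameter, limb), _ in df.groupby(
            ["task", "parameter", "limb"]):
        try:
            mat, subjects, n_excl = trial_matrix(records, parameter, limb,
                                                 task)
            res = icc_absolute_agreement(mat, alpha=alpha)
            rel_rows.append({
                "task": task, "parameter": parameter, "limb": limb,
                "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p, "sem": res.sem, "mdc": res.mdc,
                "mean": res.mean, "sd": res.sd, "n": res.n, "k": res.k,
                "n_excluded": n_excl,
            })
        except (UndefinedIccError, InvalidConfigError, EmptyInputError) as e:
            rel_rows.append({"task": task, "parameter": parameter,
                             "limb": limb, "icc": np.nan, "error": str(e)})
    reliability = pd.DataFrame(rel_rows)

    wide = med.pivot_table(index=["subject", "task", "parameter"],
                           columns="limb", values="median").reset_index()
    lsi_rows = []
    if {"dominant", "non-dominant"} <= set(wide.columns):
        for _, row in wide.dropna(
                subset=["dominant", "non-dominant"]).iterrows():
            if row["dominant"] == 0:
                continue
            res = lsi(row["non-dominant"], row["dominant"], band=lsi_band)
            lsi_rows.append({"subject": row["subject"], "task": row["task"],
                             "parameter": row["parameter"], "lsi": res.lsi,
                             "physiological": res.physiological})
    lsi_df = pd.DataFrame(lsi_rows)
    return CohortSummary(medians=med, summary=summary,
                         reliability=reliability, lsi=lsi_df)


def average_icc(reliability: pd.DataFrame, parameters,
                limbs=("dominant", "non-dominant"),
                task: str | None = None) -> float:
    """Mean ICC over a named parameter set, across the given limbs.

    Used for group-level comparisons such as acceleration-based versus
    angular-velocity-based parameter families.
    """
    sel = reliability[reliability.parameter.isin(list(parameters))
                      & reliability.limb.isin(list(limbs))]
    if task is not None:
        sel = sel[sel.task == task]
    if sel.empty:
        raise EmptyInputError("no ICC cells match the requested set")
    return float(sel["icc"].mean())
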