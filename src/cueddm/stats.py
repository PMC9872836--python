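"""Repeated-measures inference on per-subject condition summaries.

Implements the 2x2 fully-within ANOVA with generalized eta squared, paired
t-tests with Cohen's dz and the default JZS Bayes factor (Cauchy prior on
the standardized effect, scale 0.707, evaluated by adaptive quadrature), and
Cousineau-Morey within-participant SEMs for condition-mean error bars.

For the balanced 2x2 within design each effect has 1 and n-1 degrees of
freedom and the ANOVA F equals the square of the paired t on the marginal
means — a classical identity the test suite uses as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "rm_anova_2x2",
    "paired_t",
    "jzs_bf10",
    "within_subject_sem",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str  # "space" | "feature" | "interaction"
    F: float
    df1: int
    df2: int
    p: float
    eta_g2: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    dz: float
    bf10: float


def rm_anova_2x2(
    table: pd.DataFrame,
    dv: str,
    *,
    subject: str = "subject_id",
    space: str = "space_valid",
    feature: str = "feature_valid",
) -> list[AnovaResult]:
    """2x2 repeated-measures ANOVA from a long table (one row per cell).

    Every subject must contribute exactly one observation in each of the
    four cells (no imputation). Generalized eta squared uses the
    fully-within formulation: SS_effect / (SS_effect + all subject-related
    error SS, including the subject main effect).
    """
    wide = table.pivot_table(
        index=subject, columns=[space, feature], values=dv, aggfunc="first"
    )
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("incomplete design: every subject needs all four cells")
    n = wide.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")

    # Y[i, a, b]: a indexes space validity, b feature validity
    y = np.empty((n, 2, 2))
    for ai, sv in enumerate([False, True]):
        for bi, fv in enumerate([False, True]):
            y[:, ai, bi] = wide[(sv, fv)].to_numpy(float)

    grand = y.mean()
    subj_m = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    ab_m = y.mean(axis=0)
    ia_m = y.mean(axis=2)  # subject x space
    ib_m = y.mean(axis=1)  # subject x feature

    ss_subj = 4.0 * np.sum((subj_m - grand) ** 2)
    ss_a = 2.0 * n * np.sum((a_m - grand) ** 2)
    ss_b = 2.0 * n * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_as = 2.0 * np.sum(
        (ia_m - subj_m[:, None] - a_m[None, :] + grand) ** 2
    )
    ss_bs = 2.0 * np.sum(
        (ib_m - subj_m[:, None] - b_m[None, :] + grand) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    df2 = n - 1
    ss_error_all = ss_subj + ss_as + ss_bs + ss_abs

    results = []
    for name, ss_eff, ss_err in (
        ("space", ss_a, ss_as),
        ("feature", ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df2
        f = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        p = float(sps.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
        denom = ss_eff + ss_error_all
        eta = ss_eff / denom if denom > 0 else 0.0
        results.append(
            AnovaResult(effect=name, F=float(f), df1=1, df2=df2, p=p, eta_g2=float(eta))
        )
    return results


def jzs_bf10(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """Default JZS Bayes factor for a one-sample / paired t statistic.

    BF10 = integral of the noncentral-t likelihood over a Cauchy(0, r) prior
    on the standardized effect delta, divided by the likelihood at delta = 0.
    Evaluated by adaptive quadrature to relative tolerance ~1e-6.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, nu, delta * sqrt_n) * sps.cauchy.pdf(
            delta, 0.0, cauchy_scale
        )

    center = t / sqrt_n  # likelihood peaks near the observed effect
    lo, err_lo = integrate.quad(
        integrand, -np.inf, center, epsabs=0.0, epsrel=1e-9, limit=200
    )
    hi, err_hi = integrate.quad(
        integrand, center, np.inf, epsabs=0.0, epsrel=1e-9, limit=200
    )
    marginal = lo + hi
    null_like = sps.t.pdf(t, nu)
    return float(marginal / null_like)


def paired_t(
    cond_a,
    cond_b,
    cauchy_scale: float = 0.707,
) -> TTestResult:
    """Paired t-test with Cohen's dz and the JZS Bayes factor.

    ``dz = mean(diff) / sd(diff)``; the sign convention is ``cond_a -
    cond_b``. Rejects zero-variance differences (t undefined).
    """
    x = np.asarray(cond_a, float)
    y = np.asarray(cond_b, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences; t is undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    dz = float(d.mean() / sd)
    return TTestResult(t=t, df=df, p=p, dz=dz, bf10=jzs_bf10(t, n, cauchy_scale))


def within_subject_sem(wide: pd.DataFrame) -> pd.Series:
    """Cousineau-Morey within-participant SEM per condition.

    ``wide`` is subjects x conditions. Each row is recentered on the grand
    mean (removing between-subject offsets), the per-condition SD of the
    normalized scores is converted to an SEM, and the Morey bias correction
    sqrt(k / (k - 1)) is applied for k conditions.
    """
    if wide.shape[1] < 2:
        raise ValueError("need at least two conditions")
    if wide.isna().any().any():
        raise ValueError("complete table required")
    n, k = wide.shape
    normalized = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    sem = normalized.std(ddof=1) / np.sqrt(n)
    return sem * np.sqrt(k / (k - 1))
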