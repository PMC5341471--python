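"""Method-agreement statistics for paired measurements.

Standalone, formula-level implementations of the statistical procedures
used to validate one measurement method against another on the same
subjects:

* Pearson correlation with the conventional strength bands
  (negligible / low / moderate / high / very high),
* Bland-Altman limits of agreement, both the plain form and the
  replicate-corrected form for analyses based on per-subject means of
  repeated measurements (two observers per modality being the typical
  case),
* Steiger's z-test for two dependent, overlapping correlations (two
  correlations sharing one variable),
* a normality-routed paired test: Shapiro-Wilk on the paired
  differences decides between the paired Student t-test and the
  Wilcoxon signed-rank test,
* the paired-design sample-size calculation via the noncentral-t power
  function.

Conventions follow common statistical-package defaults: the Wilcoxon
signed-rank drops zero differences, uses mid-ranks for ties, and a
tie-corrected normal approximation without continuity correction; the
limits-of-agreement multiplier is the fixed normal quantile 1.96.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DataError,
    DegenerateSampleError,
    DomainError,
    SampleSizeError,
)

__all__ = [
    "PairedSample",
    "PearsonResult",
    "BlandAltmanResult",
    "SteigerResult",
    "RoutedTestResult",
    "PairedTestKind",
    "PowerSpec",
    "correlation_band",
    "pearson_with_band",
    "bland_altman",
    "bland_altman_replicate_corrected",
    "steiger_z",
    "routed_paired_test",
    "wilcoxon_signed_rank",
    "wilcoxon_exact_p",
    "paired_t_power",
    "sample_size_paired",
    "LOA_MULTIPLIER",
]

#: Limits-of-agreement multiplier (normal 95% quantile, not t-based).
LOA_MULTIPLIER = 1.96

#: Band edges for interpreting |r|; an edge value belongs to the upper band.
_BANDS = (
    (0.3, "negligible"),
    (0.5, "low"),
    (0.7, "moderate"),
    (0.9, "high"),
    (np.inf, "very high"),
)


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement vectors, one entry per subject.

    Paired differences throughout this module are ``values_b - values_a``;
    callers choose the direction by argument order and name it via the
    labels.
    """

    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise DataError("values_a and values_b must be equal-length 1-D vectors")
        if a.size < 3:
            raise SampleSizeError(f"need at least 3 pairs, got {a.size}")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise DataError("paired sample contains non-finite entries")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def n(self) -> int:
        return int(self.values_a.size)

    @property
    def differences(self) -> np.ndarray:
        return self.values_b - self.values_a


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    band: str
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired differences."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    corrected: bool
    n: int
    label: str = ""


@dataclass(frozen=True)
class SteigerResult:
    z_statistic: float
    p_value: float
    r12: float
    r13: float
    r23: float
    n: int


class PairedTestKind(str, Enum):
    PAIRED_T = "paired_t"
    WILCOXON = "wilcoxon"


@dataclass(frozen=True)
class RoutedTestResult:
    test_used: PairedTestKind
    statistic: float
    p_value: float
    normality_p: float
    n_effective: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a paired-design sample-size calculation.

    delta : detectable mean paired difference (same units as the data)
    sd    : assumed standard deviation of the paired differences
    power : target power, in (0, 1)
    alpha : two-sided significance level, in (0, 1)
    """

    delta: float
    sd: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.delta > 0):
            raise DomainError(f"delta must be > 0, got {self.delta!r}")
        if not (self.sd > 0):
            raise DomainError(f"sd must be > 0, got {self.sd!r}")
        if not (0 < self.power < 1):
            raise DomainError(f"power must be in (0, 1), got {self.power!r}")
        if not (0 < self.alpha < 1):
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha!r}")


# ---------------------------------------------------------------------------
# Pearson correlation with strength bands
# ---------------------------------------------------------------------------

def correlation_band(r: float) -> str:
    """Strength label for a correlation coefficient, based on ``|r|``.

    Half-open from below: 0.3 -> "low", 0.7 -> "high", 0.9 -> "very high".
    """
    a = abs(r)
    if a > 1 + 1e-12:
        raise DomainError(f"|r| must be <= 1, got {r!r}")
    for edge, label in _BANDS:
        if a < edge:
            return label
    return "very high"  # pragma: no cover


def pearson_with_band(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, str]:
    """Pearson r, its two-sided p-value and the strength band label.

    The p-value comes from the t-distribution with ``n - 2`` degrees of
    freedom.  Constant input vectors have no defined correlation and
    raise :class:`DomainError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise DataError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise SampleSizeError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation is undefined for a constant vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, float(res.pvalue), correlation_band(r)


def pearson_result(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """:func:`pearson_with_band` packaged as a :class:`PearsonResult`."""
    r, p, band = pearson_with_band(x, y)
    return PearsonResult(r=r, p_value=p, band=band, n=len(np.asarray(x)))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(s: PairedSample) -> BlandAltmanResult:
    """Plain Bland-Altman bias and 95% limits of agreement.

    bias = mean(b - a); LoA = bias +/- 1.96 * SD of the differences
    (sample SD, ddof 1).
    """
    d = s.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        corrected=False,
        n=s.n,
        label=f"{s.label_b} - {s.label_a}",
    )


def _within_subject_variance(replicates: list[np.ndarray]) -> float:
    """Pooled within-subject variance from per-subject replicate vectors.

    One-way components-of-variance estimate:
    ``sum_i sum_j (x_ij - mean_i)^2 / sum_i (m_i - 1)``; zero when no
    subject has more than one replicate.
    """
    ss = 0.0
    df = 0
    for reps in replicates:
        m = reps.size
        if m > 1:
            ss += float(np.sum((reps - reps.mean()) ** 2))
            df += m - 1
    return ss / df if df > 0 else 0.0


def _harmonic_mean_counts(replicates: list[np.ndarray]) -> float:
    counts = np.array([r.size for r in replicates], dtype=float)
    return counts.size / float(np.sum(1.0 / counts))


def bland_altman_replicate_corrected(
    a_replicates: Sequence[Sequence[float]],
    b_replicates: Sequence[Sequence[float]],
    label_a: str = "A",
    label_b: str = "B",
) -> BlandAltmanResult:
    """Bland-Altman on per-subject replicate means, with corrected SD.

    When each method is measured several times per subject (replicate
    cycles, multiple observers) and the agreement analysis is run on the
    per-subject means, the SD of the mean differences understates the
    single-measurement disagreement.  The corrected variance restores the
    averaged-out within-subject components::

        var_corr = Var(mean_b_i - mean_a_i)
                   + (1 - 1/m_a) * s2w_a + (1 - 1/m_b) * s2w_b

    with ``s2w`` the pooled within-subject (between-replicate) variance
    per method and ``m`` the harmonic mean of per-subject replicate
    counts (exact for the balanced two-replicate design).  With one
    replicate everywhere, or with zero within-subject variance, this
    reduces to the plain analysis on the means.
    """
    a = [np.asarray(r, dtype=float).ravel() for r in a_replicates]
    b = [np.asarray(r, dtype=float).ravel() for r in b_replicates]
    if len(a) != len(b):
        raise DataError("methods must have the same number of subjects")
    if any(r.size == 0 for r in a) or any(r.size == 0 for r in b):
        raise DataError("every subject needs at least one replicate per method")
    n = len(a)
    if n < 3:
        raise SampleSizeError(f"need at least 3 subjects, got {n}")
    mean_a = np.array([r.mean() for r in a])
    mean_b = np.array([r.mean() for r in b])
    d = mean_b - mean_a
    bias = float(np.mean(d))
    var_means = float(np.var(d, ddof=1))
    s2w_a = _within_subject_variance(a)
    s2w_b = _within_subject_variance(b)
    m_a = _harmonic_mean_counts(a)
    m_b = _harmonic_mean_counts(b)
    var_corr = var_means + (1.0 - 1.0 / m_a) * s2w_a + (1.0 - 1.0 / m_b) * s2w_b
    sd = math.sqrt(var_corr)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        corrected=True,
        n=n,
        label=f"{label_b} - {label_a}",
    )


# ---------------------------------------------------------------------------
# Steiger's z for dependent overlapping correlations
# ---------------------------------------------------------------------------

def _fisher_z(r: float) -> float:
    return math.atanh(r)


def steiger_z(r12: float, r13: float, r23: float, n: int) -> SteigerResult:
    """Steiger's test for two dependent correlations sharing variable 1.

    Tests ``H0: rho12 = rho13`` where both correlations involve the same
    variable (here: two index measurements each correlated with the same
    reference).  Uses the pooled-estimate variant::

        rbar = (r12 + r13) / 2
        psi  = r23 * (1 - 2*rbar^2) - rbar^2 * (1 - 2*rbar^2 - r23^2) / 2
        cbar = psi / (1 - rbar^2)^2
        z    = (atanh(r12) - atanh(r13)) * sqrt(n - 3) / sqrt(2 - 2*cbar)

    with a two-sided p from the standard normal.  The correlation triple
    must form a positive-definite 3x3 correlation matrix.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not math.isfinite(r) or abs(r) >= 1.0:
            raise DomainError(f"{name} must satisfy |r| < 1, got {r!r}")
    if n < 4:
        raise SampleSizeError(f"need n >= 4 subjects, got {n}")
    det = 1.0 + 2.0 * r12 * r13 * r23 - r12**2 - r13**2 - r23**2
    if det <= 0.0:
        raise DomainError(
            f"(r12, r13, r23) = ({r12}, {r13}, {r23}) is not a valid correlation "
            f"triple (determinant {det:.3g} <= 0)"
        )
    rbar = 0.5 * (r12 + r13)
    psi = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
        1.0 - 2.0 * rbar**2 - r23**2
    )
    cbar = psi / (1.0 - rbar**2) ** 2
    z = (_fisher_z(r12) - _fisher_z(r13)) * math.sqrt(n - 3) / math.sqrt(
        2.0 - 2.0 * cbar
    )
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return SteigerResult(z_statistic=z, p_value=p, r12=r12, r13=r13, r23=r23, n=n)


# ---------------------------------------------------------------------------
# Normality-routed paired test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    differences: Sequence[float], continuity: bool = False
) -> tuple[float, float, int]:
    """Wilcoxon signed-rank via the tie-corrected normal approximation.

    Zero differences are dropped; absolute differences get mid-ranks;
    ``Z = (T+ - mu_T) / sigma_T`` where ``T+`` is the positive-rank sum,
    ``mu_T = n(n+1)/4`` and ``sigma_T`` carries the tie correction
    ``- sum(t^3 - t)/48``.  The reported statistic applies no continuity
    correction (the convention of the routed paired test); passing
    ``continuity=True`` shrinks the deviation by half a rank unit, which
    is the appropriate form when comparing the normal tail against the
    discrete exact enumeration.  Returns ``(Z, two-sided p, n_effective)``.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateSampleError("zero variance in signed-rank statistic")
    dev = t_plus - mu
    if continuity:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, min(p, 1.0), n


def wilcoxon_exact_p(differences: Sequence[float]) -> float:
    """Exact two-sided signed-rank p by full sign enumeration (n <= 12).

    Cross-check mode for the normal approximation: enumerates all 2^n
    sign assignments of the (mid-)ranks and returns
    ``P(|T+ - mu| >= |t_obs - mu|)`` under the exchangeable-sign null.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    if n > 12:
        raise DomainError(f"exact enumeration limited to n <= 12, got {n}")
    ranks = stats.rankdata(np.abs(d))
    t_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    t_all = signs @ ranks
    return float(np.mean(np.abs(t_all - mu) >= abs(t_obs - mu) - 1e-9))


def routed_paired_test(
    s: PairedSample, alpha_normality: float = 0.05
) -> RoutedTestResult:
    """Paired test routed by a Shapiro-Wilk normality check.

    The Shapiro-Wilk test runs on the paired differences ``b - a``.  If
    its p-value is at least ``alpha_normality`` the paired Student
    t-test is used, otherwise the Wilcoxon signed-rank test (see
    :func:`wilcoxon_signed_rank` for its conventions).
    """
    d = s.differences
    if np.all(d == 0.0):
        raise DegenerateSampleError("all paired differences are zero")
    if np.ptp(d) == 0.0:
        raise DegenerateSampleError(
            "all paired differences are identical; normality is undefined"
        )
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= alpha_normality:
        t_res = stats.ttest_1samp(d, 0.0)
        return RoutedTestResult(
            test_used=PairedTestKind.PAIRED_T,
            statistic=float(t_res.statistic),
            p_value=float(t_res.pvalue),
            normality_p=sw_p,
            n_effective=s.n,
        )
    z, p, n_eff = wilcoxon_signed_rank(d)
    return RoutedTestResult(
        test_used=PairedTestKind.WILCOXON,
        statistic=z,
        p_value=p,
        normality_p=sw_p,
        n_effective=n_eff,
    )


# ---------------------------------------------------------------------------
# Paired-design sample size
# ---------------------------------------------------------------------------

def paired_t_power(n: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test at ``n`` subjects.

    Noncentral-t power with noncentrality ``(delta/sd) * sqrt(n)`` and
    ``n - 1`` degrees of freedom.
    """
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    df = n - 1
    nc = (delta / sd) * math.sqrt(n)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
    )


def sample_size_paired(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n for which the paired t-test attains the target power.

    Iterates the noncentral-t power function upward from ``n = 2``
    (doubling then bisecting) and returns the minimal integer n whose
    power is at least ``spec.power``.
    """
    lo, hi = 2, 2
    while paired_t_power(hi, spec.delta, spec.sd, spec.alpha) < spec.power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise DomainError(
                f"target power {spec.power} not reached below n = {n_max}"
            )
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(mid, spec.delta, spec.sd, spec.alpha) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return hi
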