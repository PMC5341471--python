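import numpy as np
import pytest
from scipy import stats

from rvellipse import (
    PairedSample,
    PairedTestKind,
    PowerSpec,
    bland_altman,
    bland_altman_replicate_corrected,
    correlation_band,
    paired_t_power,
    pearson_with_band,
    routed_paired_test,
    sample_size_paired,
    steiger_z,
    wilcoxon_exact_p,
    wilcoxon_signed_rank,
)
from rvellipse.exceptions import (
    DataError,
    DegenerateSampleError,
    DomainError,
    SampleSizeError,
)

from helpers import (
    replicate_corrected_sd_oracle,
    simulated_paired_t_power,
    steiger_z_oracle,
)


# ---------------------------------------------------------------------------
# Pearson with bands
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r, band",
    [
        (0.1, "negligible"), (0.80, "high"), (0.54, "moderate"),
        (0.95, "very high"), (-0.6, "moderate"),
        # boundary values belong to the upper band
        (0.3, "low"), (0.5, "moderate"), (0.7, "high"), (0.9, "very high"),
        (1.0, "very high"),
    ],
)
def test_correlation_band(r, band):
    assert correlation_band(r) == band


def test_pearson_identity_is_very_high():
    x = np.arange(10.0)
    r, p, band = pearson_with_band(x, x)
    assert r == pytest.approx(1.0)
    assert band == "very high"


def test_pearson_matches_scipy_and_constant_rejected(rng):
    x, y = rng.normal(size=20), rng.normal(size=20)
    r, p, _ = pearson_with_band(x, y)
    ref = stats.pearsonr(x, y)
    assert (r, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))
    with pytest.raises(DomainError):
        pearson_with_band(np.ones(5), y[:5])


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_bland_altman_identical_pairs():
    res = bland_altman(PairedSample([1, 2, 3], [1, 2, 3]))
    assert res.bias == 0.0
    assert res.loa_lower == res.loa_upper == 0.0


def test_bland_altman_arithmetic():
    # differences {4, 6, 8}: bias 6, sd 2, LoA 6 +/- 1.96*2
    res = bland_altman(PairedSample([0, 0, 0], [4, 6, 8]))
    assert res.bias == pytest.approx(6.0)
    assert res.sd_diff == pytest.approx(2.0)
    assert res.loa_lower == pytest.approx(2.08)
    assert res.loa_upper == pytest.approx(9.92)
    # invariants: midpoint and width
    assert (res.loa_lower + res.loa_upper) / 2 == pytest.approx(res.bias)
    assert res.loa_upper - res.loa_lower == pytest.approx(2 * 1.96 * res.sd_diff)


def test_bland_altman_large_sample_recovers_parameters(rng):
    d = rng.normal(6.0, 8.7, size=100_000)
    res = bland_altman(PairedSample(np.zeros_like(d), d))
    assert res.bias == pytest.approx(6.0, abs=0.1)
    assert res.loa_lower == pytest.approx(6 - 1.96 * 8.7, abs=0.2)
    assert res.loa_upper == pytest.approx(6 + 1.96 * 8.7, abs=0.2)


def test_bland_altman_needs_three_pairs():
    with pytest.raises(SampleSizeError):
        PairedSample([1, 2], [1, 2])


def test_replicate_correction_vanishes_for_identical_replicates(rng):
    a = rng.normal(40, 10, size=8)
    b = a + rng.normal(6, 3, size=8)
    corrected = bland_altman_replicate_corrected(
        [[v, v] for v in a], [[v, v] for v in b]
    )
    plain = bland_altman(PairedSample(a, b))
    assert corrected.bias == pytest.approx(plain.bias)
    assert corrected.sd_diff == pytest.approx(plain.sd_diff)
    assert corrected.corrected is True


def test_single_replicates_equal_plain_analysis(rng):
    a = rng.normal(40, 10, size=10)
    b = a + rng.normal(0, 5, size=10)
    corrected = bland_altman_replicate_corrected([[v] for v in a], [[v] for v in b])
    plain = bland_altman(PairedSample(a, b))
    assert corrected.sd_diff == pytest.approx(plain.sd_diff)
    assert corrected.loa_upper == pytest.approx(plain.loa_upper)


def test_replicate_corrected_matches_anova_oracle():
    a = [[38.0, 42.0], [50.0, 46.0], [30.0, 34.0],
         [55.0, 51.0], [44.0, 40.0], [60.0, 62.0]]
    b = [[45.0, 51.0], [52.0, 58.0], [39.0, 41.0],
         [60.0, 64.0], [47.0, 55.0], [66.0, 70.0]]
    res = bland_altman_replicate_corrected(a, b)
    assert res.sd_diff == pytest.approx(replicate_corrected_sd_oracle(a, b), abs=1e-6)
    assert res.bias == pytest.approx(
        np.mean([np.mean(bi) - np.mean(ai) for ai, bi in zip(a, b)])
    )


def test_replicate_corrected_sd_at_least_uncorrected(rng):
    """Correction is monotone: corrected SD >= SD of the mean differences."""
    a = [rng.normal(40, 10, size=2) for _ in range(12)]
    b = [rng.normal(46, 10, size=2) for _ in range(12)]
    res = bland_altman_replicate_corrected(a, b)
    plain_sd = np.std(
        [np.mean(bi) - np.mean(ai) for ai, bi in zip(a, b)], ddof=1
    )
    assert res.sd_diff >= plain_sd


def test_replicate_corrected_rejects_empty_subject():
    with pytest.raises(DataError):
        bland_altman_replicate_corrected([[1.0], [], [2.0]], [[1.0], [2.0], [3.0]])


# ---------------------------------------------------------------------------
# Steiger's z
# ---------------------------------------------------------------------------

def test_steiger_zero_when_correlations_equal():
    res = steiger_z(0.6, 0.6, 0.4, n=30)
    assert res.z_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_steiger_matches_independent_oracle():
    res = steiger_z(0.80, 0.54, 0.60, n=37)
    assert res.z_statistic == pytest.approx(
        steiger_z_oracle(0.80, 0.54, 0.60, 37), abs=1e-6
    )
    assert 0 < res.p_value < 0.05  # the two correlations differ significantly


def test_steiger_antisymmetric_in_swapped_correlations():
    a = steiger_z(0.80, 0.54, 0.60, n=37)
    b = steiger_z(0.54, 0.80, 0.60, n=37)
    assert a.z_statistic == pytest.approx(-b.z_statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_steiger_domain_errors():
    with pytest.raises(DomainError):
        steiger_z(1.0, 0.5, 0.5, n=30)  # degenerate correlation
    with pytest.raises(DomainError, match="determinant"):
        steiger_z(0.9, -0.9, 0.9, n=30)  # not positive definite
    with pytest.raises(SampleSizeError):
        steiger_z(0.5, 0.4, 0.3, n=3)


# ---------------------------------------------------------------------------
# Routed paired test / Wilcoxon
# ---------------------------------------------------------------------------

def test_wilcoxon_antisymmetric_differences_give_zero_z():
    d = [+1, -1, +2, -2, +3, -3, +4, -4]
    z, p, n = wilcoxon_signed_rank(d)
    assert z == 0.0
    assert p == pytest.approx(1.0)
    assert n == 8


def test_wilcoxon_matches_scipy_approximation(rng):
    d = rng.normal(2, 3, size=25).round(1)
    d = d[d != 0]
    z, p, _ = wilcoxon_signed_rank(d)
    ref = stats.wilcoxon(d, correction=False, method="approx")
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_wilcoxon_normal_approximation_near_exact_enumeration(rng):
    """The continuity-adjusted normal tail tracks the exact discrete
    enumeration; without the adjustment agreement is looser but the two
    p-values order samples identically."""
    for _ in range(10):
        mags = rng.choice(np.arange(1, 20), size=8, replace=False)
        d = mags * rng.choice([-1, 1], size=8)
        _, p_cc, _ = wilcoxon_signed_rank(d, continuity=True)
        assert abs(p_cc - wilcoxon_exact_p(d)) < 0.05


def test_routed_to_t_for_normal_differences(rng):
    a = rng.normal(40, 10, size=30)
    b = a + rng.normal(6, 5, size=30)
    res = routed_paired_test(PairedSample(a, b))
    assert res.test_used is PairedTestKind.PAIRED_T
    assert res.normality_p >= 0.05
    ref = stats.ttest_rel(b, a)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_routed_to_wilcoxon_for_skewed_differences(rng):
    a = np.zeros(60)
    b = rng.exponential(5, size=60) ** 2  # strongly right-skewed differences
    res = routed_paired_test(PairedSample(a, b))
    assert res.test_used is PairedTestKind.WILCOXON
    assert res.normality_p < 0.05
    # all differences positive -> maximal positive rank sum -> z > 0
    assert res.statistic > 0


def test_degenerate_differences_raise():
    with pytest.raises(DegenerateSampleError):
        routed_paired_test(PairedSample([1, 2, 3], [1, 2, 3]))  # all zero
    with pytest.raises(DegenerateSampleError):
        routed_paired_test(PairedSample([1, 2, 3], [4, 5, 6]))  # all equal


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

def test_sample_size_reference_case():
    assert sample_size_paired(PowerSpec(delta=5, sd=10, power=0.80, alpha=0.05)) == 34


def test_sample_size_minimality_and_simulated_power():
    spec = PowerSpec(delta=5, sd=10, power=0.80, alpha=0.05)
    n = sample_size_paired(spec)
    assert paired_t_power(n, 5, 10, 0.05) >= 0.80
    assert paired_t_power(n - 1, 5, 10, 0.05) < 0.80
    sim = simulated_paired_t_power(n, 5, 10, 0.05, reps=50_000, seed=7)
    assert sim >= 0.80 - 0.01


def test_sample_size_agrees_with_linear_scan_oracle():
    for delta, sd, power, alpha in [(5, 10, 0.8, 0.05), (3, 6, 0.9, 0.05),
                                    (50, 10, 0.8, 0.05), (2, 10, 0.5, 0.1)]:
        spec = PowerSpec(delta=delta, sd=sd, power=power, alpha=alpha)
        n = sample_size_paired(spec)
        scan = 2
        while paired_t_power(scan, delta, sd, alpha) < power:
            scan += 1
        assert n == scan


def test_sample_size_cross_checked_against_statsmodels():
    import statsmodels.stats.power as smp

    for es, power in [(0.5, 0.8), (0.3, 0.9), (1.0, 0.8)]:
        n = sample_size_paired(PowerSpec(delta=es, sd=1.0, power=power))
        ref = smp.TTestPower().solve_power(effect_size=es, alpha=0.05, power=power)
        assert n == int(np.ceil(ref))


def test_sample_size_monotonicity():
    base = PowerSpec(delta=5, sd=10, power=0.8, alpha=0.05)
    n0 = sample_size_paired(base)
    assert sample_size_paired(PowerSpec(8, 10, 0.8, 0.05)) <= n0  # easier effect
    assert sample_size_paired(PowerSpec(5, 14, 0.8, 0.05)) >= n0  # noisier
    assert sample_size_paired(PowerSpec(5, 10, 0.9, 0.05)) >= n0  # more power
    assert sample_size_paired(PowerSpec(5, 10, 0.8, 0.01)) >= n0  # stricter alpha


def test_power_spec_validation():
    with pytest.raises(DomainError):
        PowerSpec(delta=0, sd=10)
    with pytest.raises(DomainError):
        PowerSpec(delta=5, sd=10, power=1.0)
    with pytest.raises(DomainError):
        PowerSpec(delta=5, sd=10, alpha=0.0)
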