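"""Independent oracles used by the test suite.

Everything here is deliberately coded from first principles, separate
from the library implementation, so the tests compare two routes to the
same quantity.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def voxel_count_ellipsoid_volume_ml(
    d1_cm: float, d2_cm: float, d3_cm: float, voxel_mm: float
) -> float:
    """Ellipsoid volume by counting voxel centers inside the surface.

    Diameters in cm; voxel grid of pitch ``voxel_mm`` with centers at
    half-integer multiples of the pitch, symmetric about the origin.
    For each (z, y) column the number of in-surface x-centers follows in
    closed form from the half-width of the ellipse section, which makes
    the count exact for the given grid without materializing it.
    """
    a, b, c = 5.0 * d1_cm, 5.0 * d2_cm, 5.0 * d3_cm  # semi-axes in mm
    h = voxel_mm

    def centers(extent: float) -> np.ndarray:
        k = int(np.floor(extent / h + 0.5))
        return (np.arange(-k, k) + 0.5) * h

    zs = centers(c)
    ys = centers(b)
    total = 0
    for z in zs:
        r2 = 1.0 - (z / c) ** 2
        if r2 <= 0:
            continue
        inside = r2 - (ys / b) ** 2
        mask = inside > 0
        xmax = a * np.sqrt(inside[mask])
        # number of half-integer centers (i + 0.5) h in [-xmax, xmax]
        counts = np.floor(xmax / h - 0.5) + np.floor(xmax / h + 0.5) + 1
        counts = np.maximum(counts, 0)
        total += counts.sum()
    return float(total) * h**3 / 1000.0


def steiger_z_oracle(r12: float, r13: float, r23: float, n: int) -> float:
    """Independent coding of the pooled-estimate dependent-correlation z.

    Written in matrix form rather than scalar algebra: the covariance of
    the two Fisher-transformed correlations sharing a variable is
    ``cbar = psi / (1 - rbar^2)^2`` with ``psi`` the pooled covariance
    expression, and the z follows from the difference of the transforms.
    """
    rbar = np.mean([r12, r13])
    psi = (
        r23 * (1 - 2 * rbar**2)
        - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    )
    cbar = psi / (1 - rbar**2) ** 2
    dz = np.arctanh(r12) - np.arctanh(r13)
    return float(dz * np.sqrt((n - 3) / (2 - 2 * cbar)))


def steiger_null_rejection_rate(
    n: int, reps: int, rho: float, alpha: float, seed: int
) -> float:
    """Type-I error of the dependent-correlation test by simulation.

    Draws ``reps`` samples of size ``n`` from a trivariate normal with
    all pairwise correlations equal to ``rho`` (so the two compared
    population correlations are equal), computes the three sample
    correlations and the z statistic fully vectorized, and returns the
    fraction of two-sided p-values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((reps, n, 3)) @ L.T
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    r12 = np.einsum("ri,ri->r", Xc[:, :, 0], Xc[:, :, 1])
    r13 = np.einsum("ri,ri->r", Xc[:, :, 0], Xc[:, :, 2])
    r23 = np.einsum("ri,ri->r", Xc[:, :, 1], Xc[:, :, 2])
    rbar = 0.5 * (r12 + r13)
    psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    cbar = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r12) - np.arctanh(r13)) * np.sqrt(n - 3) / np.sqrt(2 - 2 * cbar)
    p = 2 * stats.norm.sf(np.abs(z))
    return float(np.mean(p < alpha))


def replicate_corrected_sd_oracle(
    a_reps: list[list[float]], b_reps: list[list[float]]
) -> float:
    """Hand-computed components-of-variance corrected SD.

    Direct ANOVA arithmetic: pooled within-subject mean square per
    method, harmonic-mean replicate counts, corrected variance of the
    per-subject mean differences.
    """
    def within_ms(groups):
        ss, df = 0.0, 0
        for g in groups:
            g = np.asarray(g, float)
            ss += np.sum((g - g.mean()) ** 2)
            df += len(g) - 1
        return ss / df if df else 0.0

    def harm(groups):
        ms = np.array([len(g) for g in groups], float)
        return len(ms) / np.sum(1.0 / ms)

    d = np.array([np.mean(b) for b in b_reps]) - np.array(
        [np.mean(a) for a in a_reps]
    )
    var = np.var(d, ddof=1)
    var += (1 - 1 / harm(a_reps)) * within_ms(a_reps)
    var += (1 - 1 / harm(b_reps)) * within_ms(b_reps)
    return float(np.sqrt(var))


def simulated_paired_t_power(
    n: int, delta: float, sd: float, alpha: float, reps: int, seed: int
) -> float:
    """Power of the two-sided paired t-test by direct simulation."""
    rng = np.random.default_rng(seed)
    d = rng.normal(delta, sd, size=(reps, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
    return float(np.mean(np.abs(t) > t_crit))
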