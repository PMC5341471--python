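# Methods

This note documents the models, statistical conventions and numerical
choices behind `rvellipse`, in the spirit of a methods appendix: what
is computed, under which assumptions, and what the synthetic-data tests
do and do not demonstrate.

## Ellipsoid RV model

The right ventricle is approximated as an ellipsoid whose three
diameters are the TTE distances RVIT₃, RVLAX (apical four-chamber
view) and LVD (apical two-chamber view); the volume is
`(π/6)·RVIT₃·RVLAX·LVD`. With distances in cm the volume is in mL.
The formula is symmetric in the three distances and homogeneous of
degree 3, so a uniform caliper scale error of factor k biases volumes
by k³ but cancels exactly in the EF quota — the reason the model is
used for EF rather than absolute volume.

Units are cm for distances and mL for volumes throughout the library;
the CLI accepts `--units mm` and divides by 10 before computing,
because CMR tools report mm/mL while echo calipers report cm.

`ESV > EDV` (negative EF) is carried as a warning flag, not an error:
noisy retrospective measurements can invert a pair, and the agreement
statistics must keep every subject. EF is held at full floating
precision internally; rounding to integer percent happens only at
serialization/display time.

## Disk-summation reference volumetry

Reference volumes are `Σᵢ countᵢ · pixel_spacing² · slice_spacing`
over a base-to-apex stack of binary endocardial masks, divided by 1000
for mL. Two conventions matter:

- The slice factor is the **center-to-center slice spacing**, not the
  slice thickness. Clinical short-axis stacks are often gapped (5 mm
  thick slices every 8 mm); summation over the spacing tiles the long
  axis exactly, which is what makes the midpoint-style sum converge to
  the true volume.
- Basal-slice adjudication (deciding how much of the most basal slice
  belongs to the ventricle, using the valve-plane information) is a
  manual decision in practice and is **not** re-implemented as an image
  algorithm; mask stacks are taken as already adjudicated. The phantom
  generator instead exposes a `basal_clip_fraction` so clipped shapes
  can be tested against their exact analytic segment volume.

Voxelization and disk summation are midpoint rules: the error for a
smooth convex shape decreases with the grid, but its sign oscillates
with the phase of the grid relative to the shape, so the error of a
*single* shape is not monotone across spacing halvings — at a fine
fixed pixel size a coarser slice spacing can be accidentally more
accurate. The convergence tests therefore refine pixel and slice
spacing jointly (1.5/8 → 1.0/4 → 0.5/2 mm) and compare errors averaged
over several shapes; at 1.5 mm pixels and 8 mm spacing the volume error
for ventricle-sized ellipsoids is below 5 %, at 0.5/2 mm below 1 %.

## Agreement statistics

All paired differences are `b − a` with the two method labels carried
in every result; for the headline echo-vs-reference comparison the
configured direction is `TTE − CMR`, so a positive bias means the
ellipsoid model overestimates EF relative to CMR.

**Pearson bands.** |r| is labelled negligible / low / moderate / high /
very high with edges 0.3, 0.5, 0.7, 0.9. The conventional open
intervals leave the edges unassigned; the package deterministically
assigns an edge to the upper band (0.7 → "high").

**Bland-Altman.** Limits of agreement are `bias ± 1.96·SD` with the
fixed normal multiplier (standard practice; not t-based). When the
analysis runs on per-subject means of replicate measurements (here:
two observers per modality), the SD of the mean differences
understates single-measurement disagreement; the corrected variance

```
Var_corr = Var(mean diffs) + (1 − 1/m_A)·σ²_w,A + (1 − 1/m_B)·σ²_w,B
```

restores the averaged-out within-subject components, with σ²_w the
pooled within-subject (between-replicate) variance per method from a
one-way components-of-variance decomposition and m the harmonic mean
of per-subject replicate counts (exact for the balanced two-observer
design; the harmonic mean degrades gracefully under imbalance). With
one replicate everywhere, or zero within-subject variance, the
correction vanishes and the result equals the plain analysis; the
corrected SD is never smaller than the uncorrected one.

**Dependent correlations.** Whether the echo model correlates with the
reference better than TAPSE does is a comparison of two correlations
sharing a variable (the reference EF). The package implements the
pooled-estimate z-test for dependent overlapping correlations
(Fisher-transform difference scaled by the pooled covariance term;
the Z̄₁\*-type variant, chosen over Williams' t for its simple normal
reference distribution). The correlation triple must form a
positive-definite matrix; |r| = 1 is rejected as degenerate. Type-I
error at the study's n = 37 is calibrated by simulation in the test
suite (10,000 trivariate-normal null replicates; rejection rate within
[0.04, 0.06] at α = 0.05).

**Routed paired test.** Shapiro-Wilk on the paired differences at
α = 0.05 routes to the paired Student t (normal) or the Wilcoxon
signed-rank (non-normal). Wilcoxon conventions: zero differences
dropped, mid-ranks for ties, tie-corrected variance, no continuity
correction in the reported Z — matching mainstream statistical-package
defaults. Exact enumeration of all 2ⁿ sign assignments is available
for n ≤ 12 as a cross-check mode. When validating the normal
approximation against the exact enumeration, the normal tail is
evaluated with the half-rank continuity adjustment: a continuous tail
systematically overshoots a discrete one near the null, and with the
adjustment the approximation agrees with the exhaustive enumeration
within 0.05 for every reachable statistic at every n ≤ 10 (the
agreement is worst, ~0.049, at n = 4 and tightens as n grows). The
*reported* statistic remains uncorrected by convention; the adjustment
is a property of the discrete-vs-continuous comparison, not of the
test.

Note on signs: the package's Wilcoxon Z is `(T⁺ − μ)/σ` of the b − a
differences, so an overestimating method B yields a positive Z; some
packages report the equivalent negative-rank-sum Z with opposite sign.

**Sample size.** The smallest n ≥ 2 such that a two-sided paired
t-test at level α with noncentrality `(δ/σ)√n` and n − 1 degrees of
freedom reaches the target power, found by doubling/bisection over the
noncentral-t power function (power is monotone in n here). For
δ = 5, σ = 10, power 0.80, α = 0.05 this gives n = 34. Note that for
very large effects the noncentral-t criterion does not collapse to
n = 2: at δ/σ = 10 the power at n = 2 is 0.733 (one degree of freedom
is heavy-tailed), so the minimum is 3; generic solvers that bracket at
n ≥ 2 can mask this.

## Cohort pipeline

Input is a long-format CSV (one row per observer × cycle × phase for
TTE, one row per observer for CMR volumes). The averaging protocol
mirrors clinical practice and the study design: distances averaged
over up to three cardiac cycles, EF per observer from the averaged
distances, modality EF as the two-observer mean. Averaging distances
before the (nonlinear) EF computation is deliberate — it is what an
echo workstation does.

Subjects missing a modality are excluded from that modality's
statistics with a machine-readable reason code; a single-observer
subject contributes that observer's value with a logged warning;
inverted (ESV > EDV) subjects are never dropped. Every statistic in
the report is recomputable from the per-subject derived table alone,
and machine CSV output is written at full float precision (`%.17g`,
reread with round-trip parsing) so a serialized derived table
reproduces the report bit-for-bit. A wide-format reader ingests
per-subject EF-level tables (e.g. a published supplement) directly,
bypassing derivation.

Display rounding (integer EF/TAPSE, one decimal for r and z) applies
only to formatted output, never to machine output.

## Synthetic data

**Phantoms** voxelize an (optionally basal-clipped) ellipsoid into
short-axis slices; truth volumes are the exact analytic segment
integrals, so the only error in a phantom test is the voxelization
itself. Both phases share one grid so stack dimensions match.

**Cohorts.** The simulator draws, per subject: a true (reference) EF
from its group's normal — defaults 38 ± 10 % for 25 patients with
reduced RV function and 56 ± 4 % for 12 healthy volunteers; a CMR EDV
uniform in 100-250 mL (a physiologic window; ESV follows from EF, and
EF rather than volume is the validated quantity); an echo-modality EF
equal to the true EF plus a +6 ppt offset and 7 ppt subject-level
noise; per-modality observer pairs placed symmetrically around the
modality EF at half the drawn observer difference (difference ~
Normal(bias, SD), defaults 6 ± 7 ppt for echo and 2 ± 6 ppt for CMR),
so the two-observer mean is exact; cycle counts drawn from
{1: 0.1, 2: 0.2, 3: 0.7} (three cycles being the routine case); and
TAPSE linear in true EF (slope 0.28 mm/ppt, intercept 6.4 mm, residual
SD 4.2 mm — chosen to pass through ≈17 mm at EF 38 and ≈22 mm at EF 56
with realistic scatter).

Because only EF-level statistics are observable in a validation study,
the TTE distance triplets are **reverse-engineered**: a diastolic
triplet is drawn in physiologic ranges (RVIT₃ 3.5-5.0, RVLAX 6.0-8.5,
LVD 4.0-6.0 cm) and the systolic triplet is the diastolic scaled by
the uniform per-axis factor whose cube gives the target volume ratio.
Per-cycle EF perturbations (SD 2 ppt) are centered within each
observer so replicate scatter does not bias the cycle-averaged value;
per-cycle multiplicative distance jitter (CV 2 %) adds realistic
caliper noise. True EF draws are clipped to (0.5, 99.5) %; at the
default group parameters the clip is essentially never active.

All randomness flows through a single `numpy.random.Generator` seeded
from the config; identical seeds give byte-identical cohorts.

What the simulator does **not** emulate: joint distributions of real
distances (none are observable from EF data), regional deformation
(ARVC-like shapes), imaging physics, proportional (EF-dependent) bias,
or missing data. Passing end-to-end tests therefore demonstrates that
the pipeline recovers the statistical structure it is told to inject —
bias, observer effects, group means — not that the ellipsoid model is
accurate on anatomically abnormal ventricles.

## Problem sizes used in validation

The test suite favours exact and exhaustive checks where possible:
voxel-oracle agreement uses 20 random triplets at 0.2 mm voxels
(counted in closed form per grid column, so the oracle is exact for
its grid); the signed-rank comparison enumerates every reachable
statistic for n = 4…10; the dependent-correlation calibration uses
10,000 simulated studies of n = 37; simulator parameter recovery uses
10,000 subjects per group. These sizes make Monte-Carlo error small
relative to the asserted tolerances while keeping the whole suite in
the seconds range.

## Known limitations

- One ellipsoid axis is an LV measure (LVD); RV dilatation that does
  not widen the LV basal diameter is invisible to the model, so
  abnormal RV morphology degrades accuracy in a structured way the
  simulator does not model.
- The basal-clip convention of real reference segmentations (whether
  partial basal slices are area-weighted or included whole) varies by
  operator; the phantom clip plane makes the question testable but no
  single convention is asserted.
- The replicate-corrected Bland-Altman assumes exchangeable replicates
  within subject per method; systematic observer identity effects are
  captured only through the within-subject variance, not as a crossed
  factor.
- No multiplicity adjustment is applied across the report's many
  tests, matching common practice in method-comparison studies.
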