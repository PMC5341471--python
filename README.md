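# rvellipse

Right-ventricular (RV) ejection fraction from three routine 2D
echocardiographic distances, plus everything needed to validate such an
estimate against a volumetric reference: disk-summation volumetry over
short-axis segmentation stacks, the full method-agreement statistics
battery, a cohort analysis pipeline, and synthetic phantom/cohort
generators.

## Who this is for

Assessing RV systolic function by 2D transthoracic echocardiography
(TTE) is hard: the RV sits behind the sternum, its free wall is often
incompletely visualized, and the standard one-dimensional surrogate
(TAPSE, the tricuspid annular excursion) ignores everything but
longitudinal motion. Cardiac MR (CMR) gives reference ejection
fractions but is not always available. `rvellipse` implements a simple
volume-based alternative — modelling the RV as an ellipsoid spanned by
three distances that are easy to measure even with a poorly seen free
wall — together with the statistical machinery a method-comparison
study needs, so the model can be evaluated end-to-end at desk scale.

## The model

With the RV inflow tract distance RVIT₃ and the RV long axis RVLAX
(apical four-chamber view) and the LV maximum outer basal diameter LVD
(apical two-chamber view), all in cm, the RV volume in mL is the
ellipsoid volume

```
RVV = (π/6) · RVIT₃ · RVLAX · LVD
```

Evaluating at end-diastole and end-systole gives EDV and ESV, and

```
RVEF (%) = 100 · (EDV − ESV) / EDV.
```

Absolute volumes from TTE distances are biased low, but the bias
largely cancels in the EF quota — EF is the quantity this model is
meant for.

Around the model the package provides:

- **Reference volumetry** (`rvellipse.volumetry`): disk summation
  `Σ areaᵢ · slice_spacing` over binary short-axis mask stacks (NIfTI
  or PNG directory + JSON sidecar), the way CMR reference EFs are
  produced from endocardial delineations.
- **Agreement statistics** (`rvellipse.agreement`): Pearson r with the
  conventional strength bands, Bland-Altman limits of agreement with
  the replicate-mean SD correction, Steiger's z-test for two dependent
  overlapping correlations, a Shapiro-Wilk-routed paired t /
  Wilcoxon signed-rank test (with an exact-enumeration cross-check
  mode), and paired-design sample-size calculation via the
  noncentral-t power function.
- **Cohort pipeline** (`rvellipse.cohort`): long-format CSV in, cycle
  averaging (up to three cardiac cycles), per-observer EFs, two-observer
  means per modality, the full agreement report including the
  patient-only subgroup and inter-observer (intra-modality) blocks.
- **Synthetic data** (`rvellipse.synthetic`): voxelized ellipsoid
  phantoms with closed-form truth volumes, and a seeded two-group
  cohort simulator (patients with reduced RV function, healthy
  volunteers) with observer- and cycle-level noise.

## Worked example

```
$ rvellipse volume --rvit3 4.0 --rvlax 7.5 --lvd 5.0
RV volume: 78.54 mL

$ rvellipse ef --dia 4.2,7.8,5.1 --sys 3.4,6.5,4.4
EF: 41.8% (EDV 87.48 mL, ESV 50.91 mL)

$ rvellipse power --delta 5 --sd 10 --power 0.8 --alpha 0.05
Minimum subjects: 34
```

The first command is the ellipsoid volume of a diastolic triplet; the
second composes both phases into an EF; the third is the study-design
question "how many subjects to detect a 5-percentage-point mean EF
difference between two methods, assuming the paired differences have
SD 10, at 80% power and two-sided α = 0.05" — answer 34.

A full simulated study, from cohort generation to the agreement report:

```
$ rvellipse simulate --seed 42 --out cohort.csv
cohort with 37 subjects written to cohort.csv
$ rvellipse analyze --input cohort.csv --out report.json
```

With seed 42 the report contains (among much else): overall
RVEF_TTE 50.2 ± 14.1 %, RVEF_CMR 44.0 ± 11.6 %, a high TTE-CMR
correlation r = 0.89, Bland-Altman bias +6.2 ppt with limits of
agreement −10.3 to 22.8 ppt (replicate-corrected, TTE − CMR), and a
TTE inter-observer difference of 5.9 ± 6.7 ppt — i.e. the analysis
recovers the +6 ppt echo offset and the observer-noise structure that
the simulator injected.

`rvellipse phantom` / `rvellipse refvol` / `rvellipse refef` exercise
the reference-volumetry path on voxel phantoms with known truth.

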