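# Methods

## The measurement and the model

In large-vessel-occlusion stroke, *thrombus perviousness* quantifies how much
contrast agent penetrates the occluding clot. The standard measure is the
thrombus attenuation increase, TAI = ρ_CTA − ρ_NCCT, where ρ is the mean clot
density in Hounsfield units measured with small spherical ROIs on the
non-contrast scan and the arterial-phase angiogram. With a third, late
venous-phase acquisition (CTV), the density *trajectory* across the three
timepoints can be classified into four dynamic patterns, using a 5 HU change
threshold:

| pattern | N→A change | additional condition |
|---|---|---|
| no uptake | ≤ 5 HU | N→V change ≤ 5 HU |
| late uptake | ≤ 5 HU | N→V change > 5 HU |
| early uptake with washout | > 5 HU | A→V drop ≥ 5 HU |
| early uptake without washout | > 5 HU | A→V drop < 5 HU |

The first two collapse to *non-pervious* and the last two to *pervious*
under the binary standard definition.

### Gap-closure conventions

The verbal rules above do not cover every real triple, so `classify_dynamic`
adopts the following conventions, making the rule a total, exclusive
partition (property-tested over dense grids and 10⁶ random triples):

- Changes are **signed increases**. A density decrease of any magnitude is
  never uptake; triples that fall (or fall then rise by ≤ 5 HU) are
  `no_uptake`, and a triple whose venous phase alone rises by > 5 HU is
  `late_uptake`.
- Boundaries are inclusive as worded: a change of exactly 5 HU is *not*
  uptake; a drop of exactly 5 HU *is* washout.
- Early uptake followed by a further rise of any size is
  `uptake_without_washout`: categories 3 and 4 partition all early-uptake
  triples purely by the presence of a ≥ 5 HU drop.
- The threshold is configurable (`--threshold-hu`), default 5 HU.

### ROI protocol

Three spherical ROIs of 1 mm diameter are placed along the clot. Per phase,
each ROI's mean HU is computed first and the **unweighted mean of the three
ROI means** is the phase density — an ROI that happens to cover more voxels
does not get more weight. (Whether the original protocol weighted by voxel
count is not decidable from its description; the two-step wording supports
the unweighted reading, which we adopt and record in the run report.)

A voxel belongs to an ROI iff its **center** lies within the sphere radius
(inclusive) in world coordinates; partial volumes are not weighted. This is
the simplest reproducible rule at the 1 mm-ROI / sub-millimetre-voxel scale.
If a sphere captures no voxel center at all, the nearest voxel is used and a
warning is logged rather than failing: 1 mm ROIs on 0.8 mm slices operate at
grid resolution by design. Co-registration of the three phases is a
*precondition*; the package verifies grid identity and refuses mismatched
affines but performs no registration.

### Clot typing

Histologic composition arrives as a closed three-part percentage vector
(fibrin/platelets, RBC, WBC). The dominance rule uses an **absolute
percentage-point margin** (default 15): RBC-rich iff rbc − fibrin > 15,
fibrin/platelet-rich iff fibrin − rbc > 15, otherwise mixed, with the
boundary (difference exactly 15) resolving to mixed. A relative-ratio
variant (`relative=True`, dominance = exceeding the other component by a
factor 1.15) exists for sensitivity analysis only. Compositions whose sum
deviates from 100 by more than a tolerance (default 1 point) are rejected;
smaller deviations are renormalised.

## Statistics

- **Normality screen**: Kolmogorov–Smirnov against a normal with
  sample-estimated mean/SD. Because the parameters are estimated, the
  Lilliefors-corrected critical values are used (the uncorrected KS test is
  anti-conservative here); the correction is noted in each result.
- **Kruskal–Wallis** (composition percentage across uptake categories):
  tie-corrected H with the chi-squared approximation; no exact small-sample
  tables.
- **Chi-squared** (clot type × category, clot type × mTICI): Pearson
  statistic without Yates correction by default (a flag enables it);
  expected counts below 5 raise a warning note rather than switching to an
  exact test. Empty rows/columns are dropped with a note.
- **Benjamini–Hochberg** step-up adjustment, one family per analysis block:
  the pairwise category comparisons form one family, the composition
  Kruskal–Wallis tests another, the clot-type associations a third. The
  family decomposition is a documented choice (the source protocol does not
  define it) and is recorded in the output metadata.
- **Pairwise category comparisons**: for each unordered pair of uptake
  categories, a 2×2 chi-squared of (fibrin/platelet-rich vs. RBC-rich +
  mixed) × category, BH-adjusted as one family. Degenerate tables (a zero
  margin) score statistic 0, p = 1 — absence of evidence, not an error.
- **Pearson correlations** between component pairs within each category,
  labelled very strong (|r| ≥ 0.90), strong (0.70–0.89), moderate
  (0.40–0.69), weak (0.20–0.39), negligible (< 0.20).
- **Summary table**: counts and percentages (100·count/n, default 1 decimal,
  configurable because published tables mix integer and one-decimal
  precision) plus mean ± SD for age and NIHSS.

## The synthetic cohort generator

No public dataset couples three-phase clot densities with histology, so the
generator defines the conditions under which the pipeline is exercised:

- **Category mix** (0.20, 0.15, 0.35, 0.30) over the four patterns — a
  plausibility choice; no per-category counts are published.
- **Densities**: baseline NCCT clot density N(50, 8²) HU; uptake magnitudes
  exponential above the threshold with mean 20 HU; washout drops mean 12 HU;
  triples are constructed *noiseless* so each satisfies its category's
  inequalities with a margin of at least 2× the configured measurement noise
  (default noise 1.5 HU → margin 3 HU). Classifying a record's own densities
  therefore always recovers its true category; noise enters only when
  phantoms are rendered.
- **Phantoms**: soft-tissue background (35 HU), a straight vessel along x
  with phase-dependent lumen density, an 8 mm clot segment carrying the
  record's densities, i.i.d. Gaussian voxel noise, and three 1 mm ROIs 2 mm
  apart on the clot axis. ROI means average the voxel noise down by roughly
  √20 per ROI set, which is why category recovery at default noise is
  essentially perfect; the margin construction, not tuning, guarantees it.
- **Composition**: 3-part Dirichlet with base concentration
  12 × (0.40, 0.50, 0.10) (fibrin, RBC, WBC — WBC deliberately minor). The
  `fibrin_effect` knob adds to the fibrin concentration for the no-uptake
  and uptake-with-washout categories, implanting the direction that those
  clots are more often fibrin-rich than uptake-without-washout clots;
  0 means full independence.
- **Clinical labels**: occlusion site and TOAST etiology are drawn from the
  empirical frequencies of a published 39-patient thrombectomy cohort;
  mTICI is independent of category by default (success probability 30/39),
  with a coupling knob for power studies; age N(71, 17²), NIHSS N(14, 4²),
  female 19/39, r-tPA 29/39.

What the phantoms do **not** emulate: contrast-bolus pharmacokinetics,
collateral flow, scanner physics (beam hardening, reconstruction kernels),
curved vessels, partial-volume texture, registration error. Passing the
recovery tests therefore shows the measurement-and-classification chain is
self-consistent at realistic noise, not that it is robust to real scanner
artefacts.

## Calibration experiments and problem sizes

`clotperv.experiments` runs three checks, also reported by
`scripts/acceptance.py`:

- **Phantom recovery**: 50 patients at zero noise (expected 100%) and 100
  patients at default noise (expected ≥ 95%), on 40³ voxel grids at 0.5 mm.
- **Power**: 100 replicate cohorts of n = 400 with a large implanted
  composition effect (fibrin_effect = 6); fraction of replicates in which
  the with-washout vs. without-washout fibrin-rich comparison rejects at
  BH-adjusted 0.05.
- **Null calibration**: the same design with fibrin_effect = 0; family-wise
  rejection rate of the pairwise family, expected at or below the nominal
  0.05 within Monte-Carlo error (the discrete chi-squared makes the
  procedure slightly conservative).

These sizes keep each experiment in the seconds-to-a-minute range while
leaving the Monte-Carlo standard errors (≈ 2 percentage points at 100
replicates) small relative to the margins being checked.

## Numerical choices and limitations

- Sphere membership uses a 1 nm (1e-9 mm) slack so voxels exactly on the
  boundary are included deterministically despite affine round-trips.
- Phantom volumes are written as float32 NIfTI-1; round-tripping through
  disk perturbs densities by ~10⁻⁵ relative, far below the 3 HU margin.
- The TAI additivity identity (N→V = N→A + A→V) is made exact in floating
  point by computing the third difference as the sum of the first two.
- All randomness flows from one root seed through named `SeedSequence`
  substreams (cohort draws; per-patient phantom noise), so partial pipeline
  reruns are stable and a full rerun is byte-identical.
- The published headline p-values and correlations of the motivating
  39-patient study depend on unavailable patient data and are not
  reproduced; the package reproduces the *procedures* and verifies them on
  synthetic data and in-print worked examples instead.
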