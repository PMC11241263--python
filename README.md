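# clotperv

Dynamic perviousness analysis of occlusive stroke clots from three-phase CT.

In acute large-vessel-occlusion stroke, the density of the occluding thrombus
on CT changes as contrast agent penetrates it. The standard imaging biomarker,
*thrombus attenuation increase* (TAI = ρ_CTA − ρ_NCCT, the mean clot density
difference between non-contrast CT and arterial-phase CTA measured with small
spherical ROIs), uses only two timepoints. Adding a late venous acquisition
(CTV) lets the whole uptake *trajectory* be classified into four dynamic
patterns — no uptake, late uptake, early uptake with washout, early uptake
without washout (the first two collapsing to *non-pervious*, the last two to
*pervious*) — which carry information about clot histology: washout patterns
differ in their likelihood of fibrin/platelet-rich clots, which matters for
choosing a thrombectomy technique.

`clotperv` implements this analysis as a reusable, tested pipeline for
neuroimaging researchers:

- **ROI densitometry** (`clotperv.roi`): NIfTI-1 phase volumes, spherical
  ROI sampling in world coordinates (voxel-center membership, inclusive
  radius), and per-phase densities as the unweighted mean of three 1 mm ROI
  means.
- **Classification** (`clotperv.perviousness`): TAI computation and the
  four-pattern rule with a 5 HU threshold, made total over arbitrary density
  triples by documented conventions (signed changes; decreases are never
  uptake; a drop of exactly 5 HU is washout).
- **Histology** (`clotperv.histology`): clot typing from (fibrin/platelet,
  RBC, WBC) percentages by the 15-percentage-point dominance rule
  (RBC-rich / fibrin-platelet-rich / mixed).
- **Statistics** (`clotperv.stats`): Lilliefors-corrected KS normality
  screen, tie-corrected Kruskal–Wallis, Pearson chi-squared, pairwise
  fibrin-rich comparisons across uptake categories with Benjamini–Hochberg
  FDR control, per-category Pearson correlations with verbal strength
  bands, and the population-characteristics summary table.
- **Synthetic cohorts and phantoms** (`clotperv.synthetic`,
  `clotperv.experiments`): since no public dataset couples three-phase clot
  densities with histology, a generator produces cohorts with known
  category labels, margin-constructed density triples, Dirichlet
  compositions with a controllable fibrin–category coupling, and rendered
  vessel-plus-clot phantom volumes, enabling recovery, power and
  null-calibration experiments.
- **Pipeline and CLI** (`clotperv.pipeline`, `clotperv` command):
  simulate → extract → classify → clot-type → analyze with persisted CSV
  intermediates, a JSON run report listing every convention in force, and
  full seed-driven reproducibility.

See `docs/methods.md` for the conventions, generator design, and limitations.

## Worked example

```python
from clotperv import classify_dynamic, compute_tai, validate_composition, classify_clot_type
from clotperv.roi import PhaseDensities

d = PhaseDensities(rho_ncct=48.2, rho_cta=61.0, rho_ctv=52.9)
tai = compute_tai(d)
cat = classify_dynamic(d)
print(f"TAI  N->A {tai.tai_cta_ncct:+.1f} HU   A->V {tai.tai_ctv_cta:+.1f} HU   N->V {tai.tai_ctv_ncct:+.1f} HU")
print(f"pattern: {cat.label}   standard: {cat.standard}")
comp = validate_composition(86, 10, 4)
print("clot type:", classify_clot_type(comp).label)
```

prints

```
TAI  N->A +12.8 HU   A->V -8.1 HU   N->V +4.7 HU
pattern: uptake_with_washout   standard: pervious
clot type: fibrin_platelet_rich
```

The clot gained 12.8 HU from the unenhanced to the arterial phase (> 5 HU:
early uptake) and then lost 8.1 HU by the venous phase (≥ 5 HU: washout), so
it is classified *early uptake with washout* — a pervious clot. A clot with
86% fibrin content exceeds the RBC fraction by more than 15 points and is
fibrin/platelet-rich.

A full synthetic run from the shell:

```
clotperv run-all --out-dir demo --seed 1 --skip-imaging
```

writes `cohort.csv`, `densities.csv`, `classified.csv`, `clot_types.csv` and
an `analysis/` bundle (summary tables, `tests.csv` with statistic / p /
BH-adjusted p per family, per-category correlations, metadata) plus
`run_report.json`. Drop `--skip-imaging` to also render per-patient phantom
NIfTI volumes and extract densities from them via the ROI protocol.

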