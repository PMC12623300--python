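# panometry

Rule-based classification of esophageal motility from **FLIP panometry**
(functional lumen imaging probe), with adjudication against high-resolution
manometry (HRM, Chicago Classification v4.0) and timed barium esophagram
(TBE), and a diagnostic-concordance analysis calibrated to a published
two-center cohort of 805 patients.

FLIP panometry measures luminal diameters on a 16-cm, 16-sensor balloon
catheter during stepwise volumetric distension (40 → 70 mL in 10-mL steps,
each held 30–60 s) at sedated endoscopy. Two derived axes drive diagnosis:

* **EGJ opening** — from the esophagogastric-junction distensibility index
  at 60 mL, EGJ-DI = CSA<sub>min</sub>/P (mm²/mmHg, circular-lumen CSA), and
  the maximum EGJ diameter over 60–70 mL. Normal if EGJ-DI ≥ 2.0 and
  D<sub>max</sub> ≥ 16 mm; reduced if EGJ-DI < 2.0 and D<sub>max</sub> <
  12 mm; otherwise inconclusive.
* **Contractile response (CR)** — the pattern of distension-induced
  (secondary) peristalsis in the diameter topography: *normal* (> 1 distinct
  antegrade contraction of ≥ 6 cm axial length with a pressure rise
  > 10 mmHg), *spastic* (sustained occluding or sustained LES contraction),
  *absent* (no contractility), or contractility failing normal criteria,
  split at a 60-mL pressure of 40 mmHg into *diminished* (≤ 40) and
  *disordered* (> 40). The v1.0 scheme merges diminished/disordered into a
  single impaired/disordered category.

A total decision table maps (CR × EGJ opening) to a motility class (normal,
hypocontractility, non-spastic obstruction, spastic obstruction, possible
spasm, possible obstruction, obstruction with normal CR). HRM labels enter
as CCv4.0 codes; EGJOO is inconclusive at the HRM level and is resolved by
TBE (abnormal → conclusive EGJOO; normal → normal outflow; missing or
inconclusive → excluded from the primary analysis). The package is aimed at
researchers studying esophageal motility diagnostics who need a tested,
fully explicit implementation of these rule systems plus synthetic data to
exercise them.

## What's inside

| module | contents |
| --- | --- |
| `panometry.topo` | synthetic FLIP studies with known CR/EGJ-opening phenotypes |
| `panometry.features` | EGJ-DI, max EGJ diameter, contraction-event detection |
| `panometry.classify` | v1.0/v2.0 rule systems and auditable decision tables |
| `panometry.adjudicate` | IRP cut-offs, TBE rules, conclusive/inconclusive outflow |
| `panometry.cohort` | packaged 805-patient cross-tabulation + calibrated sampling |
| `panometry.concordance` | contingency tables, PPV/NPV, version reclassification |
| `panometry.pipeline`, `panometry.cli` | config, cohort CSV IO, `panometry` CLI |

## Worked example

Simulate a study with diminished contractility and reduced EGJ opening, then
extract metrics and classify:

```python
from panometry import (TopographySpec, simulate_topography,
                       extract_metrics, classify_study_metrics)

spec = TopographySpec.from_phenotypes("diminished", "reduced", seed=7)
study, truth = simulate_topography(spec)
m = extract_metrics(study)
cr, egjo, motility = classify_study_metrics(m)
print(f"EGJ-DI (60 mL):       {m.egj_di_60:.2f} mm^2/mmHg")
print(f"max EGJ diameter:     {m.max_egj_diameter:.1f} mm")
print(f"60-mL pressure:       {m.pressure_60:.1f} mmHg")
print(f"qualifying antegrade: {m.n_qualifying_antegrade}")
print(f"CR pattern:           {cr.value}")
print(f"EGJ opening:          {egjo.value}")
print(f"motility class:       {motility.value}")
```

prints

```
EGJ-DI (60 mL):       1.00 mm^2/mmHg
max EGJ diameter:     9.0 mm
60-mL pressure:       30.0 mmHg
qualifying antegrade: 0
CR pattern:           diminished
EGJ opening:          reduced
motility class:       non_spastic_obstruction
```

EGJ-DI 1.00 mm²/mmHg with a 9-mm maximum diameter is a reduced EGJ opening;
contractility is present but no antegrade contraction qualifies and the
60-mL pressure is ≤ 40 mmHg, so the CR is diminished — together,
*non-spastic obstruction*, the FLIP class most strongly associated with
type I/II achalasia.

The same flow is available from the shell:

```bash
panometry simulate --cr diminished --egjo reduced --seed 7 --out studies/
panometry extract --study studies/study_000 --out metrics.json
panometry classify --scheme v2 --metrics metrics.json
panometry concord --out report.json     # cohort concordance report
```

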