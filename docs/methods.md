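# Methods

## Scope and data model

The package implements the FLIP panometry motility classification schemes
(v1.0 and v2.0) as explicit rule systems, the HRM/TBE adjudication of EGJ
outflow, and the concordance analysis between the two modalities. No
patient-level FLIP recordings are publicly deposited for this kind of study,
so the package carries two synthetic generators as first-class, tested code:
a topography simulator (`topo`) producing diameter grids with known
ground-truth phenotypes, and a cohort sampler (`cohort`) calibrated to the
published 805-patient cross-tabulation, which is packaged verbatim as
structured text (`panometry/data/table2_counts.csv`).

A `FlipStudy` is a uniformly sampled time series (default 10 Hz) of a
16-channel diameter grid (1-cm spacing, channel 0 proximal), a bag-pressure
trace and a fill-volume step function over {40, 50, 60, 70} mL, each step
held for a configurable dwell (default 40 s, constrained to the protocol's
30–60 s). Channels 12–14 straddle the EGJ by default (configurable);
channel 15 models the sensor beyond the EGJ.

## Topography simulator

Contractions are modelled as Gaussian-in-space, travelling-in-time
multiplicative diameter reductions on a per-fill-step baseline: a narrow
band (spatial sigma 0.44 channels, depth 95% of baseline) whose centre
moves at the requested signed speed (default +4 cm/s, antegrade) across the
requested axial extent. The narrow instantaneous width makes the detected
channel span equal the traversed span, so the injected extent is recovered
to the detector's channel resolution. Spastic studies instead inject a
stationary band (sigma 1.2 channels) lasting `occlusion_duration` (default
12 s) either in the esophageal body (occluding, minimum diameter ~1 mm) or
at the EGJ (sustained LES contraction mode). Each contraction carries a
synchronous half-sine bag-pressure rise (default 15 mmHg).

The EGJ trace is constructed backwards from the requested metrics: the
60-mL step's narrowest EGJ diameter is the one whose circular CSA divided by
the 60-mL pressure equals the requested EGJ-DI; the 70-mL step carries the
requested maximum diameter. Phenotype defaults: EGJ opening normal
(DI 4.0, 18 mm), inconclusive (1.5, 14 mm), reduced (1.0, 9 mm); CR normal
(3 antegrade bands of 8 cm), diminished/disordered (2 bands of 4 cm — too
short to qualify — at 30 vs 55 mmHg), absent (none), spastic (one sustained
band). Contradictory requests (e.g. absent CR with contractions, a DI whose
implied 60-mL diameter exceeds the requested maximum) are rejected at spec
construction.

The five CR phenotypes and "sustained"/"occluding" are defined by criteria
human raters apply, not by a published algorithm; the quantitative defaults
here (sustained ≥ 10 s, occluding ≤ 2 mm, distinctness ≥ 2 s or ≥ 2
non-contracting channels, normal-CR thresholds ≥ 6 cm and > 10 mmHg) are
declared configuration, with the 6-cm/10-mmHg/40-mmHg values anchored to the
published v2.0 criteria and the rest chosen as physiologically sensible
operationalisations.

Randomness: the geometry is fully deterministic given the spec; diameter
noise (additive Gaussian, clipped at 0.5 mm so diameters stay positive) is
the only stochastic element and derives from the spec's seed through a
dedicated `SeedSequence` stream, so identical specs are bit-identical.

## Feature extraction

* **EGJ metrics.** EGJ-DI at 60 mL = median(narrowest-EGJ-channel CSA) /
  median(bag pressure) over an analysis window defaulting to the final 10 s
  of the 60-mL step (the step's end is when the distension response has
  equilibrated; the window is configurable since the published protocol does
  not fix it). Maximum EGJ diameter is taken over the whole 60- and 70-mL
  steps. Medians, not means, are used throughout for robustness to
  contraction transients. Studies missing the 60- or 70-mL step raise a
  protocol-incomplete error, mirroring the exclusion of technically limited
  studies.
* **Event detection.** The contraction mask is `diameter <
  min(0.5 × baseline, 9 mm)` — a relative drop with an absolute floor,
  whichever is stricter — where the baseline is the per-channel,
  per-fill-step median diameter (contractions are transient within a step,
  so the step median is a robust baseline; a rolling baseline would behave
  identically on these data and the threshold rule is configurable). Events
  are 8-connected components of the mask, restricted to fill volumes
  ≥ 50 mL (the analysis period), then merged when separated by less than
  both 2 s and 2 channels (the "distinct contraction" rule). Direction is
  the sign of the slope of the per-time centroid channel regressed on time
  (|slope| < 0.25 cm/s → mixed); pressure rise is the peak bag pressure
  during the event minus the median over the 5 s before onset. The
  labelling step is cross-checked in the tests against a brute-force BFS
  connected-component oracle.
* **Metrics.** `n_qualifying_antegrade` counts antegrade events with extent
  ≥ 6 cm and pressure rise > 10 mmHg; `sustained_occluding` requires a
  sustained (≥ 10 s) occluding (≤ 2 mm) event off the EGJ;
  `sustained_les` a sustained event overlapping the EGJ channels. The RAC
  (repetitive antegrade contraction) flag is descriptive only and never
  alters classification.

## Classification rules and decision tables

CR v2.0 applies a fixed precedence — spastic, then normal, then
diminished/disordered (split at 60-mL pressure ≤ 40 vs > 40 mmHg), then
absent — so spastic features dominate every other criterion. Boundary
behaviour is pinned in tests: pressure exactly 40 mmHg is diminished;
exactly 2 qualifying antegrade contractions is normal ("> 1"). CR v1.0 is
derived by the nomenclature merge (diminished/disordered → impaired/
disordered, spastic → spastic-reactive), which makes the v1.0/v2.0
coherence property true by construction and testable against independent
random metric draws.

EGJ-opening cut-offs (2.0 mm²/mmHg; 16/12 mm) come from the consensus
literature rather than the validation study itself and ship as explicit
`consensus-default` configuration.

The motility mapping is a total, serialisable `DecisionTable` (one cell per
line: version, CR, EGJ opening, class, provenance). The shipped v2.0 table
has 15 cells; cells printed in the source (reduced × absent/diminished →
non-spastic obstruction, reduced × disordered/spastic → spastic
obstruction, reduced × normal → obstruction with normal CR, normal × normal
→ normal, normal × diminished/absent → hypocontractility, normal ×
disordered/spastic → possible spasm) are marked `paper-anchored`; the
inconclusive-EGJ-opening column is not printed numerically in the source
and is marked `consensus-default`, with inconclusive × spastic assigned to
possible spasm (an open choice; overridable per cell). The v1.0 table is a
documented reconstruction — all 12 cells `consensus-default` — in which
spastic-reactive CR dominates at every EGJ-opening class and borderline
(inconclusive) opening with non-spastic CR maps to a borderline/other
class. A validator checks totality, single-valuedness and provenance
labelling of any table, shipped or user-supplied.

## Adjudication

IRP: median > 15 mmHg supine or > 12 mmHg upright is abnormal (strict
inequalities). TBE: abnormal if the 5-min column exceeds 5 cm, or the 1-min
column exceeds 5 cm with tablet impaction; inconclusive if the 1-min column
exceeds 5 cm but clears by 5 min with the tablet not administered or passed,
or the 1-min column is ≤ 5 cm with tablet impaction; otherwise normal. The
"no tablet administration or tablet passage" clause is grammatically
ambiguous in the source; the default parse treats either state as
qualifying, and the alternative (not-administered only) is selectable. The
2-min image is carried in the data model but consumed by no rule, matching
the printed criteria. Achalasia of any subtype is a conclusive outflow
disorder regardless of TBE; EGJOO resolves via TBE; a missing or
inconclusive TBE leaves the diagnosis inconclusive and excluded from the
primary analysis. The label set includes an `inconclusive_other` code for
HRM studies inconclusive for non-EGJOO reasons (the cohort table carries
three such patients); it always adjudicates to inconclusive.

## Cohort generator and concordance

`calibrate_joint_from_counts` normalises any non-negative count table into
a joint distribution over (HRM category × FLIP class); the packaged table
gives the study's joint. `sample_cohort` draws i.i.d. patients and attaches
metrics guaranteed to re-classify to the drawn FLIP class: a (CR, EGJ
opening) pair is drawn uniformly from the class's preimage under the v2.0
table, then metrics are drawn uniformly within that pair's region of metric
space (the source gives thresholds, not distributions, so uniform-in-region
is the minimal assumption). Inconclusive-EGJOO patients receive an EGJOO
label with a missing TBE — the dominant pattern behind the study's excluded
group — and conclusive-EGJOO patients an abnormal TBE. Demographics
(age ~ N(55, 17) clipped to 18–91, 62% female) are decoration and never
feed classification.

The concordance module partitions adjudicated cohorts into conclusive and
excluded subsets (counts always conserved), cross-tabulates in canonical
label order, and computes within-class proportions and predictive values
for the fixed positive condition *disorder of EGJ outflow* = achalasia (any
subtype) or conclusive EGJOO. Percentages are integers rounded half away
from zero (92.7 → 93, 98.5 → 99), matching the printed convention; raw
numerator/denominator pairs are always retained. Group comparisons use the
uncorrected χ² test for categorical data and t/ANOVA or
Mann-Whitney/Kruskal-Wallis for continuous data, two-tailed, with no
multiple-testing correction (matching the source analysis); the χ² p-value
is property-tested against a label-permutation Monte-Carlo null. The
v1.0 × v2.0 reclassification flow table conserves cohort size and is
checked against the reachability relation implied by the two shipped
tables.

Known inconsistency: the packaged table's conclusive column sums give 75
spastic-obstruction and 200 possible-obstruction patients, while the source
prose reports 76 and 199. The fixture stores the table verbatim; all
headline denominators used here (137, 163, 78, 51, 200, 37) follow from the
table.

## What the synthetic data does and does not show

The simulator produces idealised topographies: piecewise-constant
baselines, clean Gaussian bands, and stationary catheter position. Passing
the round-trip tests demonstrates that the detector and rule layers are
mutually consistent and robust to moderate diameter noise (0.5 mm SD); it
does not validate the detector against real device recordings, where
baseline drift, breathing artefact, catheter movement and non-Gaussian
contraction morphology occur. Likewise the cohort sampler reproduces the
published joint distribution by construction; it cannot test whether the
classification rules would reproduce that joint from raw recordings.

## Problem sizes and numerical choices

Default study size is 1,600 samples × 16 channels (four 40-s steps at
10 Hz). The test suite uses 20 seeds per phenotype pair for round-trip
recovery (600 simulations), 50,000 patients for cohort calibration
(all cells with probability ≥ 0.005 within 3 binomial SE, fixed seed), and
10,000 random metric draws for the scheme-coherence property; the whole
suite runs in well under a minute. Diameter noise is clipped at 0.5 mm to
keep diameters positive; event direction falls back to "mixed" for regions
too short to regress (< 3 distinct time samples). Floating-point ties at
rule boundaries follow the printed inequalities exactly (≤ 40 diminished,
> 15 abnormal supine IRP, ≥ 2.0/≥ 16 normal opening).
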