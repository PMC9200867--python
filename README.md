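# vcgdi — vectorcardiographic quantification of ventricular electrical dyssynchrony

`vcgdi` turns a routine digital 12-lead ECG into a single number — a
**dyssynchrony index** — that quantifies how far a patient's ventricular
electrical activation departs from healthy conduction.  It is aimed at
cardiac-electrophysiology researchers studying candidate selection and
device optimization for cardiac resynchronization therapy (CRT), where the
established criteria (QRS width and morphology) leave a large fraction of
non-responders.

## The method

1. **VCG reconstruction.**  The 12-lead ECG is band-pass filtered
   (zero-phase Butterworth), detrended (10th-order polynomial), and mapped
   to the orthogonal leads X(t), Y(t), Z(t) with the Kors regression
   matrix.  Two scalar series summarize the dipole's motion:

   - *voltage*(t) = √(X² + Y² + Z²) — spatial magnitude, mV;
   - *speed*(t) = |d(X,Y,Z)/dt| — magnitude of the dipole velocity, mV/s.

2. **Signal-averaged beat.**  Depolarization peaks are detected on the
   voltage series; a 220-ms window around each peak is endpoint-zeroed,
   peak-aligned and ensemble-averaged.  Recordings whose beats correlate
   below r = 0.9 (minimum pairwise Pearson) are excluded — this removes
   low-SNR traces and extrasystoles.

3. **Adaptive depolarization limits.**  A voltage threshold is swept in
   0.001-mV steps; the duration of the supra-threshold run containing the
   peak defines a length-vs-threshold curve, fitted with a 7th-order
   polynomial.  The patient-specific threshold is where the normalized
   derivative of that curve first recovers to −0.275 after its initial
   steep descent, and the depolarization onset/offset follow from it.

4. **The index.**  Over the detected segment,

   - VTI = ∫ voltage dt  (mV·ms — the "QRS area" of the VCG literature),
   - STI = ∫ speed dt  (mV — 10³ × the loop's 3-D path length).

   In healthy conduction STI is proportional to VTI.  After
   nondimensionalizing (VTI/100 mV·ms, STI/10,000 mV) an OLS line
   `sti_n = k + m·vti_n` is fitted to a control population, and

   **index = |k + m·vti_n − sti_n| / √(1 + m²)** ,

   the normalized perpendicular distance to the control line.  A
   Youden-optimal cutoff on the index separates electrically
   dyssynchronous patterns (left bundle branch block, ventricular pacing)
   from the rest, and an 18-segment time-to-peak-strain standard deviation
   (TPS-SD) is provided for echocardiographic cross-validation.

The package also contains a synthetic 12-lead ECG generator (rotating
dipole loop, Dower lead projection, realistic noise/drift/powerline and
extrasystoles) with closed-form ground truth, so the whole chain is
testable without any recordings.

## Worked example

```python
from vcgdi import ControlLine, YoudenCutoff, analyze_records, generate_cohort

records, truth = generate_cohort({"control": 30, "lbbb": 6}, seed=7)
table, excluded = analyze_records(records)

controls = table[table.label == "control"]
line = ControlLine(controls.vti, controls.sti).fit()
print(line.summary())

scored = line.score(table)
print(scored.groupby("label")["index"].median().round(3))
print(YoudenCutoff(scored["index"], (scored.label == "LBBB").astype(int))
      .fit().summary())
```

prints

```
Control line (normalized STI on normalized VTI, OLS)
----------------------------------------------------
n controls                  28
intercept k_norm       -0.0255  (se 0.0254)
slope m_norm            0.7394  (se 0.0480)
slope raw [1/ms]         73.94
r^2                     0.9012
norms: VTI/100 mV·ms, STI/10000 mV
label
LBBB       0.447
control    0.015
Youden-optimal dyssynchrony-index cutoff
----------------------------------------
n (dyssynchronous / other)  5 / 28
cutoff range                [0.0636, 0.3029]
cutoff (mean of range)      0.1833
max Youden index            1.0000
sens/spec at mean cutoff    1.000 / 1.000
```

The raw slope (≈ 74 ms⁻¹ here) is the inverse "tissue characteristic
time" of healthy conduction; healthy records sit on the line
(median index 0.015) while left-bundle-branch-block records sit far below
it (median 0.447, wide-slow loops: large VTI without the matching STI),
and the Youden cutoff separates the groups perfectly on this cohort.

A command-line interface mirrors the library
(`vcgdi simulate / analyze / fit-controls / index / cutoff / tps-sd`);
WFDB (header + format-16) and CSV records are read natively.

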