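# Methods

This note documents the models, numerical choices and known limitations of
`vcgdi`, in the spirit of a statistical package's methods appendix.  All
internal units are millivolts and milliseconds; speed is expressed in mV/s
and time integrals are taken over a millisecond time axis, so the speed
time integral (STI) is numerically 10³ × the loop path length — the scale
on which its nondimensionalization constant (10,000 mV) and the printed
STI/VTI slope (≈ 70 ms⁻¹ in healthy conduction) live.

## Signal chain

**Preprocessing.**  Zero-phase Butterworth band-pass (default order 4,
0.5–150 Hz, forward–backward via `sosfiltfilt` with generous padding) and
per-lead subtraction of a 10th-order least-squares polynomial fitted on a
time axis rescaled to [−1, 1].  Both steps are linear and
length-preserving.  Division of labour: the 0.5-Hz high-pass edge removes
oscillatory baseline wander (a degree-10 polynomial can only track
sub-0.2-Hz drift across a 10-s trace — roughly n/π half-cycles for degree
n), while the polynomial removes residual slow trends and any DC left by
edge effects.  Order of application: filter, then detrend.

**VCG reconstruction.**  The Kors regression matrix (hard-coded, every
coefficient pinned by a unit test) maps the 8 independent leads
(I, II, V1–V6) to X/Y/Z; augmented limb leads are linearly dependent and
ignored.  Derivatives for the speed series use second-order central
differences with second-order one-sided stencils at the ends, so all
series share one length.

**Beat averaging.**  Peaks: local maxima of the voltage series above 40%
of its global maximum, ≥ 300 ms apart (the larger peak wins inside a
refractory span), discarding peaks within 110 ms of the record edges.
Windows: 221 samples (220 ms) centred on the peak.  Endpoint zeroing is
implemented as per-axis linear-tilt removal (the line through each axis'
own first and last sample); zeroing the voltage norm directly would break
the norm identity, so the voltage is always recomputed from the corrected
axes — likewise the averaged beat's voltage/speed are computed from the
averaged X/Y/Z, never by averaging per-beat norms.  Quality control uses
the minimum pairwise Pearson correlation of the voltage windows with an
inclusive ≥ 0.9 pass rule (a beat-to-average variant is available); whole
recordings, not single beats, are excluded.

## Depolarization limits

The supra-threshold duration L(θ) of the run containing the voltage peak
is evaluated on a 0.001-mV grid from 0 to 95% of the peak, with linear
interpolation between bracketing samples, so analytic pulses reproduce
their closed-form length curves exactly.  The curve is fitted with a
7th-order polynomial (`Polynomial.fit`, internally rescaled domain).

**Normalization of the criterion (a design decision).**  The slope dL/dθ
is normalized by window_ms / peak_mV, making the initial flank collapse
O(−1) for any beat amplitude; the detection criterion −0.275 is applied to
this normalized derivative.  The equivalent raw-slope criterion is
−0.275 × window/peak ≈ −60 ms/mV for a 1-mV beat.  The threshold is the
first grid point where the normalized derivative *recovers* to the
criterion after having first dipped below it; if it never dips below, the
criterion is met immediately (first grid point); if it dips and never
recovers, the fallback returns the flattest point of the descent.  Both
the criterion and the polynomial order are configuration values, since the
criterion was originally a tuned constant.

**Sub-sample resolution.**  The full detector interpolates the averaged
voltage 8× with a cubic spline before the sweep.  At 1-ms sampling, L(θ)
is piecewise linear with segments ≈ 0.02–0.03 mV wide near the criterion,
which quantizes any finite-difference slope estimate; spline interpolation
recovers the smooth curve (with less ringing than sinc reconstruction on
these not-band-limited pulses).  A brute-force route — span-limited central
differences on the raw length curve, no polynomial — is kept as an
independent cross-check of the polynomial route; on the generator's
template beats the two agree within ≈ 0.002 mV, and within ≈ 0.02–0.03 mV
through the full projection/noise/filter chain (the polynomial smooths what
the measurement chain bends).

## Synchrony index and cutoff

VTI and STI are trapezoidal integrals between the interpolated onset and
offset.  The control line is ordinary least squares of STI/10,000 on
VTI/100 (statsmodels under the hood; intercept k and slope m are taken
from this normalized fit), exposed as a Model → Results pair
(`ControlLine(...).fit()` → summary, standard errors, r², confidence band,
JSON round trip).  The index is the normalized perpendicular distance to
the line; it is invariant to joint rescaling of data and normalization
constants and grows with slope one per unit of normalized perpendicular
displacement.

The Youden cutoff sweeps the midpoints of consecutive sorted unique index
values, calling `index ≥ cutoff` positive.  The maximal-Youden plateau is
reported as the data values bracketing the first contiguous block of
optimal midpoints, with the plateau mean as the working cutoff.  A
logistic regression of class on index accompanies the cutoff for
probability reporting; on cleanly separated cohorts the likelihood
diverges, and a weakly ridge-regularized fit is substituted (flagged in
the summary).  TPS-SD is the n−1 standard deviation of the 18 per-segment
times of minimum strain on the common time axis; a flat segment is an
error naming the segment.

## Synthetic data generator

The generator exists so every stage is testable with known ground truth;
its defaults define the package's study conditions.

**Beat model.**  One beat is a rotating dipole: magnitude R(t) × a unit
direction sweeping a fixed loop plane at a uniform angular rate
(`loop_turns` full rotations across the QRS).  Voltage is then exactly
amp·R(t) (axis anisotropy is renormalized into the direction, shaping only
the loop's eccentricity and hence the speed), and the STI/VTI slope is set
by the rotation rate — about 2π·turns/width × 10³ in the printed ms⁻¹
scale.  A full rotation over a ~95-ms QRS gives the healthy slope of
≈ 70 ms⁻¹; the `lbbb`/`paced` presets rotate slowly over wide, tall loops
(large VTI, depressed STI), `rbbb` is intermediate.  The normal preset's
rotation rate is calibrated so its template slope is 70.26 ms⁻¹ and its
amplitude so control cohorts land at VTI ≈ 45 mV·ms — the healthy regime.

**Profile design.**  R(t) is defined through its width function: the
supra-level width W(θ) is a monotone degree-7 polynomial (a decelerating
flank collapse onto the QRS core, a tilted plateau, a smooth fall to the
peak) that reaches zero exactly at the edges of the 220-ms analysis
window.  Two consequences: (i) the template has *closed-form
depolarization limits* under the detector's own criterion — the ground
truth VTI/STI are fine quadratures of the loop over that analytic segment;
(ii) the emitted length-vs-threshold curve is itself essentially a
7th-order polynomial, which the detector's fit can represent without bias
— this is what makes the polynomial-vs-brute-force agreement testable at
millivolt-thousandth resolution.  P and T waves sit wholly outside the
analysis window.

**Lead projection.**  The loop is projected to the 8 independent leads
with the Dower image-surface matrix (augmented leads derived from I and
II); analysis uses the Kors matrix, so synthesis and analysis matrices
differ and the round trip is a measured approximation, not an identity
(voltage relative RMS error ≈ 3%, integral errors ≤ ~3% on clean presets;
tolerances pinned in tests).  The loop plane is oriented
frontal-plane-dominant, the physiological regime in which the two
regression matrices transport loops near-isometrically.  Beats snap to
whole samples (sub-sample phase is not modelled), the first beat sits at
1 s clear of filter edge transients.

**Disturbances and cohorts.**  Defaults: white noise 8 µV RMS per lead,
0.05-mV baseline wander at 0.25 Hz, 0.01-mV powerline at 50 Hz,
no extrasystoles (extrasystoles — premature, narrower, taller,
slower-rotating beats — are available and reliably trip the correlation
gate).  Cohort jitter: a common log-normal amplitude factor (σ = 0.25,
the dominant inter-subject spread, shared by VTI and STI), per-axis
factors (σ = 0.05), QRS-width factor (σ = 0.03), loop-rate factor
(σ = 0.08), heart rate uniform 55–85 bpm.  With these conditions control
cohorts fit the line with r² ≈ 0.9 and slope ≈ 0.70–0.73 (normalized),
and about 5–8% of records fail the correlation gate — wide paced
morphologies are over-represented among exclusions because their flat
voltage maxima misalign under noise.

**What passing tests do and do not show.**  The generator exercises every
pipeline stage with controlled truth, but its beats are cleaner than real
ECGs: morphology is identical beat to beat (no respiratory modulation or
QRS alternans), noise is stationary and Gaussian, the T wave never leaks
into the analysis window, and the class presets are well separated.
Perfect Youden separation on synthetic cohorts therefore says the
*pipeline* is sound, not that real LBBB/paced patients separate perfectly;
on real data the index distributions overlap and the cutoff has
sensitivity/specificity below 1.

## Problem sizes

The default test suite and the acceptance script run on 10-s, 1-kHz,
12-lead records; the acceptance cohort is 90 controls + 9 RBBB + 8 LBBB +
11 paced records (the populations the method was designed around), which
the full pipeline processes in a few seconds.

## Known limitations

- Only WFDB format 16 and plain CSV are parsed; the WFDB reader is a
  minimal native implementation (single signal file, format 16 — the PTB
  layout), not a general WFDB library.
- The depolarization-limit criterion normalization is pinned by this
  package (see above); other normalizations would shift the −0.275
  default.
- The confidence band on the control line is a mean-response (confidence)
  band, not a prediction band.
- Survival/outcome modelling and speckle-tracking image analysis are out
  of scope; TPS-SD starts from an exported time–strain table.
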