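# Methods

This note documents the models, parameter choices and numerical decisions
behind `fecgkit`, and what the synthetic-data experiments do and do not
demonstrate about real abdominal recordings.

## Signal model

An abdominal channel is modelled as the sum of a maternal ECG projection, a
fetal ECG projection and interference:

```
x_c(t) = g_m,c · m(t) + g_f,c · f(t) + n_c(t)
```

where `m` and `f` are quasi-periodic PQRST trains and `n_c` collects EMG
noise, 50 Hz powerline and baseline wander. The maternal QRS spans about
100 ms, the fetal about 40 ms; these two widths are used consistently as
the analysis windows for power estimation, coincidence determination and
per-beat shape coefficients. Maternal/fetal beat *coincidence* (overlap of
those windows) is the central nuisance: it corrupts per-beat power and
shape estimates and makes template fitting ambiguous.

## Preprocessing

The notch comb `H(z) = z^-50 − (1/36)·((1−z^-60)/(1−z^-10))²` is expanded
to its explicit 101-tap FIR form (a unit tap at delay 50 minus a triangular
comb 1..6..1 on the 10-sample lattice, divided by 36) rather than realised
recursively. The rational form has pole–zero cancellations on the unit
circle at every zero of `1−z^-10`; the expanded FIR is unconditionally
stable and its nulls at multiples of 50 Hz are exact in floating point
(verified to <1e-12). Both branches share a linear-phase delay of 50
samples, which is removed after filtering so beat fiducials stay aligned.
Edges are handled by reflect-padding with one filter length and trimming,
making outputs deterministic. Delays scale by `rate/500`; rates not
divisible by 50 Hz are rejected because the notches would leave the
integer-delay lattice.

## Maternal ECG suppression

* **Auxiliary signal.** The channel mean is used to detect maternal R
  waves: maternal QRS adds coherently across electrodes while fetal beats
  and EMG, being uncorrelated or differently weighted, are attenuated
  roughly by 1/√channels.
* **Detection.** Band-pass 8–35 Hz, differentiate, square, 120 ms
  integration, adaptive threshold at half an exponentially updated peak
  level, 300 ms refractory (maternal rate ≤ 200 bpm), apex refinement on
  the band-passed signal within ±60 ms.
* **Template.** The PQRST template spans 250 ms before to 450 ms after R —
  wide enough to cover P through T at maternal rates. It is initialised
  from the per-sample median of the first 8 complete beats and then updated
  exponentially with weight 1/8. Before each update the incoming beat is
  clamped to ±3 robust SD around the current template: a fetal QRS crossing
  the window is a transient outlier that must not be absorbed into the
  maternal pattern, while slow morphology drift passes through the clamp.
* **Subtraction.** Per beat, a scale on the template and a scale on the
  first derivative of its QRS portion are fitted by least squares over
  QRS ± 50 ms (the QRS carries the energy; fitting the T wave is
  unstable), then the full cycle is subtracted. The derivative term
  linearises sub-sample fiducial error: `x(t−δ) ≈ x(t) − δ·x'(t)`, so
  quantising fiducials to the 2 ms grid costs little residual.
* **Scale regularisation.** A fetal QRS coincident with the maternal one
  is partially representable in the {template, derivative} basis, so an
  unconstrained per-beat fit absorbs (and subtracts) part of the fetal
  beat. Because maternal amplitude varies slowly, the per-beat scales are
  smoothed in a second pass: scales deviating from their 9-beat local
  median by more than 3.5 robust SD (plus a 1% floor) are replaced by that
  median. In the noiseless limit this makes suppression exact and leaves
  coincident fetal beats untouched; with EMG present it removes the
  heavy-tailed fit errors that coincidences cause.

## Fetal QRS detection

Three detection functions are computed on the channel with the highest
autocorrelation periodicity score (normalized windowed autocorrelation,
maximised over lags corresponding to 110–180 bpm, 4 s windows, unbiased
lag normalisation):

1. normalized matched filter |ρ| — correlation with the fetal template
   divided by local signal energy over the template support; bounded by 1,
   invariant to channel gain, insensitive to EMG bursts;
2. raw matched-filter magnitude;
3. band-pass energy (15–45 Hz, differentiate, square, 40 ms integration).

The fetal template is bootstrapped from the record: a generic biphasic
40 ms seed finds the 20 strongest normalized-correlation events, whose
sign- and peak-aligned average becomes the working template. Peak picking
uses threshold = 0.5 × a robust running level (exponentially updated
toward the median of the last 8 accepted peaks, so isolated spurious
accepts cannot drag the threshold down) and a 200 ms refractory period in
which the stronger of two competing peaks wins. The function with minimal
Δ (mean absolute second difference of the RR series; undefined below 4
peaks) is selected; ties go to the lowest k. In simulation the matched
filter usually wins; the Δ criterion is what makes that choice
data-driven. Reliability flags are cleared where the local
detection-function SNR falls below 2 or the local Δ over a 10-beat window
exceeds 3× the record median.

The direct-FECG detector accepts candidate normalized-correlation peaks
sequentially: among comparably strong candidates (≥70% of the window
maximum) in the plausible window `(0.5·RR_pred, 1.6·RR_pred]` after the
last beat, it picks the one minimising `|RR − RR_pred|`, with `RR_pred`
the median of the last 8 accepted intervals. The amplitude gate prevents
the timing cost from locking onto weak noise peaks whose spacing happens
to match the prediction.

## Quality indices

`P_N` is the mean square outside all maternal (100 ms) and fetal (40 ms)
windows; `P_M`/`P_F` are in-window mean squares over non-coincident beats
minus `P_N`, clipped at zero (and flagged) when negative. Windows are
centred on the R fiducial — the symmetric choice. The decomposition
assumes signal and interference are uncorrelated and that maternal P/T
waves are small; in practice P/T energy leaks into `P_N` and under the
fetal windows, which biases `P_F` upward by some 10–25% at high maternal
amplitude. This is a property of the estimator, not a bug, and is covered
by tolerance in the recovery tests.

WEM/WEF are implemented as the RMS of successive differences of the
projection coefficients rᵢ divided by their mean (RMSSD/mean). A literal
reading without squaring the differences would make the radicand sign-
indefinite and the quantity dimensionally inconsistent; the absolute-
difference variant is available via `mode="abs"` for comparison. Both are
zero for constant beats and invariant to overall scale.

Per-record indices are the arithmetic mean over the four channels, and
batch summaries are the arithmetic mean over records — the same
aggregation path is used for measured reports and for the published
per-record tables shipped in `fecgkit.reference`.

## FHR analysis

Instantaneous FHR (60000/RRᵢ) is held constant over each interval and
sampled at 4 Hz (zero-order hold, mirroring cardiotocograph behaviour).
Intervals adjacent to a reliability-flag-0 beat, or outside 50–250 bpm,
are masked; masked grid samples count as signal loss and enter no
statistic. The basal level starts at the histogram mode (0.5 bpm bins) of
a 0.04 Hz low-passed trend and is refined twice as the median of samples
within ±10 bpm of the current level — the mode anchors the estimate at the
dwell level, the median step removes the edge bias a mode estimator has on
oscillatory traces. Accelerations/decelerations are departures from the
baseline (onset threshold 5 bpm) whose peak reaches ±15 bpm and whose
duration reaches 15 s; episodes in progress at either record boundary are
not counted. Fluctuation is the mean minute-wise peak-to-peak excursion
around the basal level with episode spans excluded; oscillation is the
minute-wise peak-to-peak of the fast component (grid minus its 0.04 Hz
trend). STV/LTV use 3.75 s epoch means of RR (16 epochs/min): STV is the
mean absolute successive-epoch difference, LTV the mean minute-wise epoch
range. LTI is the interquartile range of √(RRᵢ² + RRᵢ₊₁²), STI the
interquartile range of arctan(RRᵢ₊₁/RRᵢ), II the per-minute coefficient of
variation of RR (averaged), and DI 1000× the SD of
(RRᵢ₊₁−RRᵢ)/(RRᵢ₊₁+RRᵢ). These are literature-standard formulations; a
proprietary monitor's exact algorithms differ in unpublished details, so
per-record FHR tables from clinical systems are not expected to reproduce
numerically — the module is validated by recovering programmed generator
patterns instead.

## Synthetic records

Morphologies are sums of Gaussians (P, Q, R, S, T) with maternal QRS
≈100 ms and fetal ≈40 ms wide; fetal P/T are kept below 1% of R, since in
abdominal leads the recorded fetal contribution is effectively QRS-only.
Beat times integrate an instantaneous-rate profile: baseline bpm,
raised-cosine acceleration/deceleration events, sinusoidal oscillation and
Gaussian beat-to-beat jitter. Defaults encode the mean antenatal
conditions: fetal baseline 142.5 bpm with 3 bpm/0.05 Hz oscillation and
2.5 ms jitter, maternal 80 bpm, targets WM 14.3 dB and WF 3.4 dB, EMG
5 µV RMS (band-limited 20–150 Hz), 3 µV powerline, 5 µV wander — levels
at which the fetal R stays below ~20 µV. Each channel's maternal and
fetal scales are calibrated by fixed-point iteration against the actual
quality-index estimator on the emitted record, so programmed and measured
operating points agree by construction (tolerance 0.15 dB, error above
1 dB raises). In the noiseless limit dB targets are undefined and nominal
amplitudes (60/15 µV) are used. Component traces are stored and sum
exactly to the emitted signal; everything is reproducible from the seed.
When a direct channel is generated, the record's fetal reference follows
the intrapartum convention (gold-standard annotations at 1 kHz).

What the simulator does *not* emulate: electrode-drop artifacts, maternal
arrhythmia, uterine-contraction EMG bursts, fetal movement repositioning
the fetal vector, and non-stationary noise. Passing the end-to-end tests
therefore shows the chain is correct and accurate under the programmed
amplitude relations, not that it attains the same scores on clinical
recordings.

## Problem sizes

The test suite exercises 2-minute records for unit-level checks; the
end-to-end recovery experiment uses a 10-minute record (≈1,400 fetal
beats) and the calibration-grid round trip 16 two-minute records, sizes at
which the measured indices are stable to well under the asserted
tolerances. The FHR pattern-recovery experiment uses a 20-minute record
with six programmed accelerations and two decelerations, mirroring a
typical antenatal session.

## Data layout and conventions

Signals are whitespace-delimited text matrices (rows = samples, columns =
channels, 6 significant digits); annotations are integer sample numbers,
1-based on disk (the common clinical export convention, configurable) and
0-based in memory, with an optional 0/1 reliability flag column in fetal
files. Reading never filters or rescales. LabView binary twins of the
text files are not parsed. Known limitations: single-fetus assumption
throughout; no morphology (ST/T) analysis; the beat-matching tolerance is
fixed at ±40 ms by convention rather than adapted to gestational age.
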