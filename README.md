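# fecgkit

A toolkit for **non-invasive fetal electrocardiography**: extracting fetal
heart beats from multichannel maternal abdominal ECG recordings, scoring
detection performance against reference annotations, quantifying signal
quality, and characterising fetal heart-rate (FHR) variability.

Abdominal recordings of fetal cardiac activity are dominated by the maternal
ECG (MECG) — the maternal QRS is typically 3–5× larger than the fetal one,
whose R wave rarely exceeds 20 µV — on top of muscle (EMG) noise, 50 Hz
powerline interference and baseline wander. `fecgkit` implements the full
processing chain needed to turn such recordings into beat-accurate FHR
signals, and a calibrated synthetic-record generator so that every stage is
testable without access to archived clinical data.

## What it implements

**Preprocessing** — a linear-phase FIR comb filter

```
H(z) = z⁻⁵⁰ − (1/36)·((1 − z⁻⁶⁰)/(1 − z⁻¹⁰))²        (500 Hz form)
```

with exact zeros at DC and every multiple of 50 Hz, a ≈5 Hz lower passband
edge, delays rescaled for other rates (1 kHz: 100/120/20) and group-delay
compensation so fiducials keep their sample positions.

**MECG suppression** — maternal R waves are detected on a spatial-mean
auxiliary signal; a PQRST template (250 ms before to 450 ms after R,
exponentially updated with robust clamping) is amplitude-fitted per beat by
least squares over the QRS ± 50 ms window, together with a term proportional
to the first derivative of the QRS template that absorbs sub-sample fiducial
jitter, and subtracted over the full heart cycle.

**Fetal QRS detection** — a bank of K = 3 detection functions (normalized
matched filter, raw matched filter, band-pass energy) with adaptive
thresholding; the best channel is chosen by a windowed autocorrelation
periodicity score, and the best detection function by minimising the RR
smoothness functional

```
Δₖ = Σᵢ |[RRₖ(i+2) − RRₖ(i+1)] − [RRₖ(i+1) − RRₖ(i)]| / (Iₖ − 3),
k_opt = argmin Δₖ.
```

A separate detector for direct (scalp-electrode) FECG uses normalized
matched filtering plus a cost rule that predicts the next heart-cycle
length with a running median.

**Signal-quality indices** — interference / maternal / fetal power
decomposition around the annotations (100 ms maternal and 40 ms fetal QRS
windows, coincident beats excluded), giving

```
WM = 10·log₁₀(P_M/P_N),  WF = 10·log₁₀(P_F/P_N),  WMF = WM − WF   [dB]
```

and the QRS energy-variation indices WEM/WEF built from per-beat projection
coefficients rᵢ onto the mean beat shape.

**Detection scoring** — optimal order-preserving one-to-one beat matching
within ±40 ms, the indices PI, Acc, Se, PPV, F1, and RR-interval accuracy
statistics (ΔRR in ms and bpm).

**FHR analysis** — instantaneous FHR (60000/RRᵢ) resampled by zero-order
hold to the 4 Hz cardiotocography grid; signal loss, basal FHR,
fluctuation, acceleration/deceleration episodes (±15 bpm / 15 s),
oscillation, Dawes/Redman STV/LTV on 3.75 s epochs, de Haan LTI/STI and
Yeh II/DI.

**Simulator** — sum-of-Gaussians PQRST morphologies, programmable FHR
profiles (baseline, accelerations/decelerations, oscillation, beat-to-beat
jitter), EMG/powerline/wander noise, a 4-channel mixing model and a direct
1 kHz fetal channel. Maternal and fetal amplitudes are calibrated in closed
loop so the emitted record measures the requested (WM, WF) operating point.

## Worked example

```python
from fecgkit import simulate, preprocess, mecg, fqrs, metrics, quality

cfg = simulate.SimulationConfig(duration_s=600.0, seed=1)  # WM 14.3, WF 3.4 dB
bundle, truth = simulate.generate_record(cfg)

rep = quality.record_quality_report(bundle)
# {'WM': 14.21, 'WF': 3.35, 'WMF': 10.86, 'WEM': 0.05, 'WEF': 0.36}

filtered = preprocess.comb_filter(bundle.abdominal_raw)
fecg, maternal_r, _ = mecg.suppress_mecg(filtered)
ann, detail = fqrs.detect_fetal_r(fecg)
m = metrics.match_beats(truth.fetal_r, ann, tolerance_ms=40.0)
p = metrics.performance_indices(m)
stats = metrics.rr_accuracy(m, truth.fetal_r, ann)
# channel A1, detection function 2
# Se 99.16%  PPV 98.54%  F1 98.85%  |ΔRR| 1.37 ms
```

The quality report confirms the generator hit its programmed operating
point (maternal QRS ≈ 14 dB and fetal QRS ≈ 3.4 dB above the interference
floor, i.e. the maternal complex is ~3.5× the fetal in amplitude); the full
chain then recovers over 99% of the fetal beats with a mean RR-interval
error of 1.4 ms — accurate enough for beat-to-beat FHR variability
analysis.

The same chain is available from the shell:

```bash
fecg simulate --seed 3 --duration 120 --out-dir rec
fecg preprocess --in rec/synthetic_abSignals_01.txt --rate 500 --out filt.txt
fecg suppress   --in filt.txt --rate 500 --out fecg.txt
fecg detect     --in fecg.txt --rate 500 --out det.txt
fecg evaluate   --ref rec/synthetic_Fetal_R_01.txt --ref-rate 1000 \
                --test det.txt --rate 500 --out metrics.json
fecg fhr        --annotations rec/synthetic_Fetal_R_01.txt --rate 1000 --out fhr.json
```

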