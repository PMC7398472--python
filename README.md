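# tcdenv

Calibration-free maximal blood flow velocity estimation from transcranial
Doppler (TCD) spectrograms, with a beat-by-beat signal quality index.

## The problem

Transcranial Doppler ultrasonography insonates cerebral arteries — typically
the middle cerebral artery (MCA, flow toward the probe, positive velocity) or
the internal carotid artery (ICA, flow away, negative velocity) — and records
a complex demodulated echo ("IQ") signal.  Its short-time spectrum is a
time–velocity image whose upper edge, the *envelope*, is the maximal blood
flow velocity: the clinically used TCD quantity, feeding pulsatility indices,
vasospasm screening and non-invasive intracranial-pressure estimation.  TCD
spectrograms have low SNR and intermittent signal loss, which makes robust
envelope tracing hard.

## The method

Given a spectrogram `SP[t, v]` normalised to [0, 1], each 60 s segment is
processed as follows:

1. **Flow region** — compare summed intensity in ±(5–125) cm/s; the stronger
   band fixes the flow sign, and processing continues on velocity magnitudes.
2. **Candidate segmentations** — Otsu's threshold γ\* on the flow band, then
   a grid Γ = {0.9, 0.95, 1.0, 1.05, 1.1}·γ\*.  Each γ yields a binary mask,
   despeckled with a 0.03 s × 5 cm/s median kernel.
3. **Envelope tracing** — per column, the five highest white pixels (scanned
   down from 152 cm/s) are tested against two physiological checks: the
   majority of the 40 bins (≈12 cm/s) below the candidate must be white, and
   the candidate may not deviate more than 30 cm/s from the mean of the
   previous three estimates (≈14 ms at the 217 Hz column rate).  Failing
   columns hold the previous value; after 20 consecutive failures the
   maximal candidate is taken regardless, so the trace can re-lock.
4. **Quality feedback** — each candidate envelope is cut into beats (slope-
   sum-function onset detector), screened (systolic max > 30 cm/s, pulse
   amplitude > 20 cm/s, duration within 0.25–2 s and 0.5–2× the median),
   and compared to the segment's median beat template by normalised MSE on
   the first 75 % of the template span.  NMSE > 30 % flags an artifact; the
   *artifact index* is the flagged-beat percentage and the candidate with
   the smallest artifact index wins.  Per-beat SQI = 100·max(0, 1 − NMSE).
5. **Post-processing** — 3-sample median, then zero-phase 4th-order
   Butterworth low-pass at 16 Hz; flow sign restored.

Velocity conversion uses the Doppler equation `v = Δf·c / (2 f_c cos α)`
with c = 1540 m/s, f_c = 1.75 MHz and α = 0° by default; at the 6.944 kHz
echo sampling rate the maximal detectable velocity is ≈152 cm/s.

The package also ships the classical fixed-threshold MTCM baseline, the
agreement metrics (waveform/peak bias, SD, relative error, Bland–Altman
pairs), and a synthetic scene generator with stored ground truth.

## Worked example

```python
import numpy as np
import tcdenv
from tcdenv.synth import preset_scene
from tcdenv.metrics import waveform_errors, beat_peaks, peak_errors

scene = preset_scene("mca", seed=1)          # 60 s, PSV 90 / EDV 40 cm/s
trace = tcdenv.estimate_envelope(scene.spectrogram)

seg = trace.segments[0]
print(seg.gamma_otsu, seg.selected.gamma)
wf = waveform_errors(trace.velocities, scene.true_envelope)
pk = peak_errors(beat_peaks(trace.velocities, scene.true_onsets),
                 beat_peaks(scene.true_envelope, scene.true_onsets))
```

Output on this scene:

```
flow sign          : +1
gamma_Otsu         : 0.6367
gamma grid         : [0.573, 0.6049, 0.6367, 0.6686, 0.7004]
artifact index (%) : [0.0, 0.0, 0.0, 0.0, 0.0]
selected gamma     : 0.6367
waveform bias m_e  : +0.33 cm/s  (sd 0.19, rel +0.61%)
peak bias          : -0.80 cm/s  (rel -0.89%)
mean beat SQI      : 100.0%
```

All five candidate thresholds give artifact-free envelopes on this clean
scene, so the tie-break keeps γ_Otsu; the recovered waveform is within a
fraction of a velocity bin of the ground truth and the systolic peak shows
the slight negative bias expected from the low-pass post-processing.

The same workflow is available from the shell:

```sh
tcdenv simulate --preset mca --seed 7 --out scene/
tcdenv trace --input scene/spectrogram.csv --out-envelope env.csv --out-report report.json
tcdenv evaluate --estimate env.csv --reference scene/truth.csv --out metrics.json
tcdenv mtcm --input scene/spectrogram.csv --threshold 0.6 --out-envelope mtcm.csv
```

`evaluate` accepts any reference CSV with `time_s, velocity_cm_s` columns,
including manual-trace exports.

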