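# Methods

This note documents the models, parameter choices and numerical decisions
behind `tcdenv`, and what the synthetic-scene tests do and do not show.

## Spectrogram computation

The demodulated echo is high-passed with a second-order Butterworth wall
filter (cutoff 100 Hz) to remove vessel-wall clutter.  Because processing is
offline, the filter is applied forward–backward (zero phase), which squares
the magnitude response: the effective attenuation at the cutoff is −6 dB
(amplitude gain 0.5).

The short-time Fourier transform uses a hop of 1/217 s and a window of four
hops (≈18.4 ms, 75 % overlap), Hann taper, 1024-point zero-padded FFT.
Frames are centred at k·hop with reflect padding at the edges, so the column
rate is exactly 217 Hz and column k corresponds to time k/217 s.  At the
default 6.944 kHz echo rate this gives a velocity bin of ≈0.2984 cm/s and a
two-sided axis of ±152.8 cm/s.  The window length follows from the 217 Hz
envelope rate rather than a nominal "10 ms" analysis window: the envelope
rate is the quantity every downstream constant (three-sample continuity
lookback ≈14 ms, 40-bin support ≈12 cm/s, 16 Hz post-filter) is defined
against.

Per column the two-sided power spectrum is compressed to display intensity

    I = clip(1 + 10·log10(P / P_max) / D, 0, 1),   D = 40 dB,

the standard ultrasound mapping: the global maximum maps to 1, anything more
than D below it to 0.  A zero-power input has no defined normalisation and
is rejected.

## Segmentation

Otsu's threshold is computed on a 256-bin histogram of the flow-band
(|v| in 5–125 cm/s) intensities of the segment being traced, by exhaustive
scan over interior bin edges minimising the within-class variance.  Pixels
with intensity ≥ threshold are signal, which makes threshold 0 the
deterministic all-signal case.  Constant regions and a zero threshold are
degenerate and flagged with a warning.  Note that for a perfectly bimodal
histogram with an *empty* gap between the modes the within-class variance is
flat across the gap and the scan returns the gap's first edge; any edge in
the gap produces the identical segmentation.

The candidate grid is {0.9, 0.95, 1.0, 1.05, 1.1}×γ_Otsu, clipped to ≤1 and
deduplicated.  Despeckling is a 2D median filter with a physical kernel of
0.03 s × 5 cm/s, converted to odd pixel counts (7 columns × 17 rows at the
default axes) with edge replication at the boundaries.  For a binary mask
the median equals the majority vote, so it is evaluated as an exact
separable box-count, which is much faster than a rank filter on minute-long
images and bit-identical to it.

## Envelope tracing

Per column, up to five white pixels are examined top-down starting from
152 cm/s.  A candidate is accepted if (1) strictly more than half of the 40
velocity bins below it are white — bins below the 5 cm/s wall-filter floor
(or below the axis) count as white, so genuine low-velocity edges are not
penalised for sitting on the stop band — and (2) it deviates at most
30 cm/s from the mean of the previous three estimates.  The continuity
check is skipped for the first three columns (no history); the first column
takes the highest candidate passing the support check, else 0.  When no
candidate passes, the previous value is held; after more than 20
consecutive failures the maximal candidate is taken regardless and the
failure counter resets (a column with no candidates at all keeps holding
and leaves the counter saturated).  The counter also resets whenever any
candidate passes both checks.  The trace is deterministic.

## Beat quality and threshold selection

Beat onsets are found on a rescaled copy of the envelope (linear factor
140 / mean per-beat maximum, an arterial-pressure-like scale) using a slope
sum function over a 128 ms window with an adaptive threshold — 40 % of the
median of the last five accepted SSF peaks, initialised from the segment's
98th SSF percentile — and a 250 ms refractory period.  Each accepted
crossing is mapped to the beat foot (latest envelope minimum in the
preceding 200 ms).  Rescaling affects detection only, never reported
velocities, and makes the detector exactly scale-invariant.

Each beat must pass four screens: systolic maximum > 30 cm/s, pulse
amplitude > 20 cm/s, duration in (0.25, 2) s, duration within (0.5, 2)× the
segment's median.  Valid beats are zero-padded to the longest valid beat,
the pointwise median is the template, truncated to the median valid-beat
length.  The normalised MSE between a beat and the template is evaluated on
the first 75 % of the template span (heart-rate variability concentrates in
late diastole) as mean((b−t)²)/mean(t²); beats above 30 % NMSE are
artifacts.  Screen-failed beats get SQI 0, are excluded from the template
and the NMSE set, but count in the artifact-index denominator.  The
candidate threshold with the smallest artifact index is selected, ties
broken toward γ_Otsu and then toward the smaller threshold.

A consequence worth knowing: a spectrogram containing *only* stationary
noise traces to a consistent near-constant envelope at the top of the band,
which the template matching has no pulsatility argument against — the same
failure mode classical threshold methods show.  The screens do catch flat
(pulseless) traces, dropouts and erratic segments.

## Post-processing

The selected raw envelope is median-filtered (3 samples, ≈14 ms) and then
low-passed with a zero-phase 4th-order Butterworth at 16 Hz.  The median
runs first: it must see isolated single-sample outliers to reject them,
whereas a low-pass smears a spike over ~13 samples into a bump a 3-sample
median cannot remove (measured residual 4.3 cm/s vs ~0 for median-first).
The low-pass is the main source of the small negative peak-systolic bias.

## MTCM baseline

The modified threshold crossing method slides a group of 10 velocity bins
from the high-velocity (noise) end of the flow band toward zero and sets
the envelope to the top bin of the first group with ≥5 intensities above a
fixed, manually chosen threshold; no qualifying group yields 0.  Group size
and exceed count are configurable (the classical recipes vary); the
threshold is deliberately *not* automated — automating it would reproduce
the adaptive algorithm rather than the fixed-threshold comparator.

## Agreement metrics

For e[n] = v_algo[n] − v_ref[n]: bias m_e = mean(e), population variance
σ_e² = mean((e − m_e)²) (1/N, not 1/(N−1), matching the definition of the
reported statistics), relative error r_e = Σe/Σv_ref.  The same three
statistics are computed on per-beat peak-systolic differences, with
(mean, difference) Bland–Altman pairs.  Negative-flow references are
sign-flipped before comparison; a reference whose mean is near zero
relative to its magnitude indicates sign-crossing flow and is rejected.
Beats between two traces are paired by nearest onset within 0.3 s;
unmatched beats are excluded and counted.

## Synthetic scenes

The generator emulates the statistical structure the algorithm assumes, not
acoustics.  Ground truth comes first: beats of duration N(60/HR, 0.03 s)
(floored at 0.3 s) with a raised-cosine systolic upstroke (rise time
min(0.15 s, 0.3·beat)), exponential diastolic decay (τ = 0.18·beat) from
PSV toward EDV, and a Gaussian dicrotic bump (amplitude 0.15× pulse at
0.45 of the beat) — values a physiologically plausible middle cerebral
flow waveform shows.  Presets: MCA (PSV 90 / EDV 40 cm/s, positive flow),
ICA (60/25, negative), low-SNR (10 dB) and a dropout scene with a 2 s
signal loss attenuated to 3 %.

Rendering places, per column, a unit power plateau over [5 cm/s, env(t)]
with a logistic edge rolloff of 10–90 % width 4 cm/s (the order of the
STFT-resolution broadening at an 18 ms window), an exponential
(speckle-like) noise floor 20 dB below the plateau by default, optional
salt speckle (p = 0.005) and dropout attenuation of the signal term, then
the same 40 dB log-compression as the measurement path.  The rolloff is
placed so the rendered signal support tops out at the stored truth (half
power at env − width/2): the ground truth is defined as the maximal
velocity carrying signal power, which is the quantity an edge tracer — or
a human annotator — estimates.  Centring the rolloff at the truth instead
would smear power above the true maximum and build a constant
+width/2 bias into every comparison.

The IQ synthesiser draws, per 1/217 s block, 64 scatterer velocities
uniformly below the (broadening-adjusted) envelope, smears them with a
logistic edge, maps them through the inverse Doppler equation and sums
random-phase complex exponentials plus complex white noise at the
configured SNR.  All randomness flows from the single scene seed; scenes
are bit-reproducible.

What passing these tests shows: the full loop recovers a known envelope
through segmentation, tracing, quality selection and filtering, flags
signal loss, and degrades monotonically with noise.  What it does not
show: behaviour under real spectral broadening physics (angle spread,
transit time), probe motion, aliasing, heart-rate variability beyond mild
Gaussian jitter, or reverse (sign-crossing) flow — the region-selection
design cannot represent the latter at all.

## Problem sizes and determinism

The standard scenes are 60 s (one segment, ~13 000 columns × 1024 bins);
property tests use 10 s scenes, and the noise-degradation check runs three
SNR levels (10, 0, −3 dB) × 10 seeds at 10 s.  The pipeline itself contains
no randomness: identical input gives identical output, and all synthetic
randomness is derived from explicit seeds.

## Known limitations

* Sub-bin edge localisation is not attempted; quantisation is ±0.3 cm/s.
* The artifact index cannot condemn stationary-noise segments with a
  spuriously consistent band-top trace (see above).
* Segment boundaries are hard; beats straddling them belong to the segment
  containing their onset, and threshold adaptation does not warm-start
  across segments.
* The MTCM baseline requires a manual threshold by design.
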