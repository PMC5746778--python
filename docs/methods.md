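# Methods

`uwbradar` implements the processing chain of an ambient ultra-wideband
impulse-radar (UWB-IR) smart sensor for in-home monitoring: acquisition
timing, synthetic scene rendering, clutter suppression, micro-Doppler
analysis, micro-motion signatures, EMD-based cardiorespiratory rate
estimation, and one-class-SVM fall detection. This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Acquisition timing

The monostatic radar module quantizes fast time on a sampler grid of
1 µs / 2¹⁹ = 1.9073486 ps; scan samples advance 32 quanta (61.035 ps) and are
organized in stack segments of 96 samples (5.8594 ns ≈ 0.878 m of range). A
desired window [R̃₁, R̃₂] maps to bin count N = 96⌈2(R̃₂−R̃₁)/(5.8594 c)⌉ with
c = 0.29979 m/ns, to fast-time instants T₁, T₂ via floor/ceil quantization on
the fine grid, and to the actual window Rᵢ = c/2 (Tᵢ − 10 ns). Scan duration
is ts = 0.792 µs · 2^PII · Round((T₂−T₁)/5.8594) with the pulse-integration
index PII ∈ [6, 15]; idle time fills the slow-time period 1/Fs (20 ms at
50 Hz). Rake integration of 2^k pulses improves SNR by 18 dB + 3 dB per
doubling above 64. Two deliberate numerical choices: the *exact* sampler
quantum (not its 4-digit rounding) is used in the T₁/T₂ formulas, because it
reproduces the module's published parameter table to the printed 1 ps
precision while the rounded constant is one fine bin low; and Round(·) is
half-away-from-zero (table inputs never land on .5, but the choice must be
fixed).

## Synthetic scenes

The simulator replaces hardware and human subjects. The pulse is a
Gaussian-modulated cosine at 4.3 GHz whose −10 dB power points sit at 3.1 and
5.3 GHz (σ = 0.2196 ns). Each scatterer contributes
reflectivity · p(τ − 10 ns − 2R(t)/c) per scan; white Gaussian fast-time noise
is added with a standard deviation of `noise_sigma` (default 0.2, relative to
a unit pulse peak) at the 64-pulse integration baseline, scaled down by the
rake gain at the configured PII. Narrowband interference is a fast-time
sinusoid with per-scan random phase and amplitude.

A living trunk is **two point scatterers**. The abdominal one carries the
full chest displacement — respiration and heartbeat sines with 6 mm and
0.3 mm amplitude (12 mm and 0.6 mm peak-to-peak, the excursions reported for
quiet breathing and the cardiac impulse; the ~20× ratio is what makes radar
HR estimation hard). The precordial one, offset 0.12 m in range with 0.6×
reflectivity, moves with 10 % of the respiratory excursion plus a pulsatile
cardiac impulse (fundamental + 0.2× second harmonic, normalized to 0.6 mm
peak-to-peak). This split is physiological — tidal excursion is largest at
the abdomen, while the apex beat is a localized, harmonic-rich impulse — and
it is also what makes cardiac extraction *possible in principle*: a purely
sinusoidal sub-millimetre heartbeat co-located with a centimetre breathing
motion violates the two-tone separability bound of envelope-based
decomposition (the low-frequency component dominates the derivative), so no
sifting scheme could recover it; real radar systems detect the heart because
precordial motion is localized and pulsatile.

Walkers shuttle along range at constant speed (triangular path) with two
counter-phase limb scatterers (±0.2 m at the stride rate) that produce
micro-Doppler sidebands. A fall is a raised-cosine radial transition of
1.3 m over ~1 s (peak speed ≥ 2 m/s) during which the reflectivity ramps to
4× by mid-fall — the torso turns broadside/prone during the descent — and
stays elevated through a post-fall immobile phase in which only the vitals
modulate the return. ADL (activities of daily living) streams are built from
one-minute scenes grouped into 12-minute behavioural episodes whose activity
profile (walking-speed centre, stride rate, sitting propensity) is drawn from
a continuum: a short observation samples few episodes of a person's
repertoire, a long one covers it, which is exactly why longer unsupervised
calibration helps fall detection.

What the generator does **not** model: multipath and wall penetration,
antenna patterns, RF front-end nonlinearity, non-stationary vital rates,
posture-dependent displacement direction, and multi-person occlusion. Passing
tests therefore demonstrate the correctness and self-consistency of the
processing chain under a physiologically plausible signal model, not field
performance on real subjects.

## Pre-processing

Fast-time filtering uses a 16th-order Butterworth bandpass over 3.1–5.3 GHz
(8th-order lowpass prototype, cascaded second-order sections), applied
forward–backward so the zero-phase response cannot bias range estimates; the
effective (squared) response is −30 dB at 230 MHz outside the passband.

Clutter removal zeroes leading singular values of the scan matrix. Three
selection modes are exposed: an explicit count, an energy fraction (smallest
count capturing ≥ the fraction, capped at 3), and the default *static* mode:
among the three leading components, those whose temporal singular vector
holds ≥ 60 % of its spectral energy below 0.1 Hz are removed. The static rule
exists because the other two fail on realistic scenes — with one dominant
reflector the energy rule removes a single component and leaves secondary
static structure (e.g. a body lying still after a fall) in the signal, while
a fixed count of 3 can swallow the respiratory oscillation itself. Constants,
steps and slow drift all live below the physiological band; breathing, gait
and cardiac modulation all live above it.

## Micro-Doppler and micro-motion signatures

Per range bin, the analytic slow-time signal (Hilbert transform) is cut into
16-scan frames with 50 % overlap (320 ms at 50 Hz; 3.125 Hz Doppler bins) and
transformed with orthonormal FFTs (rectangular window by default, Hann
optional), giving magnitudes over (frame, Doppler, range).

The subject distance d is the knee of the cumulative range-energy curve: the
point farthest from the chord between the curve's endpoints, computed on the
axis-normalized curve so the estimate is scale-free; ties break toward the
nearest range. The spectrogram is then gated by h(x−d) with
h(x) = 4(1+tanh x)/(2+tanh x)², which is 1 at the body, ~0 in front of it and
8/9 beyond it, and collapsed over a 9-frame window (1.6 s) into the
micro-motion signature: a 16-bin Doppler energy profile, the distance d, and
a scalar movement amplitude. The amplitude sums the profile *excluding* the
zero-Doppler bin: the breathing of a motionless body falls entirely inside
the 3.125 Hz central bin, and including it would make a high-reflectivity
prone body register sustained "movement"; excluding it makes the scalar a
genuine micro-motion measure that collapses during post-fall stillness. The
movement region D for the vitals stage is one stack segment (0.878 m) centred
on the latest d whose amplitude cleared the movement threshold.

## Vital-sign estimation

Range bins inside D are bandpassed along slow time (6th-order Butterworth,
0.125–3 Hz = 7.5 breaths/min to 180 beats/min, zero-phase) and decomposed by
empirical mode decomposition: natural cubic-spline envelopes through the
local extrema (mirror-extended at the ends), envelope-mean subtraction,
repeated until the intrinsic-mode conditions (|#extrema − #zero-crossings| ≤ 1
and envelope mean below 5 % of the envelope half-width) persist for 15
consecutive iterations — deep sifting is essential; under-sifted details mix
the cardiac mode into its neighbours. Decomposition stops at a monotone
residual or 12 modes. The sum of modes plus residue equals the input exactly
by construction.

Each mode gets the weight w = ‖pdf(s) − pdf(mode)‖₂ from histogram densities
on a shared support with bin width max{std(s_k)}/4 over the region's bins.
Along the mode index the weights rise over the noisy modes and fall to a
minimum at the modes carrying the cardiorespiratory signal; the selected set
is the descending run ending at the weight minimum (with a 15 % tolerance for
near-flat steps, since weights of low-energy modes are noisy) plus the run's
immediate shoulder — when no noisy prefix exists, the cardiac mode sits one
step above the respiratory minimum.

Rates come from zero-crossing mean frequencies, hardened in four ways that
synthetic calibration showed to be necessary and that are all physically
interpretable: (i) a **coherence gate** — a candidate counts only if ≥ 50 %
of the mode's spectral energy lies within ±35 % of its zero-crossing
frequency, which discards mode-mixed artefacts whose crossing rate sits
between their true components; (ii) **harmonic folding** — where the carrier
phase at a bin is near even symmetry the echo amplitude responds at twice the
motion frequency, so candidates with better-supported companions at half
their frequency are folded down, never across the RR/HR band edge; (iii) a
**dead band** around zero when counting crossings (0.4 σ for cardiac-band
modes, which cross steeply but carry in-band noise; 0.15 σ for
respiratory-band modes, whose genuine crossings are shallow); (iv) bins whose
slow-time standard deviation is below 10 % of the region maximum are dropped
(they carry no body return, and under the shared histogram bin width their
PDFs degenerate). Candidates are assigned to RR (0.125–0.7 Hz) or HR
(0.7–3 Hz) — the 0.7 Hz (42/min) split is a physiological choice exposed in
configuration — and each vital is the median across bins, preferring
candidates with coherence ≥ 0.75. A band with no candidate yields NaN plus a
missing flag; a movement flag marks windows whose amplitude renders the
cardiac estimate low-confidence.

With the default study conditions (resting subject at 1–3 m, default noise,
60 s windows) the chain recovers RR within ~0.5 breaths/min and HR within
~2–3 beats/min in the median over seeds; cardiac recovery degrades first as
movement or noise increase, as expected for the much smaller cardiac
displacement.

## Fall detection

Signatures are windowed (4 s, 1 s stride) into feature vectors: the
window-mean Doppler profile (16), amplitude max/mean/variance, the range
excursion, and the post-peak immobility fraction (stillness right after a
large amplitude peak is the hallmark of a fall as opposed to energetic ADL).
Features are standardized with statistics fitted on training data only, and
an RBF one-class SVM is fitted either on fall windows (supervised protocol:
train on one cohort, test on another) or on ADL-only windows (unsupervised
protocol: falls are anomalies; the realistic deployment). Scores are oriented
so larger = more fall-like in both modes; consecutive positive windows merge
into one event. ROC analysis sweeps the score threshold, reports the
trapezoidal AUC (equal to the positive-outranks-negative rank probability)
and the Youden-optimal operating point, which is also how the detector's
operating threshold and the ν/γ hyperparameters are chosen on a validation
split (ν = 0.05, γ = "scale" by default). Vital-sign accuracy against a
reference series is 1 − MRE with MRE the mean relative error.

Under the synthetic protocol (three seeds, 117 ADL-minutes each, threshold
from a validation split), the unsupervised detector flags ≥ 90 % of 30
scripted falls with ≤ 1 false event per 15 ADL-minutes, and the validation
AUC is non-decreasing in training duration (the episodic ADL model is what
produces this: longer observation covers more of the behavioural repertoire).

## Problem sizes and numerical conventions

Default analyses use the 0.5–2.5 m window (288 bins) for vitals and fall
corpora and the 0.5–5.5 m window (576 bins) for localization studies; vitals
windows are 60 s (3000 scans), fall scenes 25 s, recovery studies 20 seeds,
detection studies 3 seeds × 117 training minutes. Degenerate inputs are
handled explicitly: empty scenes render zeros; constant cumulative-energy
curves yield "no subject"; removing at least the full matrix rank in clutter
removal warns and returns zeros; series without two extrema pairs return a
pure residue; all-still signature sequences raise a no-movement error rather
than inventing a region.

## Known limitations

Whole-sequence SVD is an offline convention; streaming deployments should
re-estimate over sliding windows. Zero-crossing rates quantize to
1/(2·window) Hz, so short windows coarsen the rates. The RR/HR band split
misassigns rates outside 42–180 beats/min (bradycardia below 42 is read as
respiration). Only the nearest subject is analysed; simultaneous multi-person
vitals are out of scope. The fall-detection figures quantify the synthetic
protocol, not clinical performance.
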