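# Methods

## Signal model and assumptions

During a series of chest compressions the chest acceleration is
quasi-periodic: over a 2-s horizon it is well approximated by a harmonic
series at the compression rate. The algorithm therefore never integrates
the raw signal in time (which accumulates drift and normally requires a
force-sensor reference); it estimates the harmonic parameters of the
acceleration and converts them to displacement analytically, harmonic by
harmonic, using `s_k = −a_k/(2π f_k)²`. The price of this assumption is
that the output is the *average* compression signal of the window —
per-compression variations inside a window, and any non-periodic motion
(irregular compressions under rescuer fatigue, patient transport), degrade
the estimate. Chest recoil/leaning is invisible to a lone accelerometer
(the displacement reconstruction has no absolute reference) and is out of
scope, as is mattress compensation, which needs a second accelerometer.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_s` | 2.0 | s | feedback cadence; long enough for ≥2 cycles at 60 cpm, short enough for timely prompts |
| `power_threshold` | 0.34 | (m/s²)² | power of a 15 mm @ 100 cpm sinusoidal compression; rejects ~10 mm compressions (the known miss mode) while clinically relevant series pass by an order of magnitude |
| `rate_band_cpm` | (50, 200) | cpm | covers observed OHCA rates (≈57–182 cpm) with margin |
| `n_harmonics` | 4 | — | fundamental + 3 harmonics capture compression waveforms' sharp push without ringing |
| `n_fft` | 8192 | — | ≈0.031 Hz grid at 250 Hz; windows rarely hold integer cycles, so fine interpolation is needed before peak refinement |
| `subharmonic_ratio` | 0.5 | — | prefer `f/2` when its magnitude reaches half the dominant peak's: short-duty waveforms concentrate energy in the 2nd harmonic and would otherwise double the rate |
| `harmonic_tol_hz` | 0.15 | Hz | absorbs within-window rate drift when locating harmonic peaks |
| `noise_floor_ratio` | 0.01 | — | harmonics below 1% of the fundamental's amplitude are treated as absent |

The detection threshold is compared strictly (`P > θ`), and power is
computed after linear detrending so DC sensor offset and slow baseline
drift cannot trigger detections. A detected window whose in-band spectrum
is empty is demoted to no-compression with a logged warning.

## Fundamental and harmonic estimation

The coarse estimate is the largest magnitude peak of the Hann-tapered,
zero-padded FFT inside the rate band, refined by three-point parabolic
interpolation, followed by the subharmonic check. Two refinements beyond
plain peak readout proved necessary and are deliberate design choices:

* **Harmonic least-squares refinement of `f_cc`.** At 60 cpm a 2-s window
  spans only two cycles; the fundamental's and second harmonic's spectral
  mainlobes overlap, biasing the single-peak estimate by up to ~0.08 Hz
  (≈5 cpm). The refinement minimises the residual of a K-harmonic
  cosine-series regression (plus intercept/slope columns that absorb the
  window detrend) over a ±0.1 Hz bracket around the coarse peak, via
  bounded scalar minimisation. This is exact for noiseless harmonic
  signals and statistically efficient in noise, and its cost is fixed per
  window.
* **Amplitudes and phases by regression.** For the same reason a weak
  second harmonic can ride on the fundamental's spectral skirt without a
  local magnitude maximum of its own, so peak readout would report zero.
  The final amplitudes/phases come from the least-squares fit at the
  refined `f_cc`. A spectrum-only readout route (parabolic peak
  magnitude × taper gain; phase at the nearest bin corrected for the
  taper's window-centre delay) is retained for spectra without attached
  samples and agrees with the regression whenever harmonics are
  well-separated.

Reported phases refer to the window start and lie in (−π, π]. Harmonics
at or above Nyquist are truncated with a warning. Depth is read from the
synthesized 4-harmonic segment sampled at the input rate (exact to
sampling resolution); rate is exactly `60·f_cc`. Concatenation of
segments makes no attempt at phase continuity across window boundaries —
each window stands alone, and discontinuities at the seams are accepted.

## Integration oracle (tests only)

`oracle_double_integration` validates the spectral route independently:
cumulative trapezoidal integration to velocity and displacement with
*mean removal* at each stage. For a window holding an integer number of
sampled cycles, the means are exactly the unknown integration constants.
Line fits are avoided on purpose: a periodic signal sampled over [0, T)
has a non-zero least-squares slope (an edge effect), and subtracting it
injects cubic drift into the double integral; a cubic-polynomial detrend
over-corrects instead, absorbing part of a genuine sinusoid's amplitude.
Consequently the oracle is only meaningful on raw (un-detrended) periodic
windows, and oracle-based tests construct their inputs with
window-commensurate frequencies (multiples of 0.5 Hz for 2-s windows).

## Synthetic episode generator

Real OHCA recordings are not publicly available, so all end-to-end claims
rest on a generator whose ground truth is exact by construction:

* **Waveform.** Each compression cycle is a C¹ raised-cosine descent to
  −depth over `duty_cycle` of the period and a raised-cosine recoil back
  to −leaning. At duty 0.5 the cycle is a pure offset cosine (single-tone
  acceleration); a monotone phase warp (`harmonic_richness`) adds 2nd/3rd
  harmonic content without changing the excursion. Acceleration is the
  second-order central difference of the rendered displacement (O(dt²),
  negligible at 250 Hz) plus white Gaussian noise.
* **Episode structure.** Scenarios are ordered segments of compressions,
  pauses, and hands-off intervals; the latter carry Poisson-timed
  broadband spike bursts (Hann-enveloped white noise) emulating device
  handling. Depth decays multiplicatively per minute (fatigue) and the
  cycle-to-cycle rate jitters with a configurable sd.
* **The `paper-like` preset** draws per-series depth and rate from
  log-normal distributions with medians 41.6 mm and 110.3 cpm and
  interquartile spreads matching adult OHCA practice (clipped to the
  observed 15–95 mm / 57–182 cpm ranges), series of 20–40 s alternating
  with 6–14 s interruptions (≈3/4 compression time), duty cycles
  0.42–0.52, richness up to 0.3, 2%/min depth decay, 2 cpm rate jitter
  and 0.15 m/s² noise (compression SNR > 20 dB). Artifact bursts default
  to 2 m/s² × 0.12 s at 0.2 Hz — strong enough that coincident bursts
  occasionally trip the detector (the documented, clinically harmless
  false-positive mode) while isolated ones stay below threshold.
* All randomness flows from one `numpy` `default_rng(seed)`; a fixed seed
  reproduces episodes bitwise on any platform. A 16-bit quantization flag
  (±4 g full scale) is available and off by default, as the algorithm is
  resolution-agnostic.

What the generator does **not** emulate: non-linear, time-varying chest
stiffness; rescuer swaps with systematically different waveform shapes;
non-periodic motion during transport; mattress dynamics. Passing the
synthetic benchmark therefore demonstrates correctness of the method's
machinery under its stated quasi-periodicity assumption, not clinical
performance on arbitrary field data.

## Ground-truth labels and scoring

Per 2-s window, the gold standard (GS) depth is the mean depth of cycles
whose trough lies in the window and the GS rate is 60 over the mean
inter-trough interval of in-window troughs; a compression-labelled window
with fewer than two troughs falls back to the segment's programmed rate
(and, with no troughs, to the depths of overlapping/nearest cycles). A
window is labelled *compression* when at least half its span lies inside
a compressions segment. Reference-displacement event picking (for
evaluating against an external displacement signal) uses trough
prominence ≥ 7 mm with a 0.2 s refractory period (a 300 cpm cap);
prominence doubles as the event depth.

Windows that straddle a compression-series onset or offset have no clean
class: they contain genuine compressions over 10–50% of their span, whose
power rightly trips the detector, while the coverage rule labels them
no-compression. Interval-based annotation of real episodes scores only
cleanly labelled windows (with a comparable fraction of ambiguous time
set aside), so the synthetic benchmark excludes these transition windows
(~10% of all windows) from detector scoring; `annotate_windows` itself
keeps the plain coverage rule, and the per-window CLI comparison
(`cprfb evaluate`) scores everything it is given.

Detector reliability is summarised as sensitivity `100·TP/(TP+FN)` and
PPV `100·TP/(TP+FP)` (undefined ratios reported as absent, never 0).
Accuracy uses signed error = estimate − GS over true-positive windows;
unsigned percentiles use linear interpolation; Bland–Altman limits of
agreement are mean ± 1.96·sd with the population sd. Windows lacking a
defined GS rate are excluded from rate-error pairs. Episode-level quality
filtering (≥20 min, >1500 compressions, mean depth ≥30 mm) is provided
as `episode_inclusion`.

## Problem sizes

The default test suite and the acceptance script run the synthetic
benchmark at 30 episodes × 2 min (≈1 650 scored windows), the sinusoidal
recovery grid at 5 depths × 5 rates, and the oracle-equivalence suite at
120 random multi-harmonic windows; each completes in seconds on one CPU.
These sizes give stable medians and worst-case errors; scaling episodes
to 20 min changes none of the reported statistics beyond sampling noise,
since every window is processed independently.

## Known limitations

* Depth/rate are per-window averages; event-level (per-compression)
  metrics inside a window are out of reach of the method.
* The detector's power criterion makes detection of shallow compressions
  rate-dependent (power ∝ (depth·rate²)²): ~10 mm compressions at
  100 cpm are missed by design, while faster shallow series may pass.
* Noisy hands-off intervals can exceed the power threshold and produce
  false positives; no spectral-shape artifact rejection is attempted, as
  feedback during hands-off periods is clinically inconsequential.
* The published field-study error statistics (median unsigned errors of
  0.9 mm / 1.0 cpm on 75 OHCA episodes) cannot be recomputed here — the
  recordings are not public; the synthetic benchmark is a property-based
  analog, not a reproduction.
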