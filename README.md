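# cprfb — chest-compression quality feedback from a single accelerometer

During cardiopulmonary resuscitation (CPR), rescuers must deliver chest
compressions at the guideline depth and rate, and real-time feedback
measurably improves their performance. Most commercial feedback devices
derive chest displacement from a pad-mounted accelerometer but need an
extra force/pressure sensor to pin down the integration constants.
`cprfb` implements a feedback algorithm that needs **only the
acceleration signal**: it exploits the quasi-periodicity of chest motion
during a compression series and reconstructs the displacement spectrally,
so no running double integration (and no drift compensation hardware) is
required.

The package is for researchers and engineers working on resuscitation
monitoring: it provides the algorithm, a seeded synthetic generator of
out-of-hospital cardiac-arrest (OHCA)-like episodes with exact ground
truth, and the evaluation machinery used to characterise such detectors
(sensitivity/PPV, error percentiles, Bland–Altman agreement).

## Method

The acceleration stream `a(t)` (m/s², 250 Hz typical) is cut into
non-overlapping 2-s windows. Per window:

1. **Detection** — the window is linearly detrended and its power
   `P = mean(a²)` compared against a fixed threshold θ (default
   0.34 (m/s²)², the power of a 15 mm @ 100 cpm sinusoidal compression).
   `P ≤ θ` ⇒ *no-compression window*, no feedback, flat-line segment.
2. **Spectral estimation** — Hann-tapered, zero-padded FFT; the
   fundamental frequency `f_cc` is the dominant peak inside the
   physiologic band (50–200 cpm), refined by parabolic interpolation, a
   subharmonic check (guarding against rate doubling) and a harmonic
   least-squares fit. Amplitudes `a_k` and phases `φ_k` of the
   fundamental and the first three harmonics are estimated.
3. **Reconstruction** — each acceleration harmonic is double-integrated in
   closed form,

   `s(t) = Σₖ aₖ/(2π f_k)² · cos(2π f_k t + φₖ + π)` (mm, negative = downward),

   giving the periodic *average compression signal* of the window.
4. **Feedback values** — compression depth = peak-to-peak of `s(t)` in mm;
   compression rate = `60 · f_cc` in cpm. Concatenating the per-window
   segments reconstructs the episode's displacement for debriefing.

## Worked example

```bash
cprfb simulate --preset paper-like --duration 60 --seed 7 --out-prefix ep1
cprfb process ep1_accel.csv --out ep1_pred.csv --disp-out ep1_recon.csv
cprfb evaluate --pred ep1_pred.csv --gold ep1_gold.csv --report ep1_report.json
```

The `process` step prints `30 windows, 24 with compressions ->
ep1_pred.csv`: the 60-s episode splits into thirty 2-s windows, of which
24 carried detectable compressions. `ep1_pred.csv` holds one row per
window (`index,t_start,power,detected,depth_mm,rate_cpm`); a typical
detected row reads

```
4,8.000000,4.112890,1,44.338642,106.073338
```

i.e. window 4 (8–10 s) had power 4.11 (m/s²)² — well above θ — with an
estimated mean depth of 44.3 mm and rate of 106.1 cpm. `ep1_report.json`
compares every window against the simulator's ground truth; on this
episode the detector scores 100% sensitivity and 95.8% PPV (the single
"false positive" is a window straddling a series onset, whose real
partial compressions trip the detector while the ≥50%-coverage gold rule
labels it no-compression), with median unsigned errors of 0.19 mm and
0.15 cpm.

Python API equivalent:

```python
from cprfb import paper_like_scenario, generate_episode, process_episode

record, reference_disp, gold = generate_episode(paper_like_scenario(60.0, seed=7))
estimates, reconstruction = process_episode(record)
```

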