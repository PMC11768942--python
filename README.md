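# rppgtime

Timing correction and heart-rate estimation for irregularly sampled
remote-photoplethysmography (rPPG) signals.

## The problem

rPPG estimates the cardiac pulse from subtle skin-color changes in facial
video: the green-channel mean over a facial region of interest, tracked
across frames, carries a quasi-periodic blood-volume signal whose dominant
frequency is the heart rate. Spectrum-based HR estimation assumes samples on
a uniform time grid, but real capture pipelines — webcams on low-power or
edge devices in particular — deliver irregular frame intervals and dropped
frames. Frame loss in particular compresses the recorded sequence onto a
too-short time axis and shifts the apparent dominant frequency, biasing the
heart rate.

`rppgtime` is for signal-processing practitioners who need low-complexity,
O(n) timing correction in front of an FFT heart-rate reader, plus the
simulation machinery to quantify how much correction buys under controlled
corruption.

## What it implements

Given irregular capture timestamps s_1..s_n with values x(s_i) and a uniform
target grid t_1..t_n at the nominal rate (25 Hz, 40 ms period by default):

* **Linear interpolation** — x(t) = x(s_i) + (x(s_{i+1}) − x(s_i)) /
  (s_{i+1} − s_i) · (t − s_i) on each bracketing interval.
* **Natural cubic spline** — per-interval cubics a_i(t−s_i)³ + b_i(t−s_i)² +
  c_i(t−s_i) + d_i with C¹/C² continuity at the knots and zero second
  derivative at both ends.
* **CIC filter interpolation** — a multiplier-free cascaded integrator–comb
  multirate filter (defaults R = 10, N = 4, M = 2): samples are placed on a
  zero-stuffed lattice at R× the grid rate, pass N cascaded integrators, are
  decimated onto the grid with the group delay N(RM−1)/2 compensated, and
  pass N cascaded combs of delay M. An occupancy channel filtered by the
  same cascade normalizes the output, cancelling the (RM)^N/R gain and
  re-weighting partially filled windows. The unnormalized impulse response
  is the N-fold convolution of a length-RM boxcar.
* **HR read-out** — mean-removed, un-windowed FFT of the 750-sample window;
  the heart rate is 60 × the frequency of the largest magnitude inside the
  resting band 0.8–1.8 Hz (2 bpm resolution at 25 Hz / 750 samples).
* **Corruption models and Monte-Carlo benchmarks** — truncated-Gaussian
  timing jitter (σ = one period, clipped at one period) on a chosen fraction
  of capture instants, uniform random loss of k samples, and the
  reconstruction-RMSE and HR-RMSE/MAE experiments over grids of corruption
  levels (1000 trials per condition by default).

## Worked example

```python
import rppgtime as rt

# 30 s pulse-like recording at a nominal 25 Hz, true rate 72 bpm
dense = rt.generate_rppg_like(duration_s=30.0, hr_bpm=72.0, seed=11)
grid = rt.UniformGrid(0.0, 25.0, 750)
clean = rt.sample_regular(dense, grid)

# drop 40 of the 750 frames at random
lossy = rt.apply_sample_loss(clean, rt.LossSpec(loss_count=40, seed=12))

for method in ("none", "linear", "cubic", "cic"):
    res = rt.estimate_hr_from_series(lossy, method, grid)
    print(f"{method:>6}: {res.hr_bpm:5.1f} bpm  (peak {res.f_peak_hz:.4f} Hz)")
```

prints

```
  none:  76.1 bpm  (peak 1.2676 Hz)
linear:  72.0 bpm  (peak 1.2000 Hz)
 cubic:  72.0 bpm  (peak 1.2000 Hz)
   cic:  72.0 bpm  (peak 1.2000 Hz)
```

Without correction the 40 lost frames shift the dominant frequency upward by
about 5% (750/710), so the uncorrected estimate reads 76.1 bpm; all three
interpolators restore the true 72.0 bpm. The same objects drive the
reconstruction metric directly:
`rt.rmse(rt.reconstruct(lossy, grid, "cubic"), clean.values)` → `0.05`.

The identical chain is available from the shell:

```bash
rppgtime simulate --kind rppg --hr-bpm 72 --seed 11 --out clean.csv
rppgtime corrupt --in clean.csv --loss 40 --seed 12 --out lossy.csv
rppgtime hr --in lossy.csv --method cubic --count 750
```

`bench-recon` and `bench-hr` run the Monte-Carlo experiments from a flat
`key = value` config file and write mean/std metric tables as CSV.

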