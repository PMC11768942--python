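# Methods

## Signal model and study conditions

The continuous cardiac waveform is represented on a dense 1 kHz lattice
(`DenseSignal`); all "continuous-time" operations — ideal capture, biased
capture — are index lookups on that lattice, so biased capture instants are
quantized to 1 ms. This matches the fidelity at which the benchmarks are
defined and keeps the corruption models waveform-agnostic.

Two generators produce test material:

* `generate_sinusoid` — amplitude-√2 (unit mean power) sinusoid with
  frequency uniform in the resting band 0.8–1.8 Hz and phase uniform in
  [0, 2π), 30 s by default. This is the reconstruction-benchmark signal;
  unit power makes raw RMSE directly interpretable as a fraction of signal
  scale.
* `generate_rppg_like` — a pulse-like stand-in for a real green-channel
  trace: unit fundamental at hr_bpm/60 Hz, a second harmonic at 0.4 of the
  fundamental (the dicrotic component of a PPG pulse), white noise with
  σ = 0.15, and a 0.1 Hz baseline wander of amplitude 0.5 (respiration-scale
  drift). The defaults keep the band-limited spectral peak at the
  fundamental, so the true heart rate is known by construction. These
  levels are a plausible resting, artifact-free recording; what the
  generator deliberately does not emulate is motion artifacts, illumination
  changes, skin-tone effects, or non-stationary heart rate — conclusions
  drawn from it speak to timing defects only, not to those confounds.

Corruption models:

* **Timing jitter** (`apply_timing_jitter`): a uniformly chosen fraction of
  capture instants receives a bias b ~ N(0, σ²) with σ equal to the nominal
  period (40 ms at 25 Hz) and |b| clipped to one period. Clipping (rather
  than rejection resampling) is the simplest reading of a hard bias bound.
  The biased instant is quantized to the lattice; the logged timestamp
  records that biased instant, i.e. correction knows the true capture times,
  as a capture pipeline that logs frame timestamps does. Jittered samples
  may swap order only locally (bias ≤ one period); output is re-sorted,
  stable on the original capture index.
* **Sample loss** (`apply_sample_loss`): k indices dropped uniformly at
  random without replacement, endpoints included; surviving pairs keep their
  order. Bursty/correlated loss is out of scope.

## Interpolators

**Linear** follows the two-point formula on each bracketing interval
(`np.interp` underneath). **Cubic** is the natural cubic spline — the
boundary condition chosen where several are defensible, because it adds no
assumption beyond vanishing end curvature; fitting is delegated to
`scipy.interpolate.CubicSpline(bc_type="natural")` and re-expressed as
per-interval (a, b, c, d) coefficients, which the test suite verifies
against an independent dense solve of the full (4n−4)-equation system.
Duplicate timestamps are collapsed by value-averaging (unbiased,
order-independent) to keep the system nonsingular; with fewer than three
distinct points the fit degrades to the linear interpolant with a warning.
All methods clamp to the nearest endpoint value outside the sampled span —
the only reachable extrapolation case is a lossy record end.

**CIC.** The cascaded integrator–comb interpolator operates in the
nominal-rate clock domain at f_hi = R × grid rate:

1. each input sample lands in the nearest high-rate slot (collisions
   averaged — unbiased and order-independent), all other slots zero;
2. an occupancy indicator (1 where a sample landed) is built on the same
   lattice;
3. both channels pass N cascaded integrators, are decimated onto the slots
   nearest the grid timestamps shifted by the group delay N(RM−1)/2 (the
   half-sample residual when N(RM−1) is odd is absorbed by slot rounding),
   and pass N cascaded combs of delay M (in low-rate samples);
4. the output is filtered-signal / filtered-occupancy wherever the
   occupancy response is positive; windows containing no sample are filled
   from the nearest valid output with a warning.

On a fully occupied regular lattice this reduces to the textbook zero-stuffed
CIC interpolator, whose unnormalized response is the N-fold convolution of a
length-RM boxcar; the occupancy normalization cancels the (RM)^N/R gain
exactly (DC is preserved to machine precision) and re-weights edge and
partially filled windows, which is what lets the filter degrade gracefully
under loss. How a CIC structure should treat non-uniform input is not
standardized; this slot-assignment + occupancy-normalization scheme is this
package's design choice, documented as such.

*Numerics.* The integrator cascade grows like n^N, so running it in floating
point loses ~6 significant digits at N = 4 over a 30 s window. The cascade
is therefore run in 64-bit integer arithmetic with two's-complement
wraparound — the classic multiplier-free hardware arrangement, exact as long
as the final comb output fits in 64 bits — with input values quantized to 45
bits of headroom (relative quantization error ~3·10⁻¹⁴; configurations whose
gain would overflow are rejected). This is what lets the implementation meet
1e−9-level equivalence with the boxcar-cascade oracle.

The defaults R = 10, N = 4, M = 2 give a passband droop
|sin(πfRM/f_hi) / (RM·sin(πf/f_hi))|^N ≈ 0.94 at 1.2 Hz, i.e. an
irreducible reconstruction RMSE of ≈ 0.06 on the unit-power test sinusoid
even without corruption (`cic_passband_gain` computes this bound). That
floor is visible throughout the benchmarks and is the accuracy price of the
multiplier-free structure.

## Heart-rate estimation

The spectrum is the un-windowed FFT of the mean-removed analysis window —
no taper, no zero padding, no detrending beyond mean removal — giving
1/30 Hz (2 bpm) bins at 750 samples / 25 Hz. The heart rate is 60× the
band-restricted argmax frequency, ties broken toward the lower frequency
(an arbitrary but fixed rule). The 0.8–1.8 Hz default band nominally covers
resting rates ("50–100 bpm"; strictly 48–108 bpm — the bpm gloss is
approximate, the band in Hz is what is implemented).

The uncorrected baseline (`method="none"`) treats the recorded values as
uniform at the *nominal* rate, ignoring timestamps. This choice is what
reproduces the loss-degradation mechanism: k lost samples compress the
sequence so the dominant frequency reads high by a factor ≈ n/(n−k). Using
the empirical mean rate instead would hide exactly the error the correction
methods exist to fix.

`green_channel_mean` is the video front end: the arithmetic mean of the
green channel over a caller-supplied fractional ROI (face detection and skin
segmentation are out of scope; the ROI is an input). The caller declares the
channel order, defaulting to blue-green-red as common video decoders emit.

## Monte-Carlo protocol

Reconstruction experiment: per trial a fresh sinusoid (new f, φ — both
redrawn every trial) is sampled regularly (750 samples) as the reference,
corrupted (k losses, or jitter on a fraction r of instants), and each method
is scored against the reference on the same corrupted realization (paired
comparison). The uncorrected score compares the surviving sequence
index-by-index against the reference's leading samples, consistent with the
nominal-rate reading above. RMSE is reported in raw units of the unit-power
signal; a normalize-by-amplitude switch exists because "error as a fraction
of amplitude" is the other defensible convention.

HR experiment: a fixed pulse-like source (or several, mirroring a
multi-subject recording session) is captured at the nominal rate; per trial
k samples are dropped independently per source, each method estimates the
heart rate over the 30 s window, and the per-trial RMSE/MAE are taken across
sources (with a single source both reduce to the absolute error). Means and
standard deviations aggregate across 1000 trials per loss count. At zero
loss every trial is identical, so the standard deviation is exactly zero —
a structural property, not a numerical accident.

Per-trial seeds derive from `SeedSequence([master_seed, experiment,
condition_index, trial])`, so conditions are independent, individually
re-runnable, and the whole table is bit-reproducible for a fixed master
seed.

Problem sizes: the shipped benchmarks and the acceptance script use the full
protocol scale — 1000 trials per condition, 30 s windows — which completes
in well under a minute per experiment on one core; unit tests use smaller
grids where the property under test does not depend on scale.

## Known limitations

* The benchmark signal is a single stationary sinusoid; multi-component or
  frequency-modulated signals would show different (generally larger) CIC
  droop effects.
* The uncorrected-baseline reconstruction RMSE saturates near √2 once the
  lost-sample phase ramp decorrelates the sequences (by k ≈ 10 at these
  settings); comparisons between heavy-loss conditions therefore sit on a
  plateau where ordering is dominated by an oscillating sinc term rather
  than by a monotone trend.
* CIC accuracy depends on R: larger R reduces slot-quantization error of
  irregular timestamps but increases passband droop for fixed M; the
  defaults balance the two for the resting band at 25 Hz.
* Real-data ingestion is limited to timestamp/value CSV; no video decoding
  is shipped (the green-channel front end consumes in-memory frames).
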