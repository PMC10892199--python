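# Methods

## Signal model

Each channel of a K-electrode array is modelled as

    g_i(t) = a_i · f(t − d_i) + η_i(t),

where f is the shared cardiac signal, a_i a dimensionless gain, d_i an
integer-sample propagation delay, and η_i iid zero-mean Gaussian noise of
standard deviation σ_i (instrumentation noise, assumed unrelated across
channels and to f). The ensemble average ḡ = (1/K)Σg_i then has
E[ḡ] = f and, for equal σ, sd(ḡ_noise) = σ/√K — a 10·log₁₀K dB power-SNR
gain. Note the sd law is σ/√K (variance σ²/K); the 9.03 dB figure for
K = 8 follows only from the √K reading, which is what the package
implements and tests.

The averager deliberately performs no software re-alignment: the method
under study relies on electrode proximity keeping channels in phase, and
quantifying what misalignment costs is one of the package's experiments.

## Synthetic ECG generator

One cardiac cycle is a sum of five Gaussian bumps (P, Q, R, S, T) on a
180-sample grid (720 ms at the default 250 Hz). Defaults, as
(relative amplitude, center sample, σ samples):

| wave | amp   | center | σ   |
|------|-------|--------|-----|
| P    | 0.15  | 58     | 5   |
| Q    | −0.10 | 84     | 2   |
| R    | 1.00  | 90     | 1.5 |
| S    | −0.20 | 96     | 2   |
| T    | 0.30  | 130    | 10  |

This gives a ~80 ms P wave, an ~80–100 ms QRS span with a sharp (≈6 ms σ)
R spike, and a ~160 ms T wave; the template is rescaled so its maximum is
exactly the requested R amplitude (1000 μV chest-like by default; mastoid
and upper-arm presets use 40 and 60 μV, midpoints of the published
ranges). The narrow R spike matters: it is what makes the measured
ensemble gain collapse to ~2–3 dB under a cumulative one-sample
(2°-per-channel) misalignment, the phase-sensitivity regime the method's
feasibility depends on.

Beat-to-beat variability: each cycle is linearly resampled to a length
drawn uniformly in ±`rr_jitter` of nominal. The resampling is done in two
segments, before and after the R apex, so the apex always falls exactly
on an output sample; otherwise odd cycle lengths put the apex midway
between two samples and the returned ground-truth R index would be
ambiguous at the sample level (any detector then errs ±1 sample by coin
flip under noise). Ground-truth R indices are the argmax of each rendered
cycle and are returned with the signal.

Channel delays are integer-sample shifts with edge replication (a
physical delay does not wrap within a recording); a one-sample shift on a
180-sample cycle equals 2° of cardiac phase. All stochastic operations
require an explicit integer seed and are bit-reproducible;
omitting the seed where noise or jitter is requested is an error.

What the generator does *not* emulate: EMG and motion artifacts, baseline
wander, electrode impedance drift, waveform morphology change with heart
rate, or arrhythmias. Passing tests therefore demonstrate the averaging
law and pipeline correctness under the stated noise model, not clinical
robustness.

## Peak-to-peak SNR

SNR = 20·log₁₀(QRS_pp / noise_pp): QRS_pp is max−min over a 120 ms window
centered on the R apex; noise_pp is max−min over a 40 ms window. The noise
window is placed midway in the isoelectric T-P segment (between T end and
the next P onset) — placing it inside the R-T interval would measure the
T wave rather than noise. Over multi-beat recordings the per-beat median
is reported (robust to one corrupted beat). A noise Vpp at floating-point
dust level (≤10⁻⁹ of the QRS Vpp) is flagged as the infinite-SNR
zero-noise case.

The noise σ used in the simulation experiments is calibrated
analytically: the expected Vpp of n iid N(0, σ²) samples is σ·E[range_n],
with E[range_n] = ∫(1 − Φⁿ(x) − (1−Φ(x))ⁿ)dx evaluated by quadrature.
Solving 20·log₁₀(QRS_pp/(σ·E[range₁₁])) = 12 dB for the default template
gives σ ≈ 95 μV — a single channel whose P and T waves are visibly
disturbed, the regime the averaging method targets. The same identity
calibrates the shorted-input noise channels so each channel's expected
10 s Vpp matches its bench value (1.4, 1.5, 1.7, 1.2, 1.5, 1.25, 1.1,
1.2 μV).

## R-peak detection and heart rate

The detector is a Pan–Tompkins-style envelope method: zero-phase 5–30 Hz
band-pass, derivative, squaring, 120 ms moving-window integration;
candidate envelope peaks (250 ms refractory) are screened by a running
signal/noise-level threshold (EMA weights 0.125, threshold = noise +
0.25·(signal − noise)) and refined to the raw-signal argmax within
±100 ms. On noiseless synthetic recordings recovery is exact; under the
12 dB single-channel operating point, beat recall and precision exceed
0.99.

Heart rate is 60·fs/ΔR bpm per beat pair. To compare two recordings,
beats are greedily matched by nearest R time within ±150 ms (below half
the refractory period, so no double matching), rate is computed between
successive matched beats in each recording, and the paired series are
Pearson-correlated; unmatched beats are dropped and counted.

## Zero-phase filter chain

Stages at fs = 250 Hz: IIR notches at 50 and 100 Hz (Q = 30), 4th-order
Butterworth low-pass at 100 Hz, 2nd-order Butterworth high-pass at
0.1 Hz. Families, orders and Q are package defaults chosen to meet the
stated corner frequencies; the 100 Hz corner sits near Nyquist, so the
100 Hz notch and the low-pass overlap by design. Each stage runs once in
each time direction (`sosfiltfilt`), giving the squared magnitude
response and zero net phase; direction order is immaterial for LTI
stages.

Edge handling is load-bearing: the 0.1 Hz high-pass settles over several
seconds, and with scipy's default short odd-reflection padding its edge
ringing reaches well into a 20 s record (a pure 50 Hz tone leaves a ~2–7%
mid-record residual). The chain therefore uses even-reflection padding of
min(len−2, 2 s), which brings the mid-record 50 Hz residual to ~3·10⁻⁴
while preserving the zero-lag and unity-passband contracts. Filter-chain
measurements in the tests discard 2 s of settling at each record end.
Signals shorter than the minimum padding raise an explicit length error.

The analog front end ahead of the ADC is modelled as a first-order RC
high-pass H(s) = s/(s + 2πfc), fc = 0.15 Hz; its phase arctan(fc/f) under
±1% component tolerance differs across channels by < 2° for f ≥ 1 Hz,
which is the channel-matching budget of the averaging method.

## Packet codec and ADC scaling

A packet is 26 bytes: header (default 0xAA), eight 24-bit big-endian
two's-complement ADC codes in channel order, tail (default 0x55); header,
tail and byte order are configurable because the real device's values are
unpublished. The stream decoder resynchronizes by advancing one byte on a
framing violation, counts garbage runs and dropped bytes, and is
prefix-stable. Code-to-voltage conversion uses
μV = code·(2·V_ref/G)/2²⁴·10⁶ with defaults V_ref = 4.5 V, PGA gain 12
(one LSB ≈ 0.0447 μV input-referred). At 250 packets/s and 10 bits/byte
(8-N-1 framing) the link load is 65,000 bps, under the 115,200 bps baud —
asserted as an analytic check.

## Reference experiments and problem sizes

All experiments run from single integer seeds; child seeds are drawn from
a `numpy` Generator so replicates are independent but reproducible.

- **Aligned / misaligned SNR gain** — 4-cycle, 180-sample/cycle, 1000 μV
  recordings; 8 channels at the 12 dB single-channel operating point; 100
  replicates; per-replicate improvement = median-over-beats SNR(average)
  − SNR(channel 1), using ground-truth beat windows; the median over
  replicates is reported. Aligned: ≈ 8.8 dB (theory 9.03, bracketed in
  [6, 10]); with 1-sample-per-channel delays: ≈ 2.7 dB (≤ 3).
- **Averaged shorted-input noise** — 8 channels calibrated to the bench
  Vpp values over 10 s at 250 Hz, 100 replicates; the 95th percentile of
  the average's Vpp (≈ 0.53 μV) is compared against the 0.65 μV bound.
- **Heart-rate correlation** — one 60-beat, 5%-jitter RR process rendered
  into two independent 8-channel recordings at the 12 dB operating point;
  each is averaged and R-detected independently; Pearson r of the matched
  rate series ≥ 0.99.

These sizes complete in seconds on one core; they are the package's
chosen desk-scale operating points, not hardware measurements. The real
devices' on-body SNR figures (≈ 21–23 dB behind the ear and on the arm)
require real recordings and are out of scope.

## Known limitations

- The Gaussian-bump template is a morphological stand-in, not a
  biophysical model; absolute SNR values depend on its wave widths
  (especially the R spike) and transfer only qualitatively to real skin
  recordings.
- The noise model is white and stationary; correlated interference
  (power-line common mode, EMG bursts) defeats plain averaging
  differently and is not simulated.
- The system gain inferred from different bench quantities (PGA setting,
  differential gain, plateau frequency-response gain) need not agree;
  gain is treated as a per-dataset parameter throughout.
- WFDB export is not provided; recordings interchange as CSV.
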