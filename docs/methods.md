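# Methods

## Generative picture

All analyses assume each scalp channel is a superposition of three terms:
neuronally *delayed* copies of shared source signals, an *instantaneous*
field component (volume conduction propagates at effectively infinite
speed), and additive sensor noise. Only the delayed term carries latency
information; the instantaneous term is what makes every channel pair
correlate at lag zero, and the analysis has to separate the two through
the lag dependence of the correlation.

Delays of tens to hundreds of milliseconds between scalp sites a few
centimetres apart cannot be straight-line axonal conduction (30–70 m/s
would give sub-millisecond transits); they correspond to polysynaptic
loops or slow intracortical traveling waves (~0.1–1 m/s effective
velocity). The synthetic generator therefore uses slow effective
velocities for correlation-scale fixtures and the 30–70 m/s axonal range
for triangulation-scale fixtures; both express delay = distance / velocity.

## Lagged correlation

`lagged_correlation` is the product-moment coefficient of the aligned
pairs (p_i, q_{i+Δ}) over the full overlap, with the means and variances
taken over the same aligned segments. Key numerical and contract choices:

- Lags must be whole sample shifts at the working rate (tolerance 1e-6 of
  a sample). No fractional-lag interpolation: the intended pipeline
  records at 1 kHz and downsamples to 100 Hz, so the default grid
  (10…500 ms) is exactly 1…50 samples. Negative lags are expressed by
  swapping the pair order, never by a signed Δ.
- A constant aligned segment makes the coefficient undefined; this raises
  `UndefinedCorrelationError` (full-record form) or yields NaN (windowed
  form) — never a silent 0, which would bias epoch statistics.
- Windowed curves use cumulative-sum window aggregation (O(n · lags)).
  Variances are clipped at zero against float cancellation and windows
  with variance ≤ 1e-12 of the signal scale are marked missing. Window w
  at lag Δ pairs p_i inside the window with q_{i+Δ}, which may extend
  past the window's end; only windows whose largest lag still finds
  samples are emitted.
- Downsampling applies a zero-phase 8th-order Butterworth low-pass at
  0.4 × target rate before decimation. Zero phase matters: a causal
  filter's group delay would shift every channel equally but interact
  with the lag quantisation, corrupting latency estimates.

`latency_at_threshold` returns the *largest* grid lag with r ≥ 0.7. The
alternative reading (first downward crossing) would make a pair that
stays above threshold through 460 ms report 10 ms; the
largest-qualifying-lag reading matches how long-range coherent pairs are
summarised.

## Directionality

The index is the symmetric relative difference
2 |a − b| / (a + b) × 100 %, maximised over the lag grid, where
a = r_pq(Δ) and b = r_qp(Δ). Design choices:

- **Admissibility filter.** The ratio is unstable as a + b → 0. Lags with
  either coefficient ≤ 0 or a + b ≤ 0.05 are excluded; if no lag is
  admissible the result is an error, not a number. The 0.05 floor means
  the sampling noise of r must be well below ~0.02 for the index to be
  reliable — at 100 Hz that needs records of a few minutes, which is why
  the recovery fixtures use 120 s records (the method's intended regime
  is full-length recordings, not snippets).
- **Ties** break toward the smallest lag (shortest physiological path);
  a perfectly symmetric pair reports 0 % with the locked channel as
  source by convention.
- The index approaches 200 % for a fully one-way pair, because then
  |a − b| → a + b. Values of a few percent indicate weak asymmetry.
- No significance test is attached: the sampling distribution under
  dependence between a and b is not specified here, and the null
  simulations in the test suite serve as the calibration (under
  independent channels, values above 20 % occur in < 5 % of runs).

## Epochs

The qualitative phenomenon — spans where short latencies (10–70 ms)
dominate alternating with spans where long latencies (200–500 ms)
strengthen, on a cycle of roughly 280 ms — is operationalised as:

1. per-window mean r over each band (band edges 10–70 / 200–500 ms);
2. when several pairs are analysed, band series are averaged across
   pairs (missing windows are averaged over the pairs that define them);
3. the state is the sign of (short − long); maximal runs form epochs;
   runs shorter than 50 ms merge into the preceding epoch (debounce,
   suppressing single-window flicker at the 10 ms step while staying
   well below half of a ~280 ms cycle);
4. the alternation period is twice the mean epoch duration (equivalently
   the mean duration of one short+long cycle).

**Window length.** Resolving a cycle C requires an analysis window
shorter than the half-cycle; the default 500 ms display window averages
over ~2 cycles and flattens the alternation entirely. Epoch analyses in
the tests use 80 ms windows (8 samples at 100 Hz) — short enough to
resolve a 200 ms cycle, long enough that the per-window coefficient is
usable once averaged across pairs. Epoch boundaries are consequently
blurred by up to one window length around the true switch times.

## Triangulation

- `triangulate_absolute` solves the sphere-intersection least squares
  |x − e_k| = v t_k with a linearised seed (subtracting sphere equations
  is linear in x; the out-of-plane component is restored from sphere 0)
  refined by Levenberg–Marquardt from both mirror seeds. For planar
  arrays the two mirror solutions are exact duplicates in residual; the
  `depth_sign` argument ("below" by default) picks the one on the
  requested side of the array plane, encoding that sources lie beneath
  the scalp.
- `triangulate_tdoa` fits transit-time *differences* against electrode 0
  (≥ 4 electrodes for 3 unknowns) with five deterministic starts at the
  array centroid, 10/30/50/70/90 mm beneath the array plane — multistart
  without randomness keeps results reproducible bit for bit.
- Degenerate inputs (collinear or duplicated electrodes) raise
  `DegenerateGeometryError` rather than returning an unconstrained fit.
  Residuals are RMS timing misfits in ms.
- Units: mm for positions, ms for times, m/s for velocity — numerically
  convenient since 1 mm/ms = 1 m/s.
- The worked reference geometry (source 50 mm beneath a 10 mm-pitch grid)
  uses v = 70 m/s, which reproduces the canonical transit-time
  differences of 0.3 ms (electrode five pitches along x) and 0.1 ms
  (electrode two diagonal pitches away, i.e. at (20, 20, 0) mm). The
  alternative diagonal placement at (14.14, 14.14, 0) would give 0.08 ms
  and is not used.

## Synthetic generator

`generate_recording` realises the generative picture geometrically:
delays are distance/velocity (+ synaptic terms), rounded to the nearest
sample at the generation rate (default 1 kHz), and the analysis pipeline
then downsamples to 100 Hz — so lag quantisation is exercised end to end.
Waveforms (unit variance, scaled by an amplitude in µV):

- `alpha_like` — 10 Hz sinusoid with a slow random phase walk;
- `bandlimited_noise` — white noise low-passed at 40 Hz (zero phase);
- `broadband_noise` — Gaussian-smoothed white noise (default σ = 5 ms),
  whose narrow, non-ringing autocorrelation makes single-lag recovery
  fixtures sharp;
- `ictal_spike_train` — periodic biphasic spikes, configurable up to
  200 Hz.

Noise is Gaussian and independent across channels; correlated background
is modelled only through the instantaneous gain. Everything is
deterministic given the seed (bit-identical repeats).

**Alternating regimes.** `generate_alternating` drives, per channel pair,
two independent `broadband_noise` sources: a fast pathway with branch
delays {10, 30, 50} ms and a slow pathway with branch delays
{250, 300, 400} ms, each branch scaled 1/√3 so a pathway delivers unit
power. A square-wave schedule with half-period C/2 multiplexes which
pathway its source feeds, and the gate applies at the *source* time:
the correlation observed at a matched lag Δ then rises and falls in phase
with the schedule for any cycle length. (Gating at the receiving
channel's emission time instead would shift the long-band response by
Δ mod C — for C = 200 ms and Δ = 300 ms exactly onto the opposite
regime, cancelling the band difference.) Three branch delays per pathway
put three of the five grid lags of each band on a matched delay, lifting
the band-mean modulation well above the per-window estimation noise.
Defaults: 24 pairs (averaged at analysis time, comparable to a
few-dozen-channel montage), 30 s records, SNR 5 per source, cycle 280 ms.

## What the synthetic data do and do not show

Passing the recovery tests shows the estimators are consistent under
their own generative assumptions: stationary (or square-wave-switched)
linear delayed superposition, Gaussian independent noise, exact
sample-aligned delays. Real EEG adds nonstationarity, correlated
background across channels, reference-electrode coupling, volume
conduction with distance-dependent attenuation, and delay *distributions*
rather than discrete pathway delays. None of those are claimed to be
covered; in particular the recovery rates measured here (e.g. ≥ 95/100
source assignments) are properties of the synthetic conditions, not
clinical performance figures.

## Problem sizes used in the tests

Recovery simulations are scaled to keep the full suite inside a few
minutes while preserving the operating regime of each statistic:
correlation/directionality fixtures use 100–120 s records at 1 kHz
(downsampled to 100 Hz), alternation fixtures 30 s × 24 pairs, and the
triangulation round trip 100 random sources at depths of 10–80 mm under
a 4 × 4 grid. Full-length (~9 min) recordings only tighten the sampling
noise further.

## Known limitations

- The windowed engine assumes a uniform window step when reconstructing
  epoch boundaries (the median step is used).
- EDF output quantises to 16 bits; data are exact only when
  integer-valued within ±32767 µV (1 µV resolution), otherwise accurate
  to half a digital step of the channel's range.
- `segment_epochs` carries the last defined state across missing
  windows; leading missing windows are dropped from the analysed span.
- The directionality index has no attached inferential model; treat the
  percentage as a descriptive asymmetry measure.
- With ≤ 4 electrodes, TDOA depth estimates are ill-conditioned near the
  array's symmetry axis (all differences ≈ 0); use absolute times or a
  larger aperture there.
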