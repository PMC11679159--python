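# lagfoci

Latency-correlation analysis of multichannel EEG: windowed lagged
Bravais–Pearson correlation, a directionality index that labels the likely
source channel of a pair, segmentation of alternating correlation regimes,
and transit-time triangulation of a putative focus.

## The problem

Localising an epileptogenic focus from EEG/ECoG usually means solving an
inverse dipole-field problem, which is ill-posed at clinical electrode
counts. An alternative signal of location survives in the *timing* of the
recordings: if part of each channel is a neuronally propagated (hence
delayed) copy of shared source activity — superposed with an instantaneous
volume-conduction component and noise — then lagged correlations between
channel pairs carry usable latency structure, and transit-time differences
between electrodes can in principle be triangulated back to a source.

`lagfoci` implements that analysis chain for multichannel recordings
(EDF, BrainVision, or a plain delimited text dialect), together with a
synthetic propagated-EEG generator so that every stage has a ground-truth
recovery test without any recorded data.

## The statistics

**Lagged correlation.** For a locked channel *p*, a delayed channel *q* and
a latency Δ on a preset grid (default 10, 20, 30, 50, 70, 100, 200, 250,
300, 400, 500 ms, realised as whole sample shifts at the 100 Hz working
rate):

    r_pq(Δ) = Σ (p_i − p̄)(q_{i+Δ} − q̄)  /  √[ Σ (p_i − p̄)² · Σ (q_{i+Δ} − q̄)² ]

computed over the full overlap, or in sliding windows (default 500 ms
window, 10 ms step) for time-resolved curves. `latency_at_threshold`
reports the largest grid lag with r ≥ 0.7 (0 if none).

**Directionality.** With a = r_pq(Δ) (q delayed) and b = r_qp(Δ) (p
delayed),

    directionality [%] = max_Δ  2 |a − b| / (a + b) × 100,

maximised over lags where both coefficients are positive and a + b > 0.05.
If a > b at the maximising lag, *p* leads and is the inferred source. A
fully one-way pair approaches the 200 % ceiling; weakly asymmetric real
EEG pairs sit at a few percent.

**Epochs.** Mean windowed r over a short latency band (10–70 ms) versus a
long band (200–500 ms); the sign of their difference defines the dominant
regime, debounced runs of one sign form epochs, and the alternation period
is twice the mean epoch duration.

**Triangulation.** A source at x reaches electrode e_k after
t_k = |x − e_k| / v (velocity v = 30–70 m/s, optional synaptic delays);
the inverse solvers find x by least squares from absolute transit times
(≥ 3 electrodes, mirror ambiguity resolved toward sources beneath the
array) or from time differences against a reference electrode
(≥ 4 electrodes, deterministic multistart). Analytic design relations
(`spatial_resolution`, `required_sampling`, `min_loop_frequency`,
`loop_time`) expose the temporal-resolution requirements behind the method.

## Worked example

```python
import lagfoci as lf

# B repeats A after 30 ms (slow effective propagation: 30 mm at 1 m/s),
# plus an instantaneous field component and noise at SNR 5
cfg = lf.SynthConfig(
    channels=lf.ElectrodeArray(["A", "B"], [[0, 0, 0], [30, 0, 0]]),
    sources=[lf.SourceSpec(position=(0, 0, 0), waveform="bandlimited_noise")],
    duration_s=100.0,
    model=lf.PropagationModel(velocity=1.0),
    instantaneous_gain=0.5,
    noise_sd_uv=10.0,
    seed=1,
)
rec, truth = lf.generate_recording(cfg)
rec = lf.downsample(rec, 100.0)

curve = lf.correlation_curve(rec, "A", "B")
for lag, r in zip(curve.lags_ms, curve.r):
    print(f"lag {lag:5.0f} ms   r = {r:+.3f}")
print("latency at r=0.7:", lf.latency_at_threshold(curve), "ms")
res, = lf.pairwise_directionality(rec, [("A", "B")])
print(f"directionality: {res.percent:.1f}% at {res.lag_ms:.0f} ms, source = {res.source}")
```

prints

```
lag    10 ms   r = -0.014
lag    20 ms   r = +0.241
lag    30 ms   r = +0.893
lag    50 ms   r = -0.187
lag    70 ms   r = +0.045
lag   100 ms   r = +0.001
lag   200 ms   r = -0.016
lag   250 ms   r = -0.002
lag   300 ms   r = +0.015
lag   400 ms   r = -0.005
lag   500 ms   r = +0.008
latency at r=0.7: 30.0 ms
directionality: 186.2% at 30 ms, source = A
```

The correlation peaks at the imposed 30 ms delay; the directionality index
correctly names `A` as the source at that lag, and its large value reflects
that this synthetic pair is almost perfectly one-directional.

The forward transit-time geometry — a source 50 mm beneath the corner
electrode of a 10 mm-pitch grid at 70 m/s — and its inversion:

```python
model = lf.PropagationModel(velocity=70.0)
grid = lf.ElectrodeArray(["E0", "E5x", "Ediag"],
                         [[0, 0, 0], [50, 0, 0], [20, 20, 0]])
case = lf.generate_triangulation_case(grid, (0, 0, -50), model)
print(case.times_ms.round(3))   # [0.714 1.01  0.821]
print(case.tdoas_ms.round(3))   # [0.296 0.106]  -> 0.3 ms and 0.1 ms
est = lf.triangulate_absolute(grid.positions, case.times_ms, model)
print(est.position.round(3))    # [  0.   0. -50.]
```

## Command line

```sh
lagfoci synth --config synth.yaml --out rec.edf --truth truth.json
lagfoci corr --input rec.edf --pairs pairs.csv --window 500 --step 10 --out curves.csv
lagfoci direction --input rec.edf --pairs pairs.csv --out direction.csv
lagfoci epochs --curves curves.csv --out epochs.csv
lagfoci triangulate --montage grid.csv --times times.csv --velocity 70 --mode absolute --out source.json
lagfoci run --config run.yaml
```

`run` executes the whole pipeline (read → downsample to 100 Hz → lag
curves → directionality → epochs) and archives its configuration next to
the outputs; re-running a configuration reproduces the CSVs byte for byte.
Exit codes: 0 success, 2 config error, 3 data error, 4 numerical failure.

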