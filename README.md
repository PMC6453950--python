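# axonwave

Detection and characterization of action potentials (APs) propagating along
microchannel-confined axons in microelectrode-array / microfluidic (µEF)
recordings.

In µEF devices, axons grow through narrow microchannels lined with a series
of uniformly spaced electrodes (typically four, 100 µm apart). Confinement
boosts the extracellular signal, so one traveling AP appears as a sequence
of threshold crossings sweeping along the electrode series. `axonwave` is a
headless library + CLI for neurophysiologists working with such recordings:
it finds these *propagation sequences*, classifies their direction
(anterograde / retrograde relative to the somal compartment), estimates
conduction velocity, sorts spikes into putative axonal sources, and ships a
fully ground-truthed synthetic benchmark for validating the whole pipeline.

## Method

**Event detection.** Per electrode, the noise median *M*ₙ and standard
deviation *σ*ₙ are estimated after rejecting samples more than three scaled
median absolute deviations (MAD_sc = C·median|S − median S|, C ≈ 1.4826)
from the median. Events are contiguous regions beyond the threshold
*V*_D = *M*ₙ ± *n*_σ·*σ*ₙ, timed at their peak sample.

**Sequence detection.** For each event on a seed electrode near the channel
center, events on the other electrodes are sought inside search windows
*t*ₚ,₁ ± *C*ₛ·*D*(1,*i*) (*C*ₛ = 10 s/m, i.e. a minimum speed of 0.1 m/s).
A candidate is admitted as a propagation sequence only if (1) every
electrode contributes an event, (2) the first-to-last timing implies a
speed below 100 m/s, and (3) the Kendall rank coefficient between electrode
order and event times satisfies |τ_b| > 0.8.

**Velocity estimation.** Two estimators with complementary strengths:

- **SPV** (single-sequence propagation velocity): *v* = *D*(i,j)/τ_peak,
  where τ_peak maximizes the cross-correlation of the pair's waveforms
  (each windowed ±W·D about its peak, W = 7.5 s/m), normalized so
  autocorrelations are 1 at zero lag; the peak value is the confidence
  index CI_S. Available per pair or averaged over all pairs.
- **CPV** (cluster propagation velocity): events of one cluster are
  realigned by cross-correlation (±1.0 ms windows) to the peak of the
  cluster's mean waveform; *v* = *D*(i,j)/(t*ₚ,ⱼ − t*ₚ,ᵢ) from the
  realignment times. Robust to per-event noise — it degrades far more
  gracefully at low SNR than SPV.

**Spike sorting.** User-defined rectangular ROIs on the peak-aligned spike
overlay of one electrode assign sequences to up to four source clusters
(sequentially, cluster 1 → 4; the remainder is cluster 0).

**Synthetic benchmark.** A generator emits sinusoidal spikes (60 µV,
1.5 ms, 20 kHz) traveling at 0.5 m/s across four electrodes 100 µm apart
every 25 ms, plus moving-average noise whose correlation "memory" equals
the spike duration, at a configurable signal-to-noise ratio (SNR). Ground
truth is exact to the sample, so precision (PR = TP/(TP+FP)), detection
rate (DR = TP/NS) and velocity-estimate accuracy can be scored across SNR.

## Worked example

Simulate a noisy dataset, detect sequences, and estimate velocities:

```
$ axonwave simulate --snr 0.5 --seed 7 --out data
367 sequences over 9.175 s at SNR 0.5 -> data/

$ axonwave detect --input data/synthetic.csv --threshold-sd 2.2 --out sequences.csv
92 propagation sequences -> sequences.csv

$ axonwave velocity --input data/synthetic.csv --threshold-sd 2.2 --method cpv --pair 1,4
seq 0: CPV(1,4) = +0.5000 m/s (CI 0.705)
seq 1: CPV(1,4) = +0.5000 m/s (CI 0.723)
seq 2: CPV(1,4) = +0.4615 m/s (CI 0.589)
seq 3: CPV(1,4) = +0.5455 m/s (CI 0.757)
...
```

At SNR 0.5 the simulator needed 9.175 s of recording (367 emitted spikes)
for the detector to admit 92 sequences — a detection rate of roughly a
quarter, illustrating how noise suppresses detection long before it
corrupts the velocity estimates: the cluster-based CPV estimates cluster
tightly around the true 0.5 m/s (the `+` sign marks anterograde travel),
and each carries a confidence index quantifying waveform similarity within
the cluster. `sequences.csv` holds per-electrode peak times and voltages,
τ_b, direction, and SPV estimates for every admitted sequence. The same
pipeline runs on real recordings via `--input recording.h5 --channels
B9,B10,B11,B12 --spacing 100e-6`, and `axonwave kymo` / `axonwave audio`
render a time-electrode image or a 500× time-dilated audio playback (one
ascending note per electrode) for qualitative inspection.

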