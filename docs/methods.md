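# Methods

This note documents the models, estimators and numerical choices behind
`axonwave`, including where a design decision was genuinely open and how we
resolved it.

## Signal model and units

Everything internal is volts and seconds. Sample *k* of a recording maps to
time *t*₀ + *k*/*f* (0-based, half-open windows [start, end)). CSV input is
assumed to be microvolts unless declared otherwise — standard MEA practice;
HDF5 input is converted via the per-channel factors of the MultiChannel
Systems `InfoChannel` table (dataset path and orientation are configurable,
since vendor layouts vary). A microchannel is an ordered `ChannelGroup` of
2–16 uniformly spaced electrodes; electrode 1 is nearest the somal
compartment, which fixes the sign convention: positive velocity =
anterograde (away from the somata). The mapping of recording channels to
microchannels is device-specific, so it is explicit user configuration —
labels in somal-side-first order plus a spacing in meters.

## Noise estimation and event detection

Noise statistics are robust against the spikes riding on them: samples more
than 3·MAD_sc from the signal median are discarded, then the median *M*ₙ
and standard deviation *σ*ₙ of the remainder are taken as the noise
statistics. MAD_sc = C·median(|S − median S|) with
C = −1/(√2·erfc⁻¹(3/2)) ≈ 1.4826, the constant that makes it estimate σ for
Gaussian data. (The absolute value is essential; without it the median of
signed deviations is ~0.) For purely Gaussian input the ±3σ truncation
shrinks the reported σₙ by √(1 − 2aφ(a)/(2Φ(a)−1)) ≈ 0.987 at a = 3 — an
inherent, small bias of the two-step procedure that we deliberately do not
correct, since the detection threshold *V*_D = *M*ₙ ± *n*_σ·*σ*ₙ is defined
on the post-rejection σₙ.

Events are maximal runs of samples strictly beyond *V*_D on the chosen
polarity side; the event time is the extremal sample (earliest sample on
ties — deterministic). Runs touching the trace boundary are kept by
default (`keep_edge_events=False` drops them). Noise statistics are
estimated once per electrode over the full analysis window; there is no
re-estimation schedule. Runs separated by a single sub-threshold sample are
not merged.

## Sequence linking

The seed electrode is the one closest to the microchannel center,
⌈n_E/2⌉ for even counts (electrode 2 of 4); configurable. For each seed
event, in time order:

1. the sequence is anchored at electrode 1 by the nearest available
   electrode-1 event within ±C_s·D(1, seed) of the seed event
   (C_s = 10 s/m, the reciprocal of a 0.1 m/s minimum speed);
2. every other electrode contributes the available event nearest to
   *t*ₚ,₁ inside its window *t*ₚ,₁ ± C_s·D(1, i) — "nearest to the anchor"
   is our resolution of the (unspecified) multiple-candidate case;
3. the three admission criteria are checked: completeness, first-to-last
   speed < 100 m/s (equal times ⇒ infinite speed ⇒ reject), and
   |τ_b| > 0.8 between electrode order and event times.

τ_b is the pairwise rank statistic 2·Σ_{i<j} sign((E_i−E_j)(t_i−t_j)) /
(n_E(n_E−1)), with tied pairs scoring 0 — so for four electrodes one tied
pair still passes (τ_b = 5/6) but any discordant pair fails, and ties are
common at 20 kHz where the true inter-electrode delay is 4 samples.

Events joining an admitted sequence are consumed, so each event belongs to
at most one sequence; this prevents double-counting but means the detector
makes no attempt to disentangle overlapping sequences during bursts (a
documented failure mode of this class of detector). Each admitted sequence
stores per-electrode waveform snippets of half-width
max(1.0 ms, W·D(1, n_E)) — wide enough for both velocity estimators below.

## Velocity estimators

**SPV.** For a pair (i, j), j > i, each trace is windowed to ±W·D(i, j)
(W = 7.5 s/m) about its own event peak and the windows are fully
cross-correlated; the normalization divides by the zero-lag energy of the
reference (i-th) window, which makes every autocorrelation 1 at zero lag.
Identical waveforms therefore give confidence CI_S = 1 for *every* pair and
a peak exactly at the peak-time difference (windowing both traces about the
same instant instead would truncate near pairs asymmetrically and cap their
confidence below 1 even without noise). The confidence of the all-pairs
mean is the *minimum* pairwise CI_S. Lags stay at sample resolution, so
every SPV lies on the quantization grid D·f/k — sub-sample parabolic
interpolation exists behind `interpolate=True`, off by default. Peak ties
resolve to the smallest |τ|, then positive τ. Because v ∝ 1/τ, an
underestimated lag inflates the speed more than an equal overestimate
deflates it; the mean SPV consequently overestimates at low SNR, which is
exactly the regime where CPV is preferable. Confidence values can exceed 1
for amplitude-mismatched pairs and are reported unclipped.

**CPV.** Per electrode, the events of a cluster are realigned: each event's
±1.0 ms window is cross-correlated against the running cluster mean, the
peak lag re-centers the event, and the mean is rebuilt — two passes, which
suffices for consistent lags (the all-against-all aggregation is not
otherwise constrained; aligning to the running mean is equivalent for
consistent pairwise lags and O(n) per pass). The realignment time t*ₚ,ᵢ is
the recording time of the sample that maps to the peak of the final mean
waveform, and vₚ = D(i, j)/(t*ₚ,ⱼ − t*ₚ,ᵢ). Note the dimensional form: a
velocity must be distance over time; the reciprocal form sometimes quoted
for this estimator is a units erratum. The per-event confidence CI_Cp,i is
the mean over partners q of the peak cross-correlation with event q
normalized by event p's energy; CI_Cp = min over the two electrodes. A
single-event cluster gets confidence 1.0 with a warning. The most distant
pair is the default for cluster summaries: timing-resolution errors scale
with 1/D.

## Spike sorting

Sorting is deliberately manual (ROI-driven), not algorithmic: rectangles in
(time-relative-to-aligned-peak, voltage) space on one "event electrode"
select clusters 1–4 sequentially, consuming sequences as they match;
cluster 0 collects the rest, so the result is always a partition. With two
ROIs per cluster the default logic is conjunctive (the waveform must pass
through both) — the natural reading of gating two waveform features —
with `roi_logic="any"` available. ROI coordinates are overlay-relative
(ms from the aligned peak), which makes configs reproducible across
recordings; they load from JSON with voltages in µV.

## Synthetic data generator

The generator defines the validation conditions and is itself first-class,
tested code. Defaults: four electrodes at 100 µm, 20 kHz, spikes of 60 µV
amplitude and t_s = 1.5 ms emitted every 25 ms, traveling at 0.5 m/s
(inter-electrode delay = 200 µs = exactly 4 samples, so ground truth is
exactly representable on the sample grid and noiseless recovery is exact by
construction). Spike starts are offset by half an ISI so every waveform has
full context; a 1 s default duration emits 40 sequences.

The spike is one full sinusoid cycle (biphasic, detected lobe first,
`spike_shape="cycle"`). This is the one genuinely open reading of a
"single sinusoidal phase" spike; we also provide the half-cycle lobe
(`"half"`). The full cycle is the default because its detected lobe is
twice as steep (4× the trough curvature), keeping peak-time jitter under
noise well below the 4-sample inter-electrode delay — only then does the
benchmark behave as intended, with the detection threshold rather than
rank-order scrambling as the binding failure mode at moderate noise, and
with cluster realignment achieving few-percent velocity accuracy at SNR
0.4. A half-sine spike's shallow trough lets smooth noise displace peaks
by several samples, collapsing the detection rate at all noise levels.

Noise is an s-point moving average (s = f·t_s = 30, so its autocorrelation
"memory" equals the spike duration) of i.i.d. standard normal draws,
scaled by V_peak/SNR; the first s−1 samples average only the draws
available so far (explicit warm-up rather than discarded samples). The
trace standard deviation is V_peak/(SNR·√s), e.g. ≈15.7 µV at SNR 0.7.
Note that SNR here is a generator *scale parameter*, not an amplitude
ratio: for Gaussian draws the "maximum possible" noise value is unbounded,
so we implement the scaling formula literally. Electrodes are independent;
(config, seed) → bit-identical datasets.

`generate_dataset(auto_duration=True)` sizes the recording so the detector
at the reference 2.2-SD threshold admits at least 40 sequences, growing
the duration geometrically in whole ISIs up to a 120 s cap (a cap long
enough for the SNR range 0.3–0.7; below that the dataset is returned with
a warning). The benchmark threshold of 2.2 SD is calibrated on noise-only
data: 100 s of pure noise yields tens of thousands of raw threshold
crossings per dataset but only a handful (≈1–5) of spurious *sequences*,
because the three admission criteria must conspire across four electrodes.

### What the generator does and does not emulate

It reproduces the geometry, timing and noise correlation structure that
the detector and estimators are sensitive to. It does **not** model
biophysical AP waveforms, amplitude variation across electrodes or events,
electrode impedance differences, drift, bursting statistics, or multiple
simultaneous sources. Passing the benchmark therefore demonstrates the
correctness and noise robustness of the pipeline's machinery — not that
real recordings with overlapping units or nonstationary noise will sort
cleanly; the ROI sorter exists precisely because real sources need human
judgment.

## Validation harness

Detections are matched to ground truth greedily, one-to-one, on
first-electrode peak times with a 1.5 ms (one spike duration) tolerance —
sequences are 25 ms apart, so results are insensitive to the exact value
over roughly 0.5–5 ms. PR = TP/(TP+FP) (undefined when nothing is
detected), DR = TP/NS with NS counting *all* emitted sequences. The SNR
sweep uses three datasets per level; velocity accuracy treats the detected
true positives as one cluster (single simulated source), computes
CPV(1, n_E), SPV(1, n_E) and mean SPV per sequence as ratios to the true
velocity, and reports per-dataset |mean ratio − 1|·100 averaged over
datasets. Stochastic test assertions use Monte-Carlo bands of about three
standard errors over 3 seeds × 3 datasets; seeds are fixed in the suite.

Typical operating points (recomputed from scratch by
`scripts/acceptance.py` and the acceptance tests): PR ≈ 0.96–0.98 at SNR
0.3; DR ≈ 0.77–0.82 at SNR 0.7 collapsing below 0.10 by SNR 0.4; CPV
error ≈ 1–2.5% at SNR 0.4 while mean SPV errs several-fold worse; 2–4
spurious sequences per 100 s of pure noise at the 2.2-SD threshold.

## Visualization and audio

Kymographs map voltage linearly to intensity in time-electrode space
(min/max per window; a symmetric-about-median option suits bipolar
signals); a traveling AP is a diagonal streak of slope 1/v (2 ms/mm at
0.5 m/s), and a manual two-point readout converts a drawn line back to a
signed velocity (sign from the stroke's electrode direction). Audio
playback dilates time 500× (output duration exact to one sample at
44.1 kHz), assigns each electrode a note of an ascending just-intonation
major scale from 261.6 Hz — the specific scale is our choice; any distinct
tone set works — and modulates each tone by the electrode's rectified,
lightly smoothed voltage envelope, normalized to −3 dBFS. Anterograde
sequences are heard as ascending arpeggios, retrograde as descending.

## Known limitations

- Bursting / overlapping sequences: candidate windows overlap and the
  nearest-event rule plus event consumption resolves them greedily; no
  burst decomposition is attempted.
- The greedy one-sequence-per-event rule is an interpretation; detectors
  that allow event reuse would score slightly differently on noisy data.
- Sub-sample lag refinement is available but off by default; all default
  velocity estimates carry the sample-grid quantization.
- The noise-only false-sequence count depends on linking details beyond
  the printed criteria (window anchoring, candidate choice); plausible
  variants span roughly a factor of three around our ≈2–3 per 100 s.
- HDF5 support targets the MultiChannel Systems layout; other vendors'
  files need explicit `dataset_path`/metadata arguments.
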