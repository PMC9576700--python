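# Methods

`meaburst` couples a spiking-network model of stem-cell-derived
excitatory cultures with the spectral pipeline used to measure their
network-burst frequency from multi-electrode-array (MEA) recordings.
This note documents the model, the measurement chain, the synthetic data
the package tests itself against, the calibration constants, and the
numerical choices, in enough detail to reproduce or challenge any of
them.

## The network model

The model is a population of N adaptive leaky integrate-and-fire (AdIF)
neurons, fully excitatory (the cultures it emulates contain no
interneurons), randomly connected with probability p, and driven by
external Poisson input. The membrane potential V_i of neuron i follows

    C_m dV_i/dt = g_L (E_L − V_i) + g_e (E_e − V_i) − w
    tau_w dw/dt = a (V_i − E_L) − w
    tau_e dg_e/dt = −g_e

When V_i reaches the threshold V_th the neuron spikes and three resets
apply: V_i → V_r, w → w + b, and every postsynaptic conductance gains
the synaptic weight, g_e,j → g_e,j + w_e for all targets j. The slow
variable w lumps the intrinsic Na+/K+ currents that patch-clamp
recordings show are altered in the disease lines: `a` (nS) is
subthreshold adaptation, `b` (pA) the spike-triggered increment, and
tau_w their recovery time constant. Each neuron additionally receives
`n_ext_synapses` (default 100) independent Poisson trains at `ext_rate`
(default 20 Hz), each event incrementing g_e by w_ext.

The full profile simulates N = 1000 neurons at p = 0.05 (≈ 50 synapses
per cell) for 300 s with a 0.1 ms step. Because that is expensive, the
test and experiment profile runs 200 neurons for 60–150 s, with the
recurrent weight rescaled by 999/(n−1) so the summed recurrent
conductance per neuron at any given p matches the full-size network.
The rescaling compensates population size only; the connection
probability remains a live experimental variable.

### Dynamical regime

The operating point is deliberately *threshold-poised*: the summed
external conductance (w_ext = 0.14 nS per event, ≈ 1.4 nS mean) holds
neurons a few millivolts below threshold, so an isolated neuron is
nearly silent (≈ 0.07 Hz, fluctuation-driven). Rhythm is collective:
stray spikes recruit the population through recurrent excitation into a
near-synchronous network burst, the accumulated adaptation w terminates
it, and the slow decay of w (tau_w ≈ 1 s) sets the inter-burst interval.
This reproduces three qualitative facts about the cultures: firing is
organized into network-wide bursts; the burst rhythm sits well below
1 Hz; and removing recurrent excitation (the in-silico analogue of AMPA
receptor blockade, w_e = 0) abolishes the rhythm — the spectral pipeline
returns an exclusion rather than a peak.

Within this regime the burst frequency is governed almost entirely by
the adaptation parameters — the interval is roughly
tau_w · ln(k·b / w_ignite), with k the spikes fired per burst — while
moderate changes in C_m, E_L or g_L shift it by at most one or two
spectral bins. That separation is what makes the drop-out experiment
meaningful.

### Integration

Forward Euler for V and w at dt = 0.1 ms, with g_e decayed by its exact
factor exp(−dt/tau_e) each step; threshold test at the end of the step;
same-step synaptic delivery; no refractory period and no axonal delay
(the model equations contain neither). Unit and acceptance tests verify
the integrator against the closed-form leak relaxation, adaptation
decay, and the clamped-conductance fixed point to within 1%.

Two back ends implement the same update order: a numba kernel
(production) and a plain-numpy loop assembled from the step-level
operations (reference). They consume different random streams and are
compared statistically in tests; each is bit-reproducible given a seed.
A spike budget (`max_mean_rate`, default 250 Hz mean) aborts runs that
enter a saturated regime — with neither refractory period nor synaptic
depression, sufficiently strong recurrence (e.g. very high connection
probabilities) drives the model into near-limit firing at 1/dt, which
is reported as a runaway error rather than simulated to completion.

Initial conditions are V = E_L (optionally with a small Gaussian jitter,
2 mV in the standard configurations, to break the artificial symmetry of
identical neurons), w = 0, g_e = 0.

## The measurement chain

Raw MEA voltage (12.5 kHz, 64 electrodes per well) is processed exactly
as recorded data would be:

1. zero-phase Butterworth bandpass, 200–3000 Hz, order 3 forward-backward;
2. spike detection at 6× a robust per-electrode noise scale (median
   absolute deviation / 0.6745 over the full trace; a sliding-window
   variant is available), event time at the excursion extremum of |v|,
   1 ms dead time;
3. binarization into 1 ms bins (1 kHz), value 1 iff the bin contains a
   spike;
4. Welch power spectral density of the binary train (Hann window,
   segments of 2^16 samples — clipped to the largest power of two that
   fits shorter trains — 50% overlap, no detrending);
5. the same PSD for randomly bin-permuted copies of the train
   (permutation preserves the spike count exactly and is asserted), and
   the ratio expressed in dB: 10·log10(P_signal / P_surrogate). The
   surrogate cancels firing-rate and flat-noise structure, so 0 dB means
   "Poisson-like at this rate" and a positive peak means genuine
   temporal patterning;
6. the network-burst frequency is the frequency of the global maximum
   over all f > 0: if it falls in (0, 1] Hz it is reported, otherwise
   the train is excluded (never clamped into band). Exact ties resolve
   to the lowest frequency and are flagged.

Activity QC mirrors culture practice: an electrode is active at ≥ 5
spikes/min; a well passes with ≥ 32 of 64 active electrodes.

Simulated populations are first merged into 64 multiunit channels
(random balanced partition of neurons) before spectral analysis, since
an extracellular electrode reports the overlapping units around it;
population spectra are the per-channel dB spectra averaged over
channels, with empty trains skipped and counted.

### Why a perfectly regular comb has no usable peak

A strictly periodic binary train spreads its power equally over all
harmonics of its rate up to the Nyquist frequency, so the *global*
maximum of its spectrum is decided by estimator noise and lands on an
arbitrary harmonic. A dominant fundamental requires either wide burst
envelopes or interval jitter (harmonic k is damped roughly by
exp(−(2π k f0 σ)²) for event-time jitter σ). Biological bursting has
both; the synthetic generator therefore draws burst onsets from a
jittered-regular renewal process (CV ≤ 0.2, default 0.1) rather than a
Poisson or strictly periodic process, and the spectral oracle tests use
quasi-periodic trains (σ = 0.25 s on a 4 s period). This is a property
of the estimator defined this way, not an implementation artifact.

## Synthetic MEA data

`SyntheticWellSpec` emulates one well: background Poisson spiking per
electrode, synchronized bursts at a controllable rate (participating
electrodes fire intra-burst Poisson spikes at ~120 Hz for ~150 ms), and
optionally raw voltage: Gaussian noise of known SD plus a fixed 1 ms
biphasic (negative-then-positive) template scaled to a chosen multiple
of the noise SD at each spike time. Ground truth (onsets, spike times)
is returned with every artifact and is exactly the data generated.

What the generator does *not* emulate: electrode crosstalk, drift,
non-stationary noise, waveform variability between units, development
over weeks in culture, or inhibition. Passing the recovery tests
therefore shows the pipeline is correct for stationary,
template-shaped, quasi-periodic data — not that it is robust to every
artifact of real recordings.

Note that the bandpass filter shrinks the noise floor (only the
200–3000 Hz band of the white noise survives, ≈ 0.67 of the raw SD)
while the ~1 kHz spike template passes nearly intact, so an amplitude
quoted as m× the raw noise SD acts as ≈ 1.4·m× the in-band noise at the
detector.

## Genotype fixtures

No numeric AdIF parameters are published for the modelled lines, so the
fixtures are versioned calibration constants (v2) chosen to obey the
qualitative patch-clamp directions and to place the simulated peak
ordering as observed: MECP2-null slower than isogenic WT, the milder
L124W missense variant slightly faster.

| field | WT | NULL | L124W | direction encoded |
|---|---|---|---|---|
| C_m (pF) | 80 | 78 | 80 | null: decreased capacitance |
| g_L (nS) | 4.0 | 3.98 | 3.8 | null and L124W: higher input resistance |
| E_L (mV) | −65 | −64.9 | −65 | null: depolarized resting potential |
| a (nS) | 4.0 | 4.5 | 4.0 | altered Na+/K+ currents (adaptation) |
| b (pA) | 350 | 420 | 340 | idem |
| tau_w (ms) | 1000 | 1300 | 1000 | idem (travels with the currents) |
| w_e (nS) | 0.3 | 0.3 | 0.3 | synaptic weight, shared |

Scaled-profile medians (3 seeds): NULL ≈ 0.21 Hz < WT ≈ 0.29 Hz <
L124W ≈ 0.32 Hz. Two deliberate choices deserve emphasis:

* The membrane differences (C_m, E_L, and the null's g_L) are kept
  small. The threshold-poised regime is sensitive to excitability, and
  large membrane shifts would move the burst clock on their own —
  contradicting the attribution the drop-out experiment tests. The
  *directions* carry the phenotype; the magnitudes are calibration
  constants, not measurements.
* The L124W fixture differs from WT only in g_L and (a, b); its mildly
  faster rhythm comes mainly from the higher input resistance.

The dial that moves the burst frequency is tau_w (and, jointly, b);
`scripts/calibrate_fixtures.py` reruns the grid search around the WT
point that produced these values.

## In-silico experiments

* **Fit scan** (`run_fit_scan`): 2-D grid over C_m and the passive time
  constant tau_m, realized as g_L = C_m/tau_m (default ranges C_m ∈
  [20, 120] pF, tau_m ∈ [10, 60] ms — stated observation ranges, not
  published values); each combination simulated over replicate seeds
  and analyzed with the standard chain. `select_top_fit` returns the
  combination whose median peak is closest to a measured target, ties
  broken by smaller seed dispersion then lexicographic order.
* **Drop-out** (`run_dropout_experiment`): six conditions — WT, NULL,
  and the four swaps exchanging either the adaptation subset (a, b,
  tau_w) or the membrane subset (C_m, E_L) between them. Subset
  membership is overridable; tau_w travels with adaptation because it
  shapes the very currents the subset represents. Run at 150 s × 3
  seeds: the longer window gives the slow null-like rhythms (~0.2 Hz,
  ~30 bursts) enough cycles for a stable spectral fundamental.
  "Condition A matches condition B" is operationalized as
  |median(A) − median(B)| ≤ max(dispersion_A, dispersion_B, Δf) + Δf,
  with dispersion the across-seed range of included peaks and Δf the
  spectral bin width; the WT–NULL separation (~5 bins) must exceed that
  tolerance for the comparisons to be non-vacuous. Excluded replicates
  (out-of-band global maxima, an occasional harmonic flip in the slow
  conditions) are dropped before taking medians and are visible in the
  returned table.
* **Connectivity scan** (`run_connectivity_scan`): grid over
  subthreshold adaptation a ∈ [4, 10] nS and connection probability
  p ∈ [0.05, 0.35], with a per-a Spearman trend summary
  (`connectivity_trend`). See limitations below.

Every scan row carries status ∈ {ok, excluded, failed}; failures
(numeric, runaway) are recorded and do not abort the scan.

## Problem sizes

Simulation-heavy tests and the acceptance script use the scaled profile
(200 neurons; 60 s for single-condition checks, 150 s for the drop-out
experiment), 64 multiunit channels, 3–10 permutation surrogates, and
synthetic wells of 16 electrodes × 300 s at 12.5 kHz. These sizes were
chosen as the smallest at which the measured quantities stabilize
(burst counts ≥ ~15 per run for a reliable fundamental; ≥ 2 Welch
segments per train).

## Known limitations

* **High connection probabilities.** With the calibrated weights, the
  model at p ≳ 0.15 leaves the slow-bursting regime: recurrent drive
  grows linearly with p while spike-triggered adaptation does not, so
  runs become fast-cycling or saturate (runaway guard). Across the
  surviving grid points the peak frequency falls as p rises (negative
  Spearman trend at every a), but the subthreshold-adaptation axis is
  *not* uniformly weaker than the connectivity axis at this scale:
  raising a from 4 to 10 nS at p = 0.05 can silence the threshold-poised
  network entirely, which registers as a large "a effect". A regime in
  which both scan axes stay within the analyzable band across their full
  stated ranges was not found for this model family; the scan reports
  exclusions honestly instead of clamping.
* Slow rhythms (≲ 0.2 Hz) occasionally hand the spectral global maximum
  to a harmonic or out-of-band fluctuation at 60 s; the experiments use
  150 s windows, and remaining exclusions are reported, not patched.
* Identical neurons (no parameter heterogeneity), no inhibition, no
  synaptic plasticity or depression, no conduction delays — matching
  the modelled system's stated scope.
* The permutation surrogate shuffles 1 ms bins; an inter-spike-interval
  shuffle (`meaburst.spectral`) is not implemented because the binary
  1 kHz representation makes bin permutation the natural exchangeable
  null.
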