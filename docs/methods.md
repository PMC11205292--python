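# Methods

This note documents the models and estimators implemented in `meamod`, the
parameters that matter, the synthetic generator's assumptions, and the design
choices made where the methodology was genuinely open.

## Data model

Spike times are stored in seconds from recording start; a recording is a
`SpikeTrainSet` (per-electrode strictly increasing timestamps, duration,
optional sample rate). Electrode roles come from a user-supplied
`ElectrodeMap` with labels `source`, `target`, `channel` (microchannel
electrodes, excluded from module statistics and connectivity groups) and
`excluded`. All intervals are half-open `[onset, offset)` and all binning is
half-open with bin 0 starting at t = 0; burst spike tallies include the
offset spike, which by construction is the burst's last spike.

## Spike detection

Threshold detection on each trace with a robust noise scale
`σ = median(|x|)/0.6745` — the median-based estimator is insensitive to the
spikes themselves, and the constant makes it consistent for Gaussian noise.
Defaults: `threshold_factor = 8`, `dead_time_ms = 1`, negative polarity
(extracellular spikes are predominantly negative), no filtering (an optional
causal Butterworth band-pass is available but off). The reported spike time
is the extremum within the dead-time window, and no two spikes on one
electrode can be closer than the dead time. Detection is invariant to
positive rescaling of the trace because the threshold scales with the data.

## Network-burst detection

Per module: pool the module's spikes, count them in 50 ms bins, and take
maximal runs of bins at/above threshold as candidates. The threshold is
per-electrode (`0.25 spikes/bin/electrode`, i.e. ≥ 2 pooled spikes per bin at
8 electrodes): a *network* burst requires coincident spiking, and a
sub-one-spike effective threshold would make every stray background spike a
candidate. Candidates with fewer than `min_burst_spikes = 5` spikes are
dropped **before** merging (merging first would glue isolated background
spikes onto real bursts and drag their onsets earlier — we measured this to
bias onset-lag statistics substantially); surviving candidates closer than
`merge_gap_ms = 100` are merged. Finally the boundaries are anchored: the
onset (offset) snaps to the first (last) run of `anchor_spikes = 3` pooled
spikes within `anchor_window_ms = 25`, falling back to the first/last spike
for sparse bursts. Anchoring removes the residual case of a lone background
spike sharing the onset bin with the true burst start; without it a fraction
of Source→Target burst pairs appear time-reversed.

Burst statistics: `SBE = total spikes / module electrode count`,
`BD = (offset − onset)` in ms, bursts/min = count / recording minutes,
firing rate = module spikes / duration.

A note on threshold monotonicity: lowering the rate threshold grows the set
of supra-threshold bins, and every high-threshold candidate interval lies
inside some low-threshold candidate — but the *number* of candidates can
decrease, because newly supra-threshold bins can join two runs into one.
The test suite asserts the containment form of the property.

## Activity typing (type 1 vs type 2)

The per-burst SBE values (BD selectable) are split into two clusters by an
**exact 1-D k-means**: the optimal partition minimizing within-cluster sum of
squares is contiguous in sorted order, so a dynamic program (vectorized scan
for k = 2) finds the global optimum deterministically — no initialization, no
seed, identical inputs always give identical labels.

Cluster separation is judged by the Davies–Bouldin index,
`DB = (1/k)·Σᵢ maxⱼ≠ᵢ (sᵢ+sⱼ)/dᵢⱼ`, which for two clusters reduces to
`(s₁+s₂)/d₁₂`. The within-cluster scatter exponent is configurable
(`q = 1`: mean absolute deviation, `q = 2`: root-mean-square). **Default
q = 2.** Rationale: for a *unimodal* right-skewed burst-size distribution the
optimal 2-means split has an asymptotic DB of only ≈ 0.57–0.61 under q = 1,
so the 0.5 decision threshold sits inside finite-sample noise and unimodal
recordings are misclassified as two-cluster several percent of the time at
realistic burst counts; under q = 2 the unimodal asymptote is ≈ 0.76–0.80 and
the decision is stable. DB is scale-invariant and symmetric in cluster order;
coincident centroids raise a typed error.

Decision rule: **type 1** iff `DB ≤ 0.5` *and* both cluster fractions are
≥ 10% (a DB of exactly 0.5 counts as two clusters); otherwise **type 2**.
The large-burst cluster is the one with the greater centroid. At least 10
bursts are required; with fewer the type is undecidable and a typed error is
raised. Fewer than two distinct values ⇒ type 2 with undefined DB. The type
is computed per module; when Source and Target disagree the report carries a
warning rather than forcing equality.

## Burst propagation

Source and Target bursts are paired greedily, earliest first, one-to-one:
each Source burst takes the earliest unpaired Target burst whose onset lag
lies in `(min_onset_lag, max_onset_lag] = (0, 100]` ms (intermodular delays
in these preparations are tens of ms). The backward direction is defined
symmetrically. An interval-overlap pairing mode is available via config.
`PPST = |S→T pairs| / n_source_bursts`; undefined (None, flagged) when the
Source catalog is empty — never silently zero. Widening the window can only
increase PPST.

## CFP connectivity

For an ordered pair (i, j), `curve[b]` is the fraction of reference spikes
on i that are followed by ≥ 1 spike on j with lag in bin `(b·Δ, (b+1)·Δ]`,
Δ = 1 ms, out to 50 ms — a probability per bin, not a raw count histogram.
Electrodes with fewer than 50 reference spikes give an undefined curve. The
implementation is vectorized but exactly equal, bin by bin, to a direct
counting oracle (asserted in the tests over random inputs).

Connectedness ("the curve is not flat"): peak > off-peak mean +
`flatness_k = 3` off-peak standard deviations, **and** the peak must be
supported by at least `min_peak_hits = 5` reference spikes. The count guard
is essential for sparse trains: a curve of near-zero Poisson counts almost
always has a maximum exceeding mean + 3·sd because the background sd is
tiny, so the sd rule alone would declare connections out of noise. Strength
is the peak probability; latency is the peak-bin *center* (a deterministic
lag of exactly 4.5 ms yields latency 4.5 ms); no curve fitting is attempted.
Curves are computed for all ordered intra-Source, intra-Target and
Source→Target pairs — backward Target→Source pairs are not analyzed, since
propagation in these preparations is essentially one-directional — and group
medians of strength and latency are taken over connected pairs.

## Statistics and reporting

Group contrasts use the two-sided Mann–Whitney U test: exact enumeration
when the combined sample is ≤ 20 with no ties, otherwise the tie-corrected
normal approximation with continuity correction. P-values are raw — no
multiple-testing correction is applied, and the report header states this.
The report pools per-recording medians (SBE, BD, bursts/min, PPST) by the
Source module's activity type and compares type 1 vs type 2, plus pooled
intra- vs inter-modular connectivity strength and latency.

## Synthetic generator

The generator emulates the phenomenology of a two-module culture, not its
biophysics. Defaults are the study conditions; all are configurable.

- **Electrodes**: 8 Source + 8 Target (modules of a 60-electrode array after
  excluding channel/reference electrodes have this order of size).
- **Source bursts**: hard-core renewal process (gap = 1 s + exponential),
  default 6/min over 600 s.
- **Burst size**: SBE drawn from a log-normal mixture. Type-1-like default:
  weights 0.6/0.4, medians 2 and 35 spikes/electrode, log-sd 0.5 and 0.25
  (the large-burst component spans roughly 20–40). Type-2-like: single
  component, median 2, log-sd 0.5, at 12 bursts/min (type-2 networks burst
  more often).
- **Burst duration**: BD = 7.5·SBE + 28.5 ms with 10% multiplicative jitter —
  the affine map reproduces the canonical pairs (SBE 35 → BD ≈ 292 ms,
  SBE 1.9 → BD ≈ 43 ms).
- **Within-burst structure**: a burst is a sequence of network events spread
  over BD; every module electrode fires in an event with a common
  participation probability. Each module's electrodes split into an early
  half (delay ≈ 0) and a late half (delay ~ N(4, 1) ms per electrode), which
  plants sharp pairwise CFP lags; early→early pairs have near-zero lag and
  reverse pairs no positive-lag peak.
- **Propagation**: with probability `propagation_prob` (default 0.27), or a
  logistic function of SBE when `prop_prob_slope` is set, the Target module
  replays the event sequence after a delay. The delay is drawn **once per
  recording** from N(20, 5) ms — a culture's intermodular conduction path is
  fixed, so the delay is a property of the recording — plus 1 ms per-burst
  jitter. The per-recording delay is therefore also the planted intermodular
  pairwise CFP lag. No backward propagation is planted.
- **Background**: independent Poisson spiking at 0.2 Hz per electrode
  (~10% of spikes at type-1 defaults; most activity in mature cultures is
  burst-organized).
- **Raw traces**: optionally, Gaussian noise plus a stereotyped biphasic
  waveform (0.4 ms negative phase, 0.5 ms positive overshoot) whose trough
  lands on the spike's sample, at 20 kHz.

Everything is drawn from one seeded generator in a fixed order, so output is
bit-identical for identical (config, seed).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biophysical membrane/synaptic dynamics,
development across days in vitro, electrode-specific noise and amplitude
variation, polysynaptic lag dispersion beyond the planted two-level delay
structure, burst-shape diversity (all bursts are event sequences with a
common participation probability), and non-stationarity within a recording.

## Problem sizes and numerical choices

Recovery checks run the full pipeline across many seeds: activity typing on
100 generated recordings per regime, PPST on 100 recordings of ~300 bursts
per planted probability, latency ordering on 50 recordings with full
16-electrode CFP matrices. These sizes give the statistical assertions
comfortable margins (e.g. the binomial coverage check has nominal 95%
against a required 90%) while keeping the default suite fast. PPTS under
forward-only coupling is estimated on the pooled ensemble (total backward
pairs over total Target bursts): per-recording ratios with ~20 Target bursts
cannot resolve probabilities below 0.05.

Ties and degenerate inputs: k-means requires ≥ k distinct values; DB is
undefined for coincident centroids; curves with fewer than 3 bins are
rejected by the flatness test; empty burst catalogs give undefined (flagged)
propagation probabilities; identical-timestamp collisions on one electrode
are collapsed on read. Floating-point equality is asserted only where the
computation is exactly integer-derived (CFP counts, enumeration p-values at
1e-12).

## Known limitations

- Burst onsets are estimated at spike resolution but contaminated, at ~1%
  per burst, by background spikes within the anchor window; backward
  propagation estimates are floor-limited at roughly that rate.
- The Davies–Bouldin 0.5 rule is a hard threshold; recordings whose optimal
  split hovers near 0.5 flip type under resampling regardless of scatter
  exponent.
- CFP latency is quantized to the bin width (1 ms default).
- The exact Mann–Whitney path enumerates only for combined n ≤ 20; beyond
  that the tie-corrected normal approximation is used even for tie-free
  samples.
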