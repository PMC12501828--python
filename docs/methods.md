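# Methods

This package re-implements, as tested code, an analysis of **error
auto-cancellation**: the observation that erroneous keypresses in a
speeded choice task are released earlier than correct ones (shorter
response durations, RD), and that the error-related negativity (ERN)
tracks this cancellation. It contains five scientific components — a
conflict-monitoring network simulator with response-offset
registration, peri-error behavioral statistics, an EEG preprocessing
chain, residue-iteration decomposition (RIDE), and condition-level ERP
statistics — plus a synthetic-data generator that makes every stage
testable by parameter recovery without any external data.

## Conflict-monitoring network

The simulator is a nine-unit recurrent network: four input units (two
coding the central target letter mapped to the left/right response, two
coding the irrelevant surround), two response units, and three
attention units (one for the center pair, one per surround unit).
Between layers, connections are excitatory (input→response w = 1.5;
input↔attention w = 2.0, bidirectional); within a layer all unit pairs
inhibit each other (input −2.0, response −3.0, attention −1.0).
Internal input is scaled by 0.08 (excitatory) or 0.12 (inhibitory),
external input by `extscale = 0.4`. Activations follow a shunting rule
with step Δa = input·(a_max − a) − decay·(a − a_rest) for positive
input and Δa = input·(a − a_min) − decay·(a − a_rest) otherwise
(`activation_rule="grossberg_standard"`), bounded to [−0.2, 1] with
resting level −0.1 and decay 0.1. A trial runs 50 Euler cycles of 16 ms
each: 3 preparatory cycles (0.03 to both response units), then 0.15 to
the stimulated center unit. Response onset is the first cycle a
response unit exceeds 0.18; its offset is the first later cycle it is
back at or below 0.18, so RT = (onset − 3)·16 ms and RD =
(offset − onset)·16 ms.

**Conflict** is the Hopfield energy of the response layer,
max(0, −2·a_L·a_R·w) with w = −3, computed on the transmitted
activations (see below), so it is nonzero exactly when both response
units are co-active. Within-trial cumulative energy E feeds the center
attention unit on the next cycle, ext_C ← 0.5·ext_C + 0.5·(4.41·E +
1.08), clamped to [1, 3]; both surround attention units receive
0.5·(3 − ext_C). ext_C persists across trials; E and the activations
reset at each trial start.

Three points were genuinely open and were settled by verifying which
choice reproduces the behavioral phenomenology (commission errors at a
realistic rate, RD shortening on errors, an ERN-like post-onset
conflict difference); all three are exposed as config options:

* **Transmission** (`transmission="rectified"`): units transmit
  max(a, 0). With raw (possibly negative) activations the resting state
  is not a fixed point — mutual inhibition between two sub-resting
  units acts as mutual excitation and the whole network self-excites —
  and "errors" become entrenchments of the wrong unit with the correct
  unit pinned negative, which abolishes response co-activation and
  hence any conflict signal. Rectified transmission (the
  interactive-activation convention) restores both properties; the raw
  rule remains available as `transmission="linear"`.
* **Noise** (`noise_targets="all_units"`): zero-mean Gaussian noise
  (σ = 0.035) is added to every unit's net input on each cycle.
  Restricting noise to the two surround input units
  (`"surround_only"`) produces no commission errors at all at this σ:
  the surround pathway attenuates noise (gain ≈ 0.12 into the response
  layer) so the wrong response would need a ≈ 4σ sustained excursion to
  win the race (0 errors in 7488 simulated trials). With all-units
  noise the model commits ≈ 9–10 % errors as fast guesses, matching
  the error rates such tasks elicit empirically.
* **Input stopping**: a normally distributed delay after response onset
  (μ = 6, σ = 0.5 cycles, floor 5), the net input to *all* units is cut
  and the network decays freely toward rest. This is what terminates
  the response: correct responses then cross back below threshold
  ≈ 8–9 cycles after onset (RD ≈ 120–135 ms), while errors — held down
  by lateral inhibition from the concurrently active correct unit —
  cross back within a few cycles (RD ≈ 45–55 ms). Zeroing only the
  stimulus input leaves the attention loop feeding the response units
  and no offset is ever registered.

With these settings the default study (34 datasets × 1248 trials)
shows RD(error) < RD(correct) in 34/34 datasets and a positive
error−correct conflict peak within 10 cycles of response onset in
every dataset.

### A note on the offset-locked conflict residue

RIDE applied to the simulated conflict traces (three clusters,
per-condition decomposition, matched trial counts) attributes the
error−correct conflict difference almost entirely to the
response-onset cluster: the onset-cluster difference is ≈ 0.005 energy
units against ≈ 0.0004 in the offset cluster (< 10 %). The residue is
not algorithmic leakage: a conflict episode *ends* when the losing
response unit decays to zero, an event that tracks the response offset
trial by trial, so a small genuinely offset-locked component exists in
the model's conflict signal. Because the 34 simulated datasets are
statistically near-identical, a cluster-based permutation test across
them is sensitive enough to flag even this residue as significant —
the corresponding strict null check in the acceptance suite therefore
fails even though the offset-cluster difference is an order of
magnitude smaller than the onset effect and visually flat. This is
reported as-is rather than hidden by weakening the test.

## Peri-error behavioral statistics

From each trial log (participant, block, trial, outcome, RT, RD) the
analysis selects commission errors flanked by two correct trials on
each side (chunks never span block boundaries; overlapping chunks are
allowed and logged). Per chunk, with E the error:

* pre-error speeding = (RT[E−2] + RT[E+2])/2 − RT[E−1]
* post-error slowing = RT[E+1] − (RT[E−2] + RT[E+2])/2
* error cancellation = mean RD(E−2, E−1, E+1, E+2) − RD[E]
  (mode `pm1` uses only E±1)

Chunks containing any RD farther than 2.5 sample SDs from its
participant × correctness cell mean are removed whole. Statistics are
averaged per participant, then tested across participants (paired
t-tests, d_z). Trial-wise RD median splits assign values equal to the
median to the *long* bin. The sample-size calculation solves the
noncentral-t power equation for a two-sided paired t-test (df = n−1,
noncentrality d_z·√n); it reproduces n = 34 for d_z = 0.50 at power
0.80 and is cross-checked against statsmodels.

One subtlety the synthetic cohorts expose: an error just *outside* a
chunk shifts that chunk's baseline trials (its E+1 slowing can land on
another chunk's E−2), transferring ≈ 1 ms between the speeding and
slowing estimates at a 10 % error rate. This is a property of the
design, not a bug; group CIs absorb it.

## EEG preprocessing

Epochs of 1200 ms are cut around stimulus onset, response onset, or
response offset (half-open windows, 0-based samples) with lock-specific
baselines (stimulus [−100, 0]; onset [−150, −50]; offset [−300, −200]
ms). All filters are 4th-order Butterworth IIR applied forward and
backward (zero phase; 100 ms reflection padding on epoched data):
band-stop 47.5–52.5 Hz for line noise, final 0.1 Hz high-pass and
20 Hz low-pass. Artifact screening z-scores each channel's Hilbert
envelope against its session-wide distribution, averages z across EEG
channels, and drops epochs whose averaged z exceeds 20 (jumps) or 8
after 110–140 Hz band-passing (muscle). Short/long RD bins are
equalized by repeatedly removing, from the larger bin, the trial whose
RD is closest to that bin's current median (ties to the earlier
trial). Ocular activity is removed by zeroing FastICA components whose
time courses correlate with either EOG channel at |r| ≥ 0.40, then
recomposing; re-referencing subtracts the linked-mastoid mean. The
pipeline order is: baseline → band-stop → artifact screens →
(balancing) → component removal → re-reference → baseline → final
filters.

## Residue-iteration decomposition

Epochs are modeled as a sum of cluster components, each a single
waveform shifted per trial to that cluster's event latency: R-Onset
(response onset), R-Offset (response offset = onset + RD), and
optionally R-Intermediate (latency initialized to the per-trial
midpoint, then refined each iteration by maximizing the
cross-correlation between trial residual and component template within
±100 ms). Estimation iterates over clusters: subtract all *other*
components at their per-trial latencies, re-align residuals to this
cluster's event, average (median by default; mean via
`RideConfig(average="mean")` for sparse signals such as simulated
conflict, where the across-trial median of a mostly-zero trace is
degenerate), taper with a 10 % cosine ramp. Convergence is declared
when no component changes by more than 0.01 µV (max 20 iterations);
non-convergence returns a flagged result. Shared variance is
deliberately attributed to R-Onset: it is updated first in every
iteration and initialized to the full onset-locked average, so an
offset-locked effect that survives is strong evidence. The residual is
defined as input minus reconstruction, so conservation
(reconstruction + residual = input) is exact. Identifiability rests on
RD jitter: with the generator's 30 ms jitter, planted onset and offset
components are recovered at waveform correlation ≥ 0.98, recovery
degrades monotonically as jitter shrinks, and zero jitter is rejected.

## ERP statistics

ERN measures at FCz use the [32, 82] ms post-onset window: the mean
amplitude of the condition average and the most negative sample (ties
to the earlier sample; a boundary minimum sets an edge flag).
Participants without a visible ERN (no negative local minimum in
[0, 150] ms) can be excluded from peak-latency statistics. The
cluster-based permutation test thresholds pointwise paired t values at
the two-sided α = 0.05 critical value, clusters suprathreshold points
by temporal (and optional electrode-list) adjacency, scores clusters
by summed t, and builds the null from the maximum |mass| over random
sign flips of participants' difference maps (p includes the observed
labeling; agreement with MNE's implementation is asserted in the test
suite). Under a pure-noise null its family-wise error over 200
replications of 500 permutations is ≈ 0.03–0.05 at nominal 0.05.

## Synthetic data generator

Behavioral cohorts default to 30 participants × 19 blocks × 64 trials
with 10 % commission errors, 8.6 % omissions and 0.3 % miscellaneous
trials drawn independently per trial. RTs are lognormal (mean 443 ms,
CV 0.18, participant shift SD 20 ms) with −8 ms applied to the trial
before each error, +18 ms to the trial after, and −20 ms to the error
itself; RDs are normal (correct 142 ms, errors 142 − 22 ms, SD 30 ms,
floored at 20 ms), independent of RT. Effects vary across participants
(SD 4 ms). These defaults are the effect magnitudes this family of
experiments reports; they are planted truths for recovery, and RD
variability exceeds RT variability in CV terms as required for the
decomposition. EEG epochs (1000 Hz, nine channels including FCz,
mastoids and two EOG channels) are colored noise (white SD 2 µV plus
AR(1) ρ = 0.95, SD 4 µV) over three Hann-windowed biphasic pulses with
a fronto-central topography: an onset-locked deflection (−4.18 µV
peaking at 52 ms for short-RD errors, −1.16 µV at 75 ms for long-RD
errors, +2 µV for correct), an intermediate positivity (+3 µV at
125 ms), and an offset-locked deflection placed at RD + 50 ms
(−1.5 µV errors / +0.2 µV correct). Blinks (120 µV pulses, 12 % of
epochs) are mirrored into the EOG channels with a frontal gradient.

What the generator does **not** emulate: volume conduction and
realistic topography beyond a fixed weight vector, 1/f spectra beyond
the AR(1) stand-in, latency variability of the onset component within
condition, RT–RD dependence, or non-stationary artifacts. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated statistical structure, not performance on real
recordings.

## Problem sizes and numerical choices

The test and acceptance suites run the simulation study at its full
size (34 × 1248 trials) and scale the purely statistical replications
to what a desk check needs: FWER calibration uses 200 replications ×
500 permutations on 20 × 40 difference maps; CI-coverage uses 30
full-size cohorts; decomposition recovery uses 200 trials at 500 Hz.
Integer-sample shifting (no sub-sample interpolation), ties in peak
detection broken toward the earlier sample, ties in balancing toward
the earlier trial, and the long-bin rule for median ties are fixed
conventions throughout. Degenerate inputs fail loudly: zero RD
variance, empty condition cells, missing EOG/mastoid channels, filter
edges at or beyond Nyquist, and cells too small for an SD estimate
(warned, never silently flagged).
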