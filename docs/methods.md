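# Methods

This note documents the models, estimators and numerical choices behind
each stage of the chain, what the synthetic generators do and do not
emulate, and the design decisions taken where the procedure was genuinely
open. All quantities cited here are computed by the test suite or
`scripts/acceptance.py`; nothing is quoted from external data.

## Data model and units

A session directory holds `session.json` (geometry, sampling rate,
duration, unit metadata and binary shapes), `trials.csv`, `spikes.csv`,
`waveforms.bin` (float32 little-endian) and optionally `raw.bin`. Time is
seconds (float64), voltage µV, electrode geometry µm, stimulus coordinates
visual degrees with fixation at (0, 0), cursor coordinates cm. Orientation
lives on [0, 180), movement direction on [0, 360), with eight directions
at 45° spacing. Waveform snippets are `round(1.6 ms · fs)` samples, 0.4 ms
before and 1.2 ms after the peak/trough (32 samples at 20 kHz, 48 at
30 kHz). Floats in CSVs use the shortest round-trip decimal representation
and are parsed back with round-trip precision, so save→load→save is
byte-identical; this is what makes the end-to-end determinism check
meaningful.

## Synthetic generators: what they emulate

The generators define the conditions under which every downstream stage is
validated. They are pure functions of (parameters, seed); each unit draws
from a substream keyed by (seed, unit index) so enlarging a population
never perturbs existing units.

* **Orientation sessions** — homogeneous Poisson spiking within each trial
  at λ(θ) = b + a·exp(κ(cos 2(θ−θp) − 1)); defaults b = 2 Hz, a = 18 Hz,
  κ = 2, eight orientations at 22.5° spacing, 20 one-second trials per
  orientation. These values give peak rates (~20 Hz) and tuning widths
  typical of grating-driven primary visual cortex and make λ(θp) = b + a
  exactly, which the rate-recovery test exploits.
* **Direction sessions** — λ(d) = b + m·max(0, cos(d − dp)) inside the
  0–300 ms post-movement epoch and b elsewhere; defaults b = 4 Hz,
  m = 16 Hz (modulation/baseline = 4, comfortably above the 3× ratio at
  which vector-sum recovery is reliable with 20 trials per direction).
* **Coupled pairs** — the follower is an independent Poisson train plus,
  per leader spike with probability p, one spike at +L + N(0, σj²). The
  expected excess coincidence count is exactly p·n_leader, which gives the
  binomial-thinning oracle its closed form. Default conditions for
  calibration and power: 10 Hz trains, 600 s, p = 0.3, L = 2 ms,
  σj = 0.5 ms.
* **Raw traces** — biphasic templates (narrow trough, smaller rebound)
  inserted at spike times, amplitude decaying as exp(−d/40 µm) across
  channels at 30 µm pitch, plus white Gaussian noise and optional
  rectangular high-voltage artifacts. Overlapping insertions sum linearly.
* **Waveform drift** — session k scales the template by (1 + k·drift) with
  per-spike Gaussian noise: a one-parameter stand-in for slow electrode
  drift that moves PC clusters apart monotonically.
* **Cursor trials** — constant-speed steps (8 cm/s, 50 ms) toward eight
  targets 7.5 cm out (success = entering a 1.85 cm-radius disk before a
  10 s timeout), with Gaussian heading noise.

What they deliberately do **not** emulate: refractory periods (trains are
exactly Poisson, so ISI-violation fractions sit at 1 − e^(−rate·1.6 ms)
rather than ~0 — a 10 Hz unit hovers near the 2% gate by construction),
bursting, rate nonstationarity, correlated noise across channels,
electrode-motion waveform distortion beyond pure amplitude scaling, and
eye/arm kinematics. Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions, not robustness to every
pathology of real recordings.

## Preprocessing

Filters are Butterworth (SOS) applied forward-backward, so they are
zero-phase and detected peaks are not lag-shifted; the notch is an IIR
design with Q = 30 (≤1% passband ripple at ±10 Hz after the double pass).
The "background SD" for both artifact blanking and detection is the robust
1.4826·MAD estimate: spikes and artifacts inflate a naive SD, while the
MAD is essentially blind to them. Artifact removal tiles the trace into
0.1 s chunks and zeroes any chunk containing a sample beyond ±6 SD; on a
clean Gaussian trace the expected number of false exceedances is
2N·Φ(−6) ≈ 2·10⁻⁹·N, i.e. none at session scale. Detection takes one
candidate per contiguous supra-threshold run (its absolute extremum) and
enforces a dead time of one snippet length (1.6 ms), keeping the
larger-amplitude event on collision. In `sd` mode the trace is centered on
its median first, which makes the detected set invariant to constant
offsets.

## Curation

The ISI-violation denominator is the number of spikes (the "fraction of
firing events" reading); the per-interval variant is available via
`denominator="isis"`. SNR is peak-to-trough of the mean waveform over
twice the residual SD about the mean; with template amplitude A and noise
SD s this converges to A/2s, and numerically noise-free snippet sets
report +inf as a sentinel. GESD runs on each snippet's L2 distance from
the mean waveform with α = 0.05 and at most 10% of snippets removable; the
implementation follows Rosner's iterative studentized-extreme procedure
and is checked against an independently coded oracle on all fixture sizes
n ≤ 50. Gates are strict as stated (rate > 0.05 Hz, SNR > 1.5, ISI ≤ 2%),
so a unit at exactly 0.05 Hz fails and one at exactly 2% passes.
Duplicate-cluster merging considers pairs within the 100 µm adjacency
radius and merges when the coincidence fraction of the smaller train
(±0.5 ms window) exceeds 0.5 — chance coincidence for independent trains
is ≈ 2·rate·window ≈ 1% at 10 Hz, so the rule is far from its noise floor.

## Cross-session tracking

The PCA basis is fit on the pooled snippets of the session pair (default)
or the earlier session only (`basis="earlier"`); two components by
default. The cloud scale σ is the RMS per-component SD of the *earlier*
session's scores, and a pair matches when the center distance is below
2σ. A per-component Mahalanobis variant sits behind
`sigma_mode="mahalanobis"`. Assignment is greedy one-to-one by smallest
distance with ties broken by unit id, so chains built from consecutive
matches can never branch. Candidate pairs must share a primary channel or
lie within the adjacency radius — this reflects the recording geometry and
avoids O(n²) spurious comparisons.

## Visual tuning and receptive fields

OSI = (Rpref − Rorth)/(Rpref + Rorth), with Rorth taken at the grid
condition nearest 90° from the preferred one; the resultant-length
(1 − circular variance) variant is available. The preferred orientation is
the half-angle of the doubled-angle vector sum, with a NaN sentinel when
the resultant is numerically zero (flat or symmetric curves). RF maps
subtract an equal-length pre-onset baseline from each trial's evoked rate.
The RF fit is an axis-aligned 2-D elliptical Gaussian by bounded
least squares; size = 2·√(σₓσᵧ), eccentricity = distance of the center
from fixation, and `fit_ok` is false when the grid peak does not clear
twice the robust grid noise or the fit diverges. The depth model is
`rf_size ~ depth` with a random intercept and random slope per shank
(REML); depth is rescaled to mm internally so the slope variance is well
conditioned, and inference on the fixed slope uses t quantiles with
df = n_shanks − 1 because z-based Wald intervals undercover with a handful
of shanks. A non-converging or singular random-slope fit falls back to
random intercepts and is flagged.

## Preferred direction

The vector sum normalizes each FRᵢ by the maximum over directions; whether
the normalization divides each term or the completed sum is mathematically
irrelevant (same direction, same length), and the per-term reading is
implemented. The estimate is equivariant under 45° rotations of the rate
profile and invariant to rate rescaling; a uniform profile cancels exactly
over the eight equispaced angles and returns strength 0 with an undefined
(NaN) direction. Directions without trials raise an error naming the
direction rather than imputing.

## Functional coupling

CCG bins are 0.4 ms wide with centers spanning −200…+200 ms (1001 bins);
counts are follower-minus-leader time differences, and the implementation
is exactly equivalent to the O(n²) double loop (tested bin-by-bin). The
baseline kernel is a discrete Gaussian (σ = 25 bins) truncated at ±5σ with
its central weight multiplied by 0.4 and renormalized; convolution uses
reflection padding so the baseline is unbiased near the lag edges.
Significance: exact Poisson upper tail P(X ≥ k) at the positive-lag peak
(argmax over (0, 10] ms) with λ from the hollow baseline, at α = 0.01. The
causal-direction rule compares the positive- and negative-lag peaks with
an exact conditional binomial test (k⁺ against k⁺+k⁻ at p = ½). Both
conditions must hold; the conjunction is what keeps the false-positive
rate on independent pairs far below 2α even though the peak is a maximum
over ~25 bins — a common-drive pair with symmetric zero-lag synchrony
passes the Poisson test in both directions but fails the asymmetry test.
Spikes are pooled over the session; no trial-shuffle correction is
applied.

## Center-out metrics and comparisons

The acquisition point is the first sample inside the target disk (no hold
requirement); path efficiency is the straight-line distance from the start
to that sample over the traveled path length up to it, hence ≤ 1 and
invariant under rigid motions. Accuracy differences are tested by
resampling trials with replacement within each mode (2000 resamples) and
reading a two-tailed, add-one-corrected p from where zero falls in the
resampled difference distribution; fully degenerate inputs return p = 1.
Time cost and path efficiency use Mann–Whitney U (exact for small n via
scipy). Each metric's family of per-direction p-values is BH-adjusted
separately. The velocity decoder is ridge regression with an unpenalized
intercept — deliberately minimal plumbing to close the loop, not a model
of any production decoder. In closed loop the cosine-tuned population
fires toward the instantaneous cursor-to-target direction, which makes the
simulated brain-control trials self-correcting and produces path
efficiencies below 1 under Poisson noise.

## Problem sizes and tolerances

Stochastic checks run at sizes chosen to make their standard errors small
relative to the asserted margins: 1000 independent pairs for null
calibration (positive rate ≤ 2α), 100 replicates for coupling power
(≥ 0.9), direction recovery (±22.5° in ≥ 95%), and mixed-model CI coverage
(≥ 90%); 20 pair replicates per drift level for tracking monotonicity;
binomial slack of two standard errors is added where a nominal rate (5%
type-I) is itself the quantity under test. Exact identities (CCG oracle,
GESD vs Rosner, BH example, vector-sum closed forms, byte-level
determinism) are asserted with no tolerance.

## Known limitations

Isolation and noise-overlap metrics are pass-through fields from external
sorters, not recomputed. Spike clustering itself is out of scope — the
chain consumes sorted units. The coupling test's α is per-pair; no
across-pair multiple-comparison correction is applied by default. The
closed-loop simulator is a desk-scale analogue, not a behavioral model:
its accuracy ceiling is 1.0 by construction when the decoder is adequate.
LFP handling is limited to band extraction (0.3–300 Hz); no spectral
analysis is provided.
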