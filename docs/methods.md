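# Methods

This note documents the models, parameters and numerical choices behind
burstpipe, and what the synthetic-data validation does and does not
establish about real recordings.

## Behavioral model and SSRT

Stop-signal behavior is simulated under the independent horse-race model:
on every trial an exGaussian go process (defaults μ = 500 ms, σ = 50 ms,
τ = 100 ms) races a stop process of fixed latency `ssrt_true` (default
250 ms) that starts at the current stop-signal delay (SSD). A stop trial is
failed iff the go finishing time is below SSD + `ssrt_true` (or on the rare
trigger failure, probability 0 by default). The SSD staircases per
responding hand: initial 250 ms, ±50 ms after successful/failed stops,
floored at 0 — a 1-up/1-down rule whose fixed point is 50% stopping
accuracy. Trials occur every 4 s (2-s response deadline + 2-s intertrial
interval); one-third of trials are stop trials. A `p_wrong_press` parameter
(default 0) lets tests exercise wrong-button scoring and the accuracy-based
exclusion rules.

SSRT uses the integration method with go-omission replacement: omissions
are replaced by the 2000-ms deadline, go RTs sorted ascending, and SSRT =
RT at rank ⌈N·p(respond|stop)⌉ − mean SSD. Design choices where the
convention is genuinely open:

- the rank is the ceiling (discrete consensus convention, exactly testable
  against brute-force enumeration);
- one SSRT per participant, pooling hands (the staircase runs per hand but
  summary metrics are per participant); mean SSD pooled likewise;
- a median-split of correct-go RTs labels matched go trials fast/slow; RTs
  equal to the median go to "fast" (deterministic tie rule);
- wrong-side presses on stop trials count as failed stops (any press is a
  failure to stop).

Exclusion rules: blocks with go accuracy < 60% or without a single
successful stop are dropped; participants with overall go accuracy below
chance (50%) are dropped entirely. Every exclusion appears once in the
report table.

## LFP generator

Each site's background is Gaussian 1/f^α noise (spectral shaping of white
noise; α = 1 by default). Bursts are Gaussian-windowed sinusoids with
frequency drawn uniformly from 15–29 Hz, duration ~ N(130, 20) ms
(truncated at two cycles) and amplitude `burst_amp_snr` (default 10) times
the background's β-band RMS. The envelope SD is set so that the full width
at the detector's 6×-median crossing approximately equals the nominal
duration: σ_env = d / (2√(2·ln(SNR/√6))). The waveform family deliberately
resembles, but is not identical to, the Morlet detection kernel.

Burst times follow an inhomogeneous Poisson process: a per-site baseline
rate plus additive rate windows tied to each trial's go, stop or response
event, optionally restricted to trial outcomes. Defaults (free parameters;
reported group data do not constrain absolute rates in bursts/s): baseline
0.3 bursts/s at every site; +1.6 bursts/s in the 500 ms after the stop
signal on successful stops and +0.8 on failed stops at subcortical sites;
−0.25 bursts/s in ±200 ms around responses. Directed coupling rules spawn a
target-site burst at source time + lag with a stated probability (e.g.
STN→SMC at +50 ms), emulating cross-regional burst sequences. Every
injected event is logged (site, absolute center, trial, frequency,
duration, amplitude, coupled flag), and injection conservation is exact.

The dedicated timing-validation fixture concentrates stop-evoked STN bursts
in a 100–400 ms post-stop window at 5 bursts/s — the period in which
stop-related subcortical bursting is elevated — with target sites carrying
only the lagged copies, so that recovered cross-site lags measure the
coupling rules directly and first-burst latencies are tight enough to
resolve tens-of-millisecond lags at realistic group sizes (9 + 11
subjects).

What the generator does **not** emulate: biophysical burst generation,
pathological (long, high-amplitude) bursts, tremor artifacts, proactive
behavioral slowing, volume conduction between thalamic contacts, and
non-stationary background spectra. Passing recovery tests therefore show
the *estimators* are correct and well-calibrated, not that real recordings
meet their assumptions.

## Preprocessing

Fixed order: line-noise removal → downsample to 1 kHz → artifact rejection
→ bipolar montage. Line noise is removed by windowed least-squares
regression of sine/cosine pairs at the mains frequency and harmonics (2-s
windows), which tracks slowly drifting interference while leaving β-band
power intact (contract: ≥ 20 dB at the line frequency, < 1 dB at
15–29 Hz). Downsampling is polyphase with a rational rate approximation;
any input rate ≥ 1 kHz is accepted. Artifact handling marks whole 1-s
segments, either from an explicit list (stand-in for visual inspection) or
from an automatic |z| > 6 flagger; masked samples are excluded from the
median-power computation and any epoch overlapping them is dropped.
Bipolar channels are adjacent-contact differences per lead (4-contact DBS
leads give pairs 0–1, 1–2, 2–3, with 0 the ventral-most contact; thalamic
analyses use the 0–1 "ventral" and 2–3 "dorsal" arrays). The STN analysis
array is the one with the most bursts over the whole recording,
ventral-most on ties. The SMC analysis array is chosen by the localizer
score: mean β-band ERSP 200–800 ms post-go, most negative wins; arrays
without ≥ 1 dB suppression trigger a fallback to the lowest index with a
warning.

## Spectral machinery

The burst transform is a complex Morlet family with m = 7 cycles,
σ_t = m/2πf, on a 1-Hz grid over 15–29 Hz, applied to the continuous
signal with reflect padding; samples within 3σ_t of the recording edges
are flagged invalid and cannot host bursts. The amplitude constant is
A = 1/(σ_t√(2π)); since detection thresholds at a multiple of the
channel's own median power, any positive constant yields identical burst
sets. ERSP uses the filter-Hilbert method: per 1-Hz step (1–50 Hz), a
symmetric least-squares FIR band-pass of ±0.5 Hz applied
forward-and-backward (zero phase), analytic power via the Hilbert
transform, trial-averaged and expressed in dB relative to the −500…−200 ms
pre-stimulus baseline mean. dB is a display convention only; burst
detection never depends on it.

Lagged coherence at frequency f and lag n cycles tiles each epoch with
consecutive non-overlapping n-cycle windows, takes the Hann-tapered
Fourier coefficient at f per window, and computes
|Σ F_j·conj(F_{j+1})| / √(Σ|F_j|²·Σ|F_{j+1}|²) pooled over epochs
(frequencies 8–35 Hz, lags 1–4; cells with < 20 window pairs are NaN). A
sustained rhythm scores ≈ 1 at every lag; transient bursts lose phase
predictability as the lag grows.

## Burst detection and statistics

Detection operates on the continuous per-channel time-frequency power with
the per-frequency median over all artifact-free samples as threshold
anchor; bursts are then mapped into lock-relative epochs (go −500…+1500,
stop −500…+1000, response ±500 ms; matched go trials use the staircase SSD
as a virtual stop time). Detecting once on the continuous series rather
than per epoch avoids double-counting events that fall into overlapping go
and stop epochs of the same trial and lets one pass serve all lockings;
the threshold and criteria are identical. A local maximum is a TF sample
strictly greater than its 8 grid neighbors; maxima within 3 Hz and one
burst-duration of a larger accepted maximum are merged into it, so one
physiological event is counted once, at its center. Duration is the
contiguous supra-threshold run at the peak frequency containing the peak;
the minimum is two cycles at that frequency. All windows are half-open
[a, b) in ms with 0 at the locking event.

Derived quantities: per-site mean peak frequency and duration; rates per
100-ms bin and condition (successful/failed stop, fast/slow matched go);
counts in the trial-specific [SSD, SSD+SSRT) window; baseline rates in the
100 ms before go and before (virtual) SSD; first post-stop burst latencies
in (0, 1000] ms, also expressed relative to SSRT; and cross-site rates in
50-ms bins over −200…+200 ms around the first seed-site burst within
500 ms post-stop. Stop-locked and SSRT-locked analyses are computed and
reported separately. Subcortical events pool hemispheres; SMC is
restricted to the contralateral strip.

## Permutation inference

Observed F values come from the classical RM-/mixed-ANOVA
sums-of-squares decomposition (verified against an independent
implementation to numerical precision); no sphericity correction is
applied because inference is by permutation. The null randomizes condition
labels within subject (jointly over both within factors; group labels
across subjects for the between factor), default 10,000 permutations
(500–1000 in the test suite); an effect is significant when F exceeds the
null's 95th percentile and the permutation p (proportion of null F ≥
observed) is below .05 — a decision rule whose type-I error calibrates to
≈ 5% per effect empirically. Effect sizes are partial η². A single
label-randomization scheme serves main effects and interaction; exact
interaction nulls would require residual permutation, a documented
limitation. Missing cells drop the subject listwise. Degenerate
(constant) inputs return F = 0 via a floating-point dust floor at the
squared rounding error of cell means.

## Validation benchmarks and problem sizes

The validation suite (also driven by `scripts/acceptance.py`) uses one
session of 192 trials and four sites for detector recovery (~200 sparse
injected events at SNR 10; hits within ±25 ms and ±3 Hz), 1000 random
sets for SSRT oracle equivalence, five 400-trial sessions for SSRT
recovery, 1000 null datasets × 500 permutations for ANOVA calibration
(150 datasets for power at a 2-SD effect, n = 12), a 96-trial session for
cross-site lag recovery, 20 seed batches for interaction detection power,
and 60 epochs for the lagged-coherence contrast. These sizes are the
package's validation design; they keep each benchmark proportionate to one
recording session while leaving Monte-Carlo error well inside the asserted
margins.

Known limitations: the 6×-median threshold has an intrinsic false-positive
floor on Gaussian 1/f noise (supra-threshold noise excursions are
stretched by the wavelet's temporal autocorrelation and often last two
cycles), measured at ≈ 0.22 events/s; adaptive or percentile-sweep
thresholds are out of scope. EDF export is not provided; the HDF5
container and TSV tables are the interchange formats. No cross-site phase
coupling, waveform-shape metrics, or parametric race-model fitting.
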