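# Methods

## The analysis problem

Mobile brain/body imaging (MoBI) records high-density EEG together with
motion capture while participants act. In a three-stimulus visual oddball
task answered either by button press or by physically pointing at a moving
target, the sensor-level event-related potential (ERP) in the P3 window
(400–800 ms) mixes genuine brain activity with corneo-retinal potentials from
eye movements and with neck-muscle activity evoked by the pointing movement
itself. The pipeline implemented here separates these contributions: it
detects pointing movements from the finger-LED kinematics, cleans the EEG,
decomposes it into independent components (ICs), localizes each component
with an equivalent current dipole, clusters components across participants,
and quantifies each cluster group's contribution to the sensor ERP by
backprojection — as absolute variance (μV²) and percent variance accounted
for (pvaf).

Because no recordings ship with the package, a synthetic-session generator
with full ground truth stands in for the experiment; every stage is verified
against quantities the generator knows exactly.

## Synthetic sessions

A session is a linear dipolar mixture observed on a spherical head
(radius 9 cm, homogeneous conductivity 0.33 S/m). The surface potential of a
dipole is the exact Legendre-series solution of the boundary-value problem;
the series is summed to machine precision. The default montage places 128
scalp electrodes on a Fibonacci lattice over the upper cap plus a 28-electrode
neck ring (reduced counts at the desk scales below). Channels are referenced
to a vertex electrode at generation time, as in common-electrode recordings:
this reproduces the shared-reference correlation structure that the
neighbor-correlation cleaning rule relies on, and the realistic tendency of
channels adjacent to the reference to be rejected.

Trial structure follows the protocol: 70/15/15 standard/distractor/target
color changes at a uniform 1–5 s latency after trial start, a 4 s response
window, and a 500 ms hold, so non-target trials last 5.5–9.5 s (mean 7.5 s).
Response times are log-normal with means 383 ms (pointing) and 516 ms
(button); pointing responses launch a minimum-jerk forward thrust
(30 cm, 400 ms) of the finger LED with a slower return, tracker occlusions
(Poisson 0.1/s, mean 100 ms) and a hot-zone marker when the finger comes
within 10 cm of the screen plane.

Sources (defaults; all amplitudes are source-level μV before unit-norm
projection):

* four **brain** dipoles (parietal P3-like, anterior-cingulate, occipital,
  motor) with Gaussian event-locked potentials graded target > distractor >
  standard and pointing > button, plus ongoing band-limited heavy-tailed
  activity (8–10 μV RMS) that gives ICA leverage;
* two **eye** dipoles in the anterior-inferior eye region with Poisson
  saccade steps, slow pursuit, and a stimulus-locked saccadic gaze shift
  (σ = 0.12 s — a slower shift would fall almost entirely below the 1 Hz
  analysis high-pass and be invisible to the pipeline whose behavior it is
  meant to exercise);
* four **neck** dipoles, posterior-inferior, with 20–120 Hz EMG bursts
  gated by movement (largest for pointing targets, moderate for pointing
  distractors — response initiation — and near zero for button trials).
  Each burst carries a movement-locked slow potential at 40% of the burst
  gain, modeling the mechanical/movement artifact that survives trial
  averaging; pure zero-mean EMG would vanish in the ERP as 1/√n and any
  neck "contribution" would be a sampling artifact.

Background noise is spatially structured: ≥ 60 weak dipoles at eccentricity
≤ 0.55 with 1/f spectra (4 μV RMS per channel) plus 1 μV white sensor noise.
Deep placement gives the smooth spatial covariance of real recordings.

The generator stores ground truth: the mixing matrix, noise-free source time
courses, true movement onsets and RTs, and the event-locked variance each
source group injects into the −200…1000 ms window (computed by direct
epoching of the noise-free group projections, baseline −200…0 ms).

What the generator does **not** emulate: clock drift between streams,
non-stationary artifact topographies (electrode micro-movements), response
errors, cross-frequency structure of real EEG, and volume-conduction detail
beyond the single sphere. Tests passing on this ground truth therefore
validate the machinery, not claims about any specific real dataset.

## Kinematic analysis

Occluded samples (reliability 0 / missing coordinates) are repaired by
per-axis cubic splines. The screen-normal position is low-passed at 6 Hz with
a zero-phase Kaiser FIR (≥ 60 dB at 12 Hz, applied forward–backward as a
single FFT convolution with the taps' autocorrelation) and differentiated by
central differences. Movements are velocity peaks of at least 22% of the
participant's maximum finger velocity inside a 200–1800 ms post-stimulus
window, at most one per trial; the onset is the latest upward crossing of 5%
of the peak velocity before the peak (linearly interpolated), which for a
minimum-jerk pulse of duration T trails the true start by 0.0594 T. Onset
thresholds 5%…53% are swept for the RT comparison; per-trial RT(frac) is
monotone by construction. Trials whose protocol markers and detected
movements disagree (no movement within ±0.5 s of a marker, or a target
movement with no marker within 0.5 s of its offset) are excluded; the ±0.5 s
tolerance spans a full pointing movement and is symmetric because the
5%-criterion onset necessarily trails the true onset that response markers
encode. RT statistics: one-way ANOVA across response conditions with Tukey
HSD contrasts.

## EEG cleaning

Zero-phase FIR band-pass 1–120 Hz (Hamming; 1 Hz and 10 Hz transition widths)
then polyphase resampling to 250 Hz. Channels are removed when flat
(peak-to-peak < 1e-8 μV over more than 5 s) or when their median Pearson
correlation with the 4 nearest electrodes over 10 s windows falls below 0.6;
the correlation rule iterates to a fixed point because removals change
neighbor sets, making the operation idempotent. One-second windows with more
than 30% noisy channels are excised (a channel is noisy when the robust
z-score of its window RMS, against that channel's own window history, exceeds
5 — per-channel statistics survive windows where most channels are
contaminated); event onsets are remapped across excised spans. Data are then
re-referenced to the common average. Removed channels can be reconstructed by
order-4 spherical-spline interpolation (regularization 1e-5), and the same
spline defines a linear operator that places per-subject signals in the full
montage space for group averaging.

## ICA

Extended infomax with natural-gradient block updates (block 512, initial rate
0.1, annealing 0.9) on PCA-whitened data, with automatic sub/super-Gaussian
switching; average-referenced data are rank-reduced by one and the reduction
recorded. After one full pass, 1 s windows whose mean model log-likelihood
falls 4 SD below the mean are excluded and 10 further passes run on the
retained samples. The per-sample likelihood uses exactly the densities whose
score functions the updates follow (exp(−u²/2)·sech(u)/Z for super-Gaussian,
the N(±1,1) mixture for sub-Gaussian), so each pass ascends the recorded
likelihood; a pass that fails to improve it backtracks the learning rate, and
the final trace is non-decreasing. Components are normalized to unit-norm
mixing columns with positive extremum. Recovery is assessed by the Amari
index (typically < 0.01 for 3–10 super-Gaussian sources at 1e5 samples);
full-set backprojection reproduces the mean-removed input to < 1e-8 μV by
construction.

## Dipole fitting and clustering

Each scalp map (average-referenced) is fitted by a single dipole: coarse grid
search at 0.1 R steps over eccentricity ≤ 0.95 with the moment solved by
linear least squares at each grid point (leadfields precomputed and cached
per montage), then a multi-resolution local grid refinement (batched series
evaluations, 5 shrinking levels). Residual variance is var(map − model) /
var(map) across electrodes. Dipoles outside the head exclude a component
from clustering.

Component measures — per-cell ERPs, Welch spectrum (3–75 Hz), ERSP (Hann
window 256 samples, 50 ms hop, dB against the pre-stimulus mean), ITC, scalp
map (splined onto the full montage), dipole position — are each PCA-reduced
to 10 dimensions (dipole kept 3-D), z-normalized and weighted (dipole × 25,
ERSP × 10, others × 1), concatenated, and reduced to a 10-D joint space.
K-means (k = 36 at protocol scale, k-means++ with 50 restarts, seeded,
lexicographically canonicalized input so the partition is order-invariant)
partitions the components; components farther than mean + 3 SD of the
within-cluster distance distribution from their nearest centroid move to an
outlier cluster, and each cluster keeps at most one component per subject
(nearest to the centroid). Cluster groups are geometric: brain for centroid
dipoles inside 0.85 R and above z = −0.05 R, eye inside the anterior-inferior
eye balls, neck posterior-inferior below z = −0.3 R, else other.

## Contribution quantification

Signals are epoched −1…+2 s around color changes of correctly answered
trials (750 samples at 250 Hz), baseline-corrected over −200…0 ms, and
cleaned by iterative epoch rejection (|value| > 1000 μV or per-channel z > 5;
at most 5% of the current epochs per iteration, ranked by max |z|). For a
cluster set k, pvaf_k = 100·(1 − var(Σ_{j≠k} P_j)/var(Σ_j P_j)) with var(·)
the mean square over channels and window samples of the grand-average
backprojected ERP; variance windows are −200…1000 ms (group table) and
400…800 ms (brain-cluster table). pvaf can be negative under cancellation
and pvafs of a partition sum to 100 only for orthogonal projections. Group
grand averages zero-fill subjects missing from a cluster so that group sums
stay additive; the exploratory per-group ERP/envelope view instead skips and
reports missing subjects. The Pz′ analysis takes the electrode nearest the
standard parieto-central position, averages the brain-only backprojected ERP
over 400–800 ms per subject and cell, and runs a 2 (condition) × 3 (stimulus)
repeated-measures ANOVA (Greenhouse–Geisser correction gated by Mauchly's
test on the three-level factor) with Tukey HSD contrasts over the six cells.

## Desk-scale study conditions

The full protocol (12 participants, 5 × 50 trials per condition, 156
channels) is the generator default but is never run in the test suite. Two
reduced scales are defined once: `tiny` (26 channels, 30 trials/condition,
2 LEDs) for smoke tests, and `small` (60 channels, 80 trials/condition,
3 LEDs) for the group analyses, with the acceptance campaign at 3 subjects.
80 trials/condition keeps ~12 target trials per cell, enough that
trial-averaged residual saccade activity stays below the movement-locked neck
signal — the same ordering the full 250-trial protocol produces; at half that
trial count the qualitative contrast is genuinely underpowered. Subject-level
random effects are log-normal gain jitter (σ = 0.15) on every source and
normal jitter on RT means (SD 41/53 ms), values chosen to mimic
between-participant spread.

## Numerical choices and degenerate inputs

Legendre series truncate on a geometric tail bound (< 1e-13 by default,
1e-10 inside fit refinement); central dipoles use the exact n = 1 closed
form. Dipole fits require ≥ 16 electrodes and reject all-equal maps. ICA
warns below 20·C² samples. pvaf of a zero-total signal returns NaN with the
degenerate case flagged to the caller. Epoch rejection warns below 20 epochs.
Spline interpolation requires ≥ 3 retained channels within 90° of each
reconstructed electrode. All randomness flows from explicit seeds; sessions,
decompositions and reports are bit-reproducible given (config, seed).

## Known limitations

Single-sphere forward model (no skull/CSF layering, no realistic anatomy);
geometric rather than anatomical cluster labels; a single ICA model rather
than an adaptive mixture; no response-error model; the marker-consistency
rule is one admissible operationalization; group labels depend on the
fitted centroid dipole and can mislabel mixed components at low SNR. The
qualitative group-contribution pattern is assessed on 3 synthetic subjects,
so its per-cell percentages carry sampling noise even though the ordering is
stable across seeds.
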