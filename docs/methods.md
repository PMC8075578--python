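# Methods

`tectodyn` reimplements, as a tested pipeline with synthetic ground truth, a
family of analyses used to compare spontaneous and stimulus-evoked population
activity in larval zebrafish tectum calcium imaging: significant pairwise
correlations, retinotopic tuning, neural assemblies, high-coactivity
patterns, dimensionality, and the geometry of pattern subspaces.

## Recording model and epochs

A recording is a neurons × frames ΔF/F matrix at 2.2 Hz: 30 min of
spontaneous activity in the dark (**SA**) followed by a visual stimulation
period (**TEA**, total evoked activity) of 20 trials of nine 6°-spot
positions (45°–165° in 15° steps, within-trial order chosen to maximise
angular separation), each spot shown 1 s with a 20 s blank and 25 s between
trials. Within TEA, **EA** is the first 5 s after each onset and **SE**
("spontaneous within evoked") is 6–20 s after each onset; remaining frames
are unlabelled. Frame windows convert seconds to frames with half-up
rounding; indices are 0-based internally.

The evoked-epoch duration follows from the schedule: 20 × 9 × 21 s + 19 ×
25 s ≈ 70.9 min. (Published protocols of this design quote 61.6 min, which
no combination of the stated spot/blank/inter-trial durations reproduces; we
derive the duration from the schedule rather than forcing the quoted value.)

## Synthetic data generator

The generator is the pipeline's ground-truth source, not a test fixture. Its
defaults are the study conditions above; per-dataset structure:

- **Spontaneous assemblies.** `n_sa_assemblies` (default 5) disjoint neuron
  sets (default size ≈ 0.45 N / n_assemblies) fire jointly at Poisson rate
  `assembly_event_rate_hz` (default 0.02 Hz per assembly, i.e. roughly an
  event every 50 s, a realistic tectal assembly recurrence scale). Event
  amplitudes are 1.0 ΔF/F with ±20% per-neuron jitter.
- **Evoked ensembles.** `n_ea_ensembles` (default 9, one per spot position)
  sets of responsive neurons. A fraction `ea_sa_overlap` of each ensemble is
  drawn from the spontaneous assembly whose retinotopic home angle is nearest
  that ensemble's stimulus position; the remainder comes from neurons in no
  assembly, drawn without replacement globally, so `ea_sa_overlap = 0` gives
  fully disjoint memberships and `ea_sa_overlap = 1` (with matched counts
  and sizes) identical ones. This single knob controls how similar evoked
  and spontaneous structure are — the generator's handle on developmental
  divergence.
- **Retinotopy and geometry.** Each ensemble member's true preferred angle
  is its ensemble's position plus Gaussian jitter (`retinotopy_noise_deg`,
  default 5°); remaining assembly members take their assembly's home angle,
  and unaffiliated neurons are uniform over the stimulus range. Soma
  positions place the preferred angle linearly along the major axis of the
  neuropil ellipse (emitted as a polygon contour, rotated 20° so the
  axis fit is non-trivial), with uniform scatter along the minor axis.
- **Evoked responses.** At each presentation every responsive neuron receives
  an impulse `evoked_amplitude · exp(−(pref − θ)² / 2σ²)` (σ =
  `tuning_sd_deg`, default 15°) with ±20% trial jitter.
- **Calcium and noise.** Impulse trains are convolved with a
  single-exponential kernel `exp(−t/τ)`, τ = 1.8 s (nuclear-GCaMP6s-like
  decay at 2.2 Hz; the rise time is below one frame and not modelled), then
  white Gaussian noise of SD `noise_sd` (default 0.05 ΔF/F) is added.
- **Stimulus-dominated windows.** Assembly events are suppressed from 3τ
  before each onset until 5 s after it: the evoked window is treated as
  stimulus-dominated, and the 3τ guard keeps calcium tails of earlier
  spontaneous events from leaking into it. The assembly process continues
  everywhere else, which is what makes SE activity resemble SA.

All randomness descends from one `SeedSequence(seed)` with per-stage spawned
streams; identical configurations are bit-identical.

**Movie mode** renders disk somata (pixel value = baseline + resting-contrast
+ 80 × ΔF/F inside each disk) with Gaussian PSF blur and sqrt-scaled
shot-like noise, returning per-neuron masks as ground truth. The resting
contrast term (default 30 over a baseline of 100) is the static anatomy that
rigid registration locks onto. An optional minimum-separation relaxation
nudges rendered somata apart; the retinotopic band placement otherwise
collides disks, and physically coincident somata are unresolvable by any
correlation-based segmentation.

**What the generator does not emulate.** No spike-to-fluorescence
biophysics, rise kinetics, bleaching, neuropil contamination, non-rigid
motion, eye/tail movement, or overlapping somata in depth. Passing tests
therefore show that the analysis recovers the structure this model encodes
at the stated noise levels — not that it is robust to every artefact of real
recordings.

## Analysis stages

**Cell detection** (movie mode): rigid integer-pixel registration against a
reference frame (phase correlation on lightly smoothed frames; circular
translation so injected drifts invert exactly; constant frames tie-break to
zero shift). The activity map is the per-pixel temporal SD of the
high-pass-filtered series; it is thresholded (Otsu by default, overridable)
and watershed-segmented from local maxima. Within each region, every pixel's
trace is correlated with the mean trace of the most active pixel and its 8
neighbours; a 2-component Gaussian mixture on the correlations yields a cut
at the posterior crossing between the component means. The cut is applied
only when the mixture is genuinely bimodal — Ashman's D > 2 **and** a
component-mean gap ≥ 0.4 — because surround pixels are near-uncorrelated
with the cell while the within-cell continuum (bright centre vs dim edge) is
narrow; a homogeneous region is kept whole. Regions are re-refined on their
remainder so merged somata yield multiple ROIs. ROIs below 26 pixels
(5.5 µm² at the reference scale of ≈0.46 µm/px) are rejected; raw traces are
ROI-pixel means.

**ΔF/F**: the baseline curve is a running 20th percentile over a 30 s window
(the "smoothed curve through the lower 20% of points"; both windows
configurable), and F0(t) is the minimum of that curve in a 3 s window
centred on t, edges truncated. ΔF/F = (F − F0)/F0, undefined (an error) if
F0 ≤ 0.

**Binarization**: per neuron, active = ΔF/F strictly above mean + 2 SD, with
statistics over the full recording — a single threshold keeps SA and TEA
coactivity comparable (a per-epoch variant would renormalise away the
effect being measured). Zero-variance neurons give all-zero rows, flagged.

**Correlations**: Pearson on epoch-restricted ΔF/F. Significance by the
SHIFT surrogate: each surrogate circularly shifts every neuron's trace by an
independent uniform offset ≥ 1 frame, preserving within-neuron temporal
structure exactly (the value multiset is invariant) while destroying
between-neuron alignment. All pairwise coefficients over all surrogates
(default 1000) form one pooled null; observed r above its 95th percentile is
significant (one-sided — the procedure targets excess positive
correlation). Distance profiles average significant r in half-open 50 µm
bins; matrix similarity is the Pearson correlation of the vectorised upper
triangles of two correlation matrices (all entries by default, a
significant-only flag exists).

**Tuning**: response amplitude = mean ΔF/F over frames +4…+7 after onset
(≈1.8–3.2 s, where the kernel tail lives), averaged per position; natural
cubic spline onto a 5° grid; Gaussian-with-offset fit restarted from σ ∈
{5, 10, 20, 40, 80}° with μ started at the grid argmax and bounded to the
grid ± 15°; best restart by adjusted r² (n = grid size, p = 4). Selective ⇔
adjusted r² > 0.7 (strict); preferred = fitted μ clamped to the grid.
Neurons whose true preference sits at or beyond the sampled stimulus
boundary have truncated peaks that no estimator can localise; recovery
statements therefore refer to neurons preferring at least half a stimulus
step inside the range.

**Assemblies**: the detector interface takes the SHIFT-significance graph
(nodes = neurons, edges = significant positive correlations weighted by r)
and partitions it; the baseline is greedy modularity maximisation
(networkx), communities under 5 members discarded. The cited
graph-theoretic detector of the original analyses can be plugged in as a
callable. Statistics: centre of mass; its projection on the AP axis (major
axis of a least-squares ellipse fit to the neuropil contour, anterior = the
end nearer the coordinate origin by convention, flag documented) rescaled to
[0, 1] and clipped; spatial coverage = member convex-hull area over the
all-cells hull area; tuning mean/variance (sample variance, n−1) over ≥ 2
selective members. Overlap between assembly sets is |A∩B| / min(|A|,|B|),
best match per evoked assembly, averaged (Jaccard and Hungarian one-to-one
matching available by flag).

**Patterns and geometry**: coactivity = per-frame active count. Each of 500
surrogates permutes every raster row independently (per-neuron counts
preserved exactly); the threshold is the smallest count whose pooled
surrogate tail is below α = 0.05, and frames at or above it are significant
(a per-surrogate-maximum null is available by flag; integer counts make the
achieved level the largest attainable below α). Patterns are the binary
population vectors at strict local maxima of the count series (plateaus take
their first frame) at or above threshold, assigned to their frame's epoch
(ΔF/F-valued patterns by flag). Dimensionality K80 is the number of
principal components of the epoch-restricted, mean-centred ΔF/F reaching
80% variance. Cross-epoch similarity is the mean cosine similarity over all
cross-set pattern pairs (best-match flag available). A pattern set spans a
subspace H with orthonormal basis U (SVD, rank tolerance 1e-10 relative);
P = UUᵀ, and the unexplained fraction of a pattern p is ‖(𝟙−P)p‖/‖p‖,
clipped to [0, 1] against roundoff. The balanced analysis equalises pool
sizes per repeat (default n_select = the smallest pool of the dataset at
hand): SA/SE subsets uniform without replacement, the EA subset a consecutive
run from a uniform start (no wrap) so all stimuli stay represented; each
epoch's subspace is rebuilt per repeat and every pattern of the two other
epochs' full pools is projected; 200 repeats by default. '1 − P_X' pools the
two target epochs' patterns (weighted by pool size).

## Numerical conventions

Strict inequalities at the r² = 0.7 and binarization thresholds; half-up
rounding for frame windows; ties in constant-frame registration resolve to
zero shift; degenerate GMM falls back to keeping the region; empty bins,
empty assembly sets and missing tuning fields are NaN, never exceptions;
percentiles are numpy linear interpolation. The coactivity threshold is
reported with the pooled null mass it admits.

## Problem sizes in tests and the reproduction script

The test-suite and `scripts/acceptance.py` run the same machinery at sizes a
laptop handles in minutes: 60–100 neurons, 5–15 min SA epochs, 4–10 trials,
100–1000 surrogates, with the full 20-trial protocol exercised where only
the schedule matters. These are the package's own verification sizes; every
quantity is recomputed from freshly generated data at run time.

## Known limitations

- The baseline community detector is a stand-in for the cited
  graph-theoretic assembly algorithm; it recovers planted memberships at
  Jaccard ≈ 0.9–1.0 under the generator's conditions but carries the usual
  modularity caveats (resolution limit, occasional splits of large cliques,
  noise-neuron attachment at the 5% false-edge rate of the SHIFT mask).
- The anterior/posterior polarity of the AP axis is a convention; only
  within-dataset comparisons of com_ap are meaningful.
- Group-level statistics across fish/ages are out of scope by design: the
  pipeline emits per-fish metric tables for external testing.
- The evoked-window suppression of spontaneous events is a generator
  simplification; in real data spontaneous and evoked drive superpose, and
  measured evoked/spontaneous assembly overlap is correspondingly noisier.
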