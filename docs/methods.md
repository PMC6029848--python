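# Methods

`openarena` implements the standard analysis chain for single-unit
recordings in open arenas — real or virtual-reality (VR) — together with a
synthetic-session generator that gives every stage a known ground truth.
This note documents the models, the conventions and defaults, the design
choices that were genuinely open, and what the synthetic validation does and
does not establish about real data.

## Conventions

* Lengths in cm, times in s, angles in degrees, rates in Hz.
* Square arenas: origin at a corner, positions in `[0, width]²`.
  Cylinders: origin at the centre, positions inside radius `width/2`.
* Angles are counter-clockwise in `[0, 360)`, 0 along +x.
* Theta phase is 0° at the oscillation peak and increases within the cycle.
  Precession slopes flip sign under the opposite convention, so this is
  fixed package-wide.
* Head direction (`hd`, from the tracked LED pair or the synthetic heading)
  and running direction (`run_dir`, from displacements) are distinct signals:
  directional tuning of cells uses `hd`; behavioural directionality uses
  `run_dir`. In VR the head can rotate freely while the path is driven by
  the ball, so conflating the two would break exactly the comparisons this
  package exists for.

## Position preprocessing

Tracking gaps up to 0.5 s are filled by linear interpolation per channel
(x, y, and unwrapped head direction); longer gaps stay masked. Positions are
then smoothed with a 400 ms boxcar. At the 50 Hz sampling rate this window
is 20 samples — an even number — so the package uses the symmetric variant
with half-weight end taps (21 taps, total weight 20): a centred window that
leaves linear motion unchanged in the trial interior, which an asymmetric
even-length window would not. The window is truncated and renormalised at
trial edges and around masked samples, so smoothed positions never leave the
convex hull of the valid samples in the window.

Speed and running direction come from forward differences of the smoothed
positions; the sample rate of 50 Hz makes chord-vs-arc errors negligible at
mouse running speeds. Behavioural summary metrics (Rayleigh vector of
running direction, mean absolute direction change, path excess ratio,
quadrant dwell) operate on the trajectory down-sampled to 2.5 Hz.

## Rate maps and directional tuning

Locational rate maps use 1.5 × 1.5 cm bins; spike and dwell maps are
smoothed separately with a 5 × 5 boxcar and divided. The boxcar is applied
in a **mass-preserving** form: each bin's content is spread evenly over the
in-arena bins of its window, so column sums of the smoothing operator are 1.
This conserves total spike count and total dwell exactly, keeps the ratio
estimate unbiased at walls (where occupancy is over-represented), and
guarantees the smoothed peak rate never exceeds the raw peak rate. Bins
never visited are NaN.

Directional tuning uses 6° bins with a 5-bin circular boxcar on both the
spike counts and the occupancy. Neither the directional bin width nor the
smoothing length is principled; both are configurable and these defaults are
the common choice for this class of analysis.

Firing fields are connected components of bins at or above 50% of a local
peak, seeded at 3 × 3 local maxima in descending peak order (a stronger
field claims its bins first); the single-number "field size" is the
fraction of arena bins at or above 50% of the map's global peak. Field
detection requires a peak of at least 1 Hz and 4 bins by default — purely to
suppress noise bumps — and analyses that follow fields (per-field
directional information, phase precession) additionally restrict to fields
with peaks above the 2 Hz classification criterion.

## Spatial autocorrelation, gridness, grid scale

The spatial autocorrelogram is the Pearson correlation of the smoothed rate
map with itself at every integer bin offset, computed over the bins visited
in both copies; offsets with fewer than 20 overlapping bins are NaN. The
implementation is FFT-based and vectorised over stacks of maps because the
shuffle classifier needs a thousand correlograms per cell; the shuffled
stacks run in single precision (differences ~1e-6, far below any decision
threshold).

Gridness: the annulus between an inner radius (the first radius at which the
azimuthal mean of the correlogram falls below 0.2, bounding the central
peak) and an outer radius (1.25 × the median distance of the six nearest
positive local maxima, capped at the inscribed disc) is correlated with
itself rotated by 30°, 60°, 90°, 120° and 150°;
`gridness = min(r60, r120) − max(r30, r90, r150)`. When fewer than three
peaks are found inside the disc the outer radius is swept over seven values
and the maximum gridness taken. Grid scale is the median distance of the six
nearest peaks, in cm. All radii, thresholds and the peak-count fall-back are
keyword arguments: the construction is conventional, not unique, and
different labs use slightly different variants.

## Scalar metrics

Spatial information is the Skaggs measure
`Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` (bits/spike) with `pᵢ` the smoothed dwell
fraction; directional information is the same formula over direction bins
with occupancy weights. The Rayleigh vector is the rate-weighted resultant
length of the bin-centre unit vectors. Tuning width is the angular extent of
the contiguous region around the peak above half of (peak − baseline), with
baseline the curve minimum and linear interpolation at the crossings.
Map similarity for rotation probes is the Pearson correlation over bins
finite in both maps, with 180° rotation implemented as point reflection of
the bin grid; for head-direction cells (spatially flat maps) the analogous
probe statistic is the correlation of the two tuning curves after circular
rotation.

## The pxd (place × direction) model

Directional tuning measured by naive binning is confounded when directions
are sampled inhomogeneously inside a locational field. The pxd model fits
spike counts in joint (space, direction) bins as Poisson with intensity
`λ(i,θ) = pᵢ · d_θ · t(i,θ)` — a locational rate times a dimensionless
directional gain times the joint occupancy. Alternating closed-form updates
(iterative proportional fitting: each factor's update is the ratio of
observed to expected spikes marginalised over the other factor) maximise the
likelihood; each update is an exact block maximisation, so the
log-likelihood is non-decreasing, which the implementation asserts. The
multiplicative gauge (p·c, d/c) is fixed by renormalising the directional
gain to mean 1 over sampled bins after every sweep. Spatial bins are
coarsened to 7.5 cm (5 × 5 merge of the map bins) and directional bins to
12°, keeping the joint occupancy dense enough for stable maximum likelihood;
unvisited joint bins contribute no likelihood terms. Convergence: relative
log-likelihood change below 1e-6, at most 500 sweeps, deterministic flat
initialisation. The pxd directional information applies the Skaggs formula
to the directional gain scaled by the overall mean rate, weighted by
directional occupancy — directly comparable with the naive binned value.

A directional gain is identifiable only where place-weighted exposure
exists: if a direction is never sampled where the cell fires, its gain is
driven to zero rather than flagged. The synthetic de-confounding scenario
(biased crossing loops) therefore samples every cardinal direction inside
the field, with eastward crossings over-represented 3:1.

## Shuffle classification

The null for every statistic is a rigid circular shift of all spike times
relative to the trajectory by a single uniform draw from
`[4 s, T − 4 s]`, wrapping modulo the trial duration: spike-train temporal
structure is preserved exactly (the inter-spike-interval multiset changes
only at the wrap point) while the relation to behaviour is destroyed. A cell
is classified when its observed statistic strictly exceeds the 99th
percentile (linear interpolation between order statistics) of 1000 shuffles:

* place — spatial information, plus peak rate > 2 Hz;
* grid — gridness, plus peak rate > 2 Hz;
* head direction — Rayleigh vector length against the pooled population
  shuffle distribution ("population shuffling": all cells' shuffled values
  pooled into one null whose 99th percentile is a common threshold); a
  per-cell mode is also available;
* speed — Pearson r between running speed and the instantaneous rate
  (spike count per 20 ms position sample divided by 0.02 s).

Cells with fewer than 100 spikes are flagged `low_count` and not classified.
The shuffled statistics are produced by a vectorised engine sharing one set
of shuffle offsets across all four statistics per cell; it reproduces the
observed-statistic pipeline exactly (unit tests compare it against
statistics computed through single explicit shuffles). Under a homogeneous
Poisson cell the observed statistic is exchangeable with its shuffles, so
each classifier's false-positive rate is the nominal 1%; the acceptance
suite verifies this, and the uniformity of the empirical shuffle p-values,
over 150 simulated Poisson cells on a 10-minute foraging trajectory (sizes
chosen to keep the full calibration around five minutes on one core — the
binomial acceptance regions account for the sample size).

## Theta analysis

Instantaneous theta phase and frequency come from the analytic signal
(Hilbert transform) of the zero-phase band-passed LFP (3rd-order Butterworth
run forward and backward, band 6–12 Hz by default); the frequency is the
phase derivative, median-filtered over 50 ms, with out-of-band samples
masked. Speed–frequency profiles average the instantaneous frequency in
2.5 cm/s speed bins from 2.5 to 30 cm/s and fit a count-weighted line
through the bin means; speed–rate profiles do the same with the
instantaneous firing rate.

Spike-train rhythmicity: the distribution of spike-time lags in (0, 0.5 s]
is fit by maximum likelihood with a damped cosine density
`f(ℓ) ∝ (1 + a·cos(2πfℓ))·e^(−ℓ/τ)`; the theta index is the modulation
depth `a` and the intrinsic frequency is `f`. The likelihood is evaluated on
a 1 ms lag histogram (numerically equivalent at that resolution); the
frequency landscape is multimodal, so a dense (f, a, τ) grid seeds an
L-BFGS-B polish that is never allowed to end worse than its seed. A cell is
theta-modulated when `a` exceeds the upper 95% bound of the index from
homogeneous-Poisson surrogate trains with the same spike count and duration.
A rigid time shift cannot serve as this null — it leaves the lag
distribution unchanged — so the surrogate null is used instead; on Poisson
input the false-positive rate is the nominal 5%.

## 2-D phase precession

Each trajectory pass through a detected field (contiguous in-field segments
of at least 3 samples) is mapped radially onto the unit disc: positions are
scaled by the distance from the field peak to the field edge along their
direction, where the edge is the half-max contour located on the bilinearly
interpolated smoothed rate map (sub-bin precision). Each spike's `pdcd` is
its normalised position projected onto the unit vector of the instantaneous
running direction — −1 entering, 0 at the peak, +1 leaving — and its phase
is interpolated from the analytic LFP phase at the spike time.

The circular–linear fit chooses the slope (bounded at ±720°/pdcd unit) that
maximises the resultant length of the phase residuals, via a 1°-resolution
grid followed by bounded refinement; the offset is the circular mean of the
residuals at the optimum; the reported correlation is the circular–circular
correlation between observed and fitted phases with a permutation p-value.
Fits require at least 30 spikes. Slopes are reported in degrees per pdcd
unit (a full −1 → +1 traversal spans 2 units). A bootstrap CI for the slope
resamples (pdcd, phase) pairs; note phases within a pass share trajectory
noise, so single-cell CIs understate field-level variability — population
claims should aggregate across cells, as the acceptance suite does.

## The synthetic-session generator

The generator supplies the statistical structure the analyses assume, not a
biophysical model:

* **Trajectory** — speed follows a mean-reverting (OU) process around
  12 cm/s (typical for trained mice foraging) with relaxation time 1 s and
  stationary spread 40% of the mean; heading performs a small-step random
  walk (1.6 rad/√s) with specular wall reflection; an optional
  wall-following torque emulates thigmotaxis. Head direction equals motion
  direction plus 3° of wrapped-normal noise (the head is free only to rotate
  horizontally). These dynamics are a judgement call — the recorded
  behaviour is described only statistically — and the defaults reproduce
  plausible speeds, coverage and path tortuosity.
* **Spikes** — inhomogeneous Poisson by thinning at the 50 Hz trajectory
  rate (piecewise-constant intensity; counts per 20 ms sample, placed
  uniformly within the sample). Rate functions: Gaussian place fields;
  grid fields as the rectified, normalised sum of three plane-wave cosines
  at 60° offsets (field half-max radius ≈ 0.195 × spacing); von Mises
  head-direction tuning scaled to the peak rate; linear speed–rate coupling;
  optional multiplicative directional modulation `1 + m·cos(θ − θ₀)` on
  place/grid cells. Thinning correctness is verified by time-rescaling:
  rescaled inter-spike intervals pass a KS test against Exp(1).
* **LFP** — a phase-continuous cosine whose instantaneous frequency is
  `base + slope·v(t)` (defaults 8 Hz and 0.08 Hz per cm/s) plus white noise.
* **Precession** — spikes within 1.5 field-extents of a field centre have
  their times nudged within the theta cycle so the phase scatters
  (wrapped-normal, 40° sd) around a target sweeping linearly from 360° to 0°
  across the field (`target = 180° − (range/2)·pdcd`, pdcd clipped to ±1 so
  the sweep saturates at the half-max edge). The nudge is iterated three
  times because moving a spike in time moves it in space; without the
  iteration the achieved phase corresponds to a slightly stale position and
  the measured slope is attenuated by a few percent. This is a purely
  phenomenological implementation of the phase–distance relation; it asserts
  no mechanism.
* **VR manipulations** — a paired real/VR session generator applies the
  contrasts of interest to the VR member: place-field sigma × 1.44 and grid
  spacing × 1.42 (the measured expansion factors, used here as generative
  defaults so the pipeline can be required to recover them), optional added
  place-cell directionality, theta–speed slope scaling, and a 180° rotation
  of all spatial tuning about the arena centre.

Generative parameters are stored in the session container (`ground_truth`)
for recovery tests. Everything is deterministic under a fixed seed.

**What the synthetic validation does not show.** The generator omits, among
other things: spike-sorting contamination and drift, theta-nested gamma and
other LFP structure, conjunctive coding beyond a multiplicative directional
gain, over-dispersion relative to Poisson, behavioural state changes within
a trial, and boundary-driven distortions of real place fields. Passing
tests therefore establish that the *estimators* are correct and calibrated
under their stated assumptions — not that those assumptions hold in any
particular recording.

## Problem sizes and determinism

The validation suite uses 10-minute sessions for calibration (150 Poisson
cells × 1000 shuffles × 4 statistics) and 40-minute sessions where estimator
bias matters (field-expansion and precession recovery, where short sessions
leave visible small-sample bias in field-edge estimates). The acceptance
script mirrors these analyses at slightly smaller cell counts. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
results are reproducible bit-for-bit on a given platform, and within
documented statistical tolerances across platforms.

## On-disk format

No public raw data accompany the recordings these analyses target, so the
session container is a neutral plain-text directory (YAML config, CSV
positions, one spike-time column per cell, one LFP column, optional JSON
ground truth) with 17-significant-digit floats for bit-exact round trips.
Native acquisition formats are out of scope; an adapter only needs to
produce these files.
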