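# Methods notes

This note records the models, parameter choices and numerical decisions
behind `hippo2p`, the limits of what the synthetic-data tests establish,
and the places where the published procedure under-determines an
implementation and we had to choose.

## Behavior processing

Tracker samples arrive faster than the 10 Hz stored imaging rate (the
synthetic sampler runs at 4×, i.e. 40 Hz), so each imaging frame reduces
its samples to a median — an ordinary median for speed, heading and x/y,
and a circular median for the polar angle. The circular median minimizes
the summed angular distance over candidates drawn from the sample; ties
are resolved by the circular mean of the minimizers, so {350°, 10°}
yields 0°. Empty frames carry the previous frame forward and are flagged.

Movement filtering smooths speed with a 0.5 s boxcar (the window length
is our choice; only "smoothed" is prescribed), keeps runs above 20 mm/s
longer than 1 s, and dilates each kept run by 0.5 s. A lap is a full 2π
of net accumulated rotation from the previous lap boundary — "net" so a
brief direction reversal does not end a lap; partial laps at the session
edges are dropped. Laps whose mean instantaneous speed exceeds 180 mm/s
are excluded from tuning, because slow calcium signals cannot be
attributed to ~0.85 cm bins at such speeds.

## Trace processing

Neuropil subtraction uses
F_corr(n) = F_soma(n) − α·(F_np(n) − mean(F_np)) with α minimizing the
**absolute** Pearson correlation between the corrected trace and the
neuropil trace on [0, 1]. The absolute value is our reading: the signed
correlation is monotone in α, so signed minimization would always return
the boundary. The minimizer has a closed form (the regression slope,
clipped to [0, 1]); the grid search is retained as the documented
procedure and the closed form refines it.

F₀ is the first (lowest-fluorescence) mode of a Gaussian KDE of the
corrected trace. We use the *robust* Silverman bandwidth
(0.9·min(sd, IQR/1.349)·n^(−1/5)): transient-rich traces have a large raw
SD that would smear the narrow baseline mode into the decay shoulder and
bias F₀ upward. Peaks need 2% of maximum height and 1% prominence to
count, which suppresses ripple modes below the baseline. For cells that
fire continuously (sustained speed-modulated cells), the trace rarely
revisits baseline and the first mode can still sit high; correlation- and
information-based statistics downstream are invariant to the resulting
affine miscalibration of ΔF/F, which is why this failure mode is
tolerated rather than patched with a percentile heuristic.

Deconvolution treats the transient as an AR(2) kernel with poles
exp(−Δt/τ_decay), exp(−Δt/τ_rise); defaults τ_decay = 1.5 s,
τ_rise = 0.1 s at the frame rate, matching a slow genetically encoded
indicator. The solver inverse-filters the trace to innovations, estimates
the innovation noise scale by the normal-scaled MAD, thresholds at 3
noise units to find the active set, then re-fits the active amplitudes by
nonnegative least squares against the kernel (skipped in favor of the raw
thresholded innovations when the active set exceeds 800 frames, where the
joint refit no longer changes the result materially). On noiseless input
this recovers event times and amplitudes exactly; under noise it keeps
the reconstruction residual within 1.5× the noise level.

QC flags (mean inferred event rate while moving: > 10/s high, < 1/s low)
are advisory only; nothing is excluded without an explicit config choice.

## Place- and speed-cell classification

Spatial tuning curves divide per-lap, per-bin activity by occupancy time,
using moving frames of kept laps; unvisited bins are missing and the
mean curve ignores them. **Tuning uses the deconvolved rates, not ΔF/F**:
at ~10 cm/s a 1.5 s decay drags ΔF/F several bins past the field in the
running direction, biasing centers and widths; deconvolution removes the
kernel and restores event-time alignment. The speed score stays on ΔF/F,
as the SC procedure prescribes.

The consistency gate draws 500 random equal splits (⌈L/2⌉/⌊L/2⌋ for odd
lap counts; the split RNG is independent of the shuffle RNG), and a null
of 500 iterations of per-lap circular permutation (shift uniform on
1..71 bins) followed by a fresh split. Gates: two-sample two-sided KS
p < 0.01 AND Cohen's D = (mean_real − mean_shuf)/pooled_sd > 0.5.

A property worth knowing: the split-half correlation of group means
amplifies the session's realized mean inter-lap correlation by roughly
half the lap count, so on strictly white-noise curves the consistency
gate alone fires in a quarter to a third of sessions — it is not a
calibrated α-level test on its own. The false-positive guarantee belongs
to the **full** classifier: with each lap's activity circularly
time-shuffled, consistency and the Gaussian criteria together label 0%
of cells as place cells (the acceptance script recomputes this), and
untuned cells in intact sessions pass at ≤ 2%.

The Gaussian fit recenters the curve on its peak bin before least
squares, so fields straddling the track origin fit correctly; B is
reported modulo the circumference. Adjusted R² uses p = 4 parameters.
When A₀ ≤ 0, criterion A/A₀ > 0.5 is evaluated with A₀ clamped to 10⁻⁶
and the fit is flagged. The field center reported for a classified PC is
the fitted B (sub-bin accurate; the raw argmax of a broad noisy curve
jitters by several bins), with the argmax bin as fallback.

Spatial information follows the occupancy-weighted formula, zero-rate
bins contributing nothing; it is undefined (the cell is excluded) when
the total inferred rate while moving is zero.

## DG-to-CA1 axis

The cell-body layer is summarized by y = a(x−b)² + c fit at rotations
0..179° in 1° steps, keeping the rotation with maximal R²; the parabola
peak, de-rotated, is the inflection point. Each cell's coordinate is the
signed arc length along the curve from the inflection to the nearest
curve point (nearest point via a coarse grid plus scalar minimization;
arc length by adaptive quadrature — a dense-polyline oracle agrees to
1%). Cells beyond ±600 μm are excluded from the statistics.

The sliding-window profile defaults to 200 μm windows stepped 50 μm
(unpublished; config-exposed), with 1000-resample bootstrap s.e.m. and a
1000-permutation shuffle band (2.5–97.5%). The flat-model test uses 5
equal-width bins over ±600 μm — the published degrees of freedom
F(4, ·) imply five — and the standard nested-model F statistic; an exact
zero full-model RSS with nonzero reduced RSS reports F = ∞, p = 0, and
perfectly flat data reports F = 0, p = 1.

## Spines

A z-stack collapses to a composite by translation-registering each plane
to the center plane and averaging with normalized Gaussian weights over
plane index (σ = 1.5 planes). Registration mean-subtracts and
Hann-windows the planes and uses classic (non-phase-normalized) cross
correlation with 20× upsampling: phase normalization is unreliable on
smooth low-texture planes, and edge discontinuities otherwise bias the
sub-pixel peak (recovered shifts are good to ~0.05 px on smooth test
images).

Binarization subtracts a large-kernel (σ = 20 px) Gaussian background,
clips the negative halo to zero so Otsu sees background-vs-structure
rather than halo-vs-background, thresholds globally, optionally unions in
"rescue" components above user-specified fractions of the Otsu threshold
inside user ROIs (the automated stand-in for the published manual rescue
step), and drops objects below 1 μm².

The shaft is recovered by a morphological opening (radius 10 px by
default — larger than any spine head's half-width, smaller than the
shaft's) and skeletonized to 1 px; dendrite length is the skeleton pixel
count times μm/px (default 52/760 ≈ 0.0684). Spines are the connected
components remaining after removing a corridor: the skeleton dilated to
the shaft's median half-width. Per spine: base = pixels adjacent to the
corridor; length = base-midpoint to farthest pixel; that axis is divided
into three equal segments, the distal third being the head (circularity
4πA/P²). Aspect ratio divides length by the component's full extent
perpendicular to the axis. Neck length is the longest contiguous run of
axis slabs, proximal to the head third, whose width is below half the
head width — the literal "middle third" reading (neck = length/3) is
available via `neck_mode="thirds"` but collapses the classification
thresholds, so the width-based measure is the default.

The published class thresholds are implemented verbatim and are
internally inconsistent with the area rule: a spine whose farthest pixel
is under 0.7–0.8 μm from its base fits inside a half-disc of ≤ 1.0 μm²
and can never pass the > 1 μm² inclusion filter, so image-extracted
spines only ever classify as stubby, mushroom, or fallback-thin; the
thin/filopodium rules are reachable for directly constructed
morphometric records (and are tested there). All thresholds are
config-overridable.

Cross-day matching is greedy by arc position along the shaft (closest
pairs first, within 1 μm), with an optional curation mapping that
overrides the automation. Lost-then-refound spines count as new by
default, making the survival curve monotone. Turnover percentages use the
day pair's mean spine count; per-class turnover is normalized to the
day's total cumulative turnover with a divide-by-zero guard.

## Optics

Bead detection thresholds halfway between the median background and the
maximum, labels blobs, and keeps intensity centroids that are ≥ 25 px
from their nearest neighbor and do not touch the first or last z-plane.
Each kept bead is refined by center-of-mass in a fixed window (7 px
laterally, 9 planes axially), shifted to the grid by linear
interpolation, peak-normalized (making the measurement
amplitude-invariant), and averaged; FWHM is read off the central
row/column of the averaged XY and XZ profiles by linear interpolation at
half maximum after subtracting the profile-border median.

The theoretical model converts NA to Gaussian 1/e widths with the
two-branch lateral formula (the published branch switch at NA = 0.7 is
mildly discontinuous, ~2%, and is reproduced as printed) and the axial
formula in a medium of index n = 1.33; FWHM = 2√(ln 2)·ω. The effective
NA of the implanted prism is modeled as beam clipping: half-angle
atan(aperture/2 ÷ glass path) inside the glass, converted with the
invariant n·sinθ and capped at the objective NA (0.8). For the two prism
variants (1 mm face / 2 mm path; 1.5 mm face / 2.5 mm path) this model
gives theoretical axial FWHMs of 11.4 and 8.0 μm at λ = 920 nm — within
~5% of the published theoretical values (10.9 and 7.7 μm), whose exact
NA derivation is not stated; the residual discrepancy is documented, not
tuned away.

## Histology

Each cell centroid maps to its minimal Euclidean distance from the
implant-face segment (distances beyond the segment ends use the nearest
endpoint). Densities are binned at 50 μm on the implant and mirrored
control sides; percent change is (implant − control)/control × 100 per
bin, undefined where the control bin is empty. The bootstrap resamples
each side's whole distance vector with replacement (1000×) — resampling
whole vectors rather than within bins is our choice where the published
text is ambiguous — and reports 2.5–97.5 percentile intervals.

## Synthetic data: what it emulates and what it does not

The behavior sampler alternates run epochs (8–20 s at 80–140 mm/s with
±15% slow modulation) and rest epochs (2–5 s near zero), sampled at 40 Hz
and integrated into angle on the track midline. Place fields are von
Mises bumps parameterized by their FWHM (default 18.8 cm, a typical CA1
field width on this track) — von Mises rather than Gaussian so the
generator itself has no wrap artifact at the origin. Default cell
mixture: 25% place, 10% speed, 5% conjunctive (typical CA1 proportions).

Events are Poisson with peak in-field rate 2 /s over a 0.05 /s floor
(speed cells ramp 0.8–1.5 /s per 100 mm/s, half negatively; untuned
cells 0.3 /s), with lognormal amplitude jitter (cv ≈ 0.25) around a
0.5 ΔF/F transient amplitude. These rates keep traces returning to
baseline between transients — the regime in which a first-mode F₀ is
identifiable — and keep single transients well above the deconvolution
detection floor so field tails are not selectively lost. Traces add a
shared neuropil signal (slow drift plus fast flicker, fluctuation sd
~28 F-units on an ~100 F-unit baseline) scaled by the contamination gain,
plus white noise (sd 0.05 ΔF/F). The neuropil fluctuations must rival
the somatic signal for the α search to be well conditioned; the gain is
recovered to ±0.05 as a population mean (per-cell estimates scatter by
~±0.1 because finite sessions leave residual chance correlation between
transients and the slow neuropil component).

Passing tests on these data show the chain is correct under Poisson
events, an exact AR(2) transient, additive shared contamination and
white noise. They do not exercise motion artifacts, ROI segmentation
errors, slow photobleaching drifts, burst-dependent indicator
nonlinearity, or non-Poisson firing statistics — all upstream of, or
outside, this package's scope.

Parameter-recovery assertions are made on session medians over the
recovered place cells: at the default event budget even ground-truth
event trains give ~8% FWHM scatter cell-to-cell, so a per-cell bound
would measure the Poisson budget rather than the code. Medians land well
inside the bounds (centers ~0.4 cm against a 0.85 cm bin; widths ~8%
against 15%).

The dendrite generator renders a horizontal shaft (1.5 μm wide) with
archetypal spines at ≥3.5 μm spacing: mushroom (1 μm × 0.25 μm neck,
1.1 μm head), stubby (half-ellipse 2.8 × 1 μm), thin (rod 1.5 × 0.8 μm)
and filopodium (rod 2.8 × 0.5 μm); each spine's ground-truth label is
its own geometry pushed through the classification tree, so
self-consistency holds by construction (the long thin archetypes land in
fallback-thin under the verbatim thresholds, as any real image-extracted
spine of that shape would). Daily turnover removes and adds
round(fraction × count) spines; a position freed on a given day cannot
be reused by that day's additions, since an add at a just-vacated site is
indistinguishable from continuity for any matcher, human or automated.

Bead stacks render 3-D Gaussians (FWHM = 2√(2 ln 2)·σ) at rejection-
sampled positions honoring the isolation distance, with optional Poisson
and Gaussian noise. Axis populations place cells on a rotated parabola
with isotropic jitter and SI drawn from a profile of true arc distance.

Every generator is a pure function of its spec including the seed;
identical seeds give bit-identical outputs.

## Problem sizes used in the test suite

The classifier-performance and shuffled-control checks run one 120-cell,
600 s session (~85 laps) shared across tests; the axis test-size check
uses 400 null sessions of 210 cells and the power check 50 sessions with
a 50% SI step; spine turnover uses a 6-day series of an 11-spine
dendrite; bead stacks are 60×256×256 with 12 beads. These sizes were
chosen as the smallest at which the statistical assertions are stable.
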