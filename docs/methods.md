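# Methods

This note documents the models, estimators and numerical choices behind
`cardionano`, what the synthetic generators do and do not emulate, and the
problem sizes used by the test suite and the acceptance script.

## Synthetic data generation (`synthgen`)

**Clustered patterns.** Localization patterns are drawn from a Thomas
process: `n_parents` cluster centers uniform in the window, Poisson
(`offspring_mean`) offspring per center with isotropic Gaussian spread
`cluster_sigma`, uniform background at `background_rate` points/nm², and
additive isotropic Gaussian localization jitter `loc_precision_sigma`
(default 10 nm, the stated precision of the acquisition instrument). The
Thomas process is the standard clustered null for SMLM data and exposes
exactly the knobs the analyses respond to: cluster size, cluster density
and inter-cluster spacing. Offspring landing outside the window are
discarded, which slightly depresses the expected count
`n_parents·offspring_mean + background_rate·|W|` near the boundary; the
ensemble test allows 1 % for this truncation. Condition presets
(`control`, `loose_clusters`, `sparse_clusters`) are illustrative parameter
sets only — no biological claim is attached to them.

**Inter-cluster spacing presets.** The spacing levels used by the
hole-size analysis place a fixed number (12) of compact clusters
(3 offspring, 3 nm spread, 10 nm jitter) in windows of side 400/600/800 nm,
so mean parent spacing grows with the window while cluster size stays
fixed. Compact clusters are deliberate: with large, diffuse clusters most
H1 bars come from holes *inside* clusters, whose size is set by
`cluster_sigma` and does not respond to spacing; with compact clusters the
hole structure is dominated by the spaces between clusters, which is the
quantity the spacing presets are meant to vary.

**Emitter stacks.** Each frame is Gaussian camera background
(mean/SD configurable) plus, for every emitter currently "on", a 2-D
Gaussian PSF (`psf_sigma`, default 120 nm) carrying `photon_rate` counts.
Blinking is an explicit per-emitter list of on-intervals rather than a
kinetic on/off Markov model — simpler, fully deterministic under the seed,
and sufficient to exercise the dark-state bridging rule. Random schedules
never start at frame 0 (the difference detector has no predecessor frame
there). Not modeled: Poisson shot noise on the signal, drift, chromatic
aberration, multi-emitter overlap within a PSF.

**Calcium transients.** Within each pacing period (default 0.5 Hz) the
ratio rises linearly from diastolic `d` to systolic `s` over `rise_time`,
then decays as `d + (s−d)·exp(−(t−t_r)/τ)`; Gaussian noise is additive.
The template restarts at `d` at every stimulus, so the (small) undecayed
residual at the period end produces a discontinuity of
`(s−d)·exp(−(P−t_r)/τ)` — about 1 % of amplitude at the defaults — which is
also the inherent bias of any baseline estimate taken from pre-stimulus
samples.

**Contraction.** Trace mode is a triangular pulse train (linear up over
`t_up`, down over `t_down`, default asymmetric 0.12/0.24 s) with a phase
offset so the first upstroke is on camera. Stack mode renders a smoothed
random texture rigidly translated along x by `max_displacement_px · trace`
pixels per frame (bilinear interpolation). Rigid translation is a
simplification of real cell shortening; it suffices for the mean absolute
frame-difference readout, which responds to |velocity| regardless of the
deformation model.

All generators draw from a single `numpy.random.default_rng(seed)`;
identical parameters and seed give byte-identical output.

## Localization extraction (`locextract`)

Detection works on brightness differences between consecutive frames.
Positive differences (`max(I_t − I_{t−1}, 0)`) mark appearance events;
negative differences mark disappearance events. Connected regions
(8-connectivity) above a per-pixel threshold whose summed intensity reaches
`intensity_threshold` become events; the per-pixel threshold defaults to
5× a robust (MAD-based) noise scale of the difference images. An
appearance opens a molecule track; the matching disappearance (greedy
nearest within `merge_radius`) closes its on-interval, so the number of
merged frames counts frames the molecule was actually on. Re-appearances
within `max_gap_frames` (default 2) dark frames are bridged into the same
molecule; longer dark states start a new one. Each finished track emits
one row at the intensity-weighted barycenter of all its appearance-region
pixels, with summed intensity, first frame, and on-frame count.

Both difference signs are used because appearance-only detection cannot
count on-frames: an emitter constant over several frames produces exactly
one positive-difference event. The disappearance event adds the missing
end-of-interval information while staying within the
consecutive-frame-difference principle.

Not implemented (out of scope): Gaussian/MLE sub-pixel fitting, drift
correction, multi-emitter fitting. The intensity threshold and merge
radius are required configuration — the reference acquisition software is
proprietary and its values unknown, so no defaults are claimed faithful.

## Ripley / NNA (`pointstats`)

The unbiased count estimator `K̂(r) = |W|/(n(n−1)) Σ 1(0 < d_ij ≤ r)` is
used with either no edge correction (for real crops) or toroidal wrapping
(for synthetic rectangular windows, exact under the periodic null).
Isotropic Ripley weighting is deliberately not offered: it could not be
validated against the reference analyses. Torus mode requires
`max(r) ≤ min(width, height)/2`. The default grid is 0–500 nm in 5 nm
steps, bracketing the 25–75 nm chromatin/cluster scale of interest. The
peak of L(r) − r resolves ties toward the smaller radius. Duplicate points
are legal in K (the indicator excludes only self-pairs) and are surfaced as
a warning count in NNA rather than dropped.

`pair_distance_frequency` serves the "normalized distance frequency"
reading of the Ripley analyses: pairwise-distance histograms divided
bin-wise by the mean histogram of seeded CSR patterns of equal n and
window, giving ≈1 under CSR. Both this curve and classical L − r are
available so either convention can be reproduced.

## Persistent homology (`topohomology`)

The filtration parameter is the **circle radius**: an edge is born at
d/2 (two expanding circles touch), a triangle at the maximum of its edge
births (Vietoris–Rips). This is half the diameter convention of most
persistence libraries — all reported nm values differ by 2× from
diameter-based tools. Rips is used rather than Čech; Rips can fill a hole
slightly later than the circles geometrically cover it, and the worked
unit tests use configurations where the two agree.

H0 is computed by union-find over edges in birth order (elder rule; finite
deaths are exactly the halved MST edge lengths, which the tests verify
independently via `scipy.sparse.csgraph.minimum_spanning_tree`). H1 comes
from mod-2 column reduction of the triangle boundary matrix in filtration
order — columns are packed into Python integers keyed by edge rank, so
column addition is one XOR. By the clearing lemma, pivots of reduced
triangle columns are always creator edges, so reducing the triangle matrix
alone yields the complete H1 pairing. Determinism follows from the total
simplex order (birth, dimension, vertex tuple). Zero-persistence H1 pairs
are omitted; all H0 bars are kept so their count equals the point count.
Unpaired creator edges (holes never filled within `max_radius`) are
reported as infinite bars and excluded from hole-size histograms, where
they are counted separately.

Clouds above 500 points (configurable) are seeded-subsampled before the
filtration is built, since triangle count grows cubically; the pipeline
logs the subsample size. Hole-size histogram default bins are 0–200 nm in
25 nm steps.

## Kinetics (`kinetics`)

Definitions, all configurable:

* diastolic D — mean of the last 20 % of the *preceding* beat window
  (pre-stimulus); the first beat falls back to its own window minimum.
  On the synthetic template this estimate carries the undecayed residual
  bias noted above, and the recovery tests bound the error by that
  closed-form residual rather than asserting exact equality.
* systolic S — window maximum; amplitude = S − D.
* rise time — 10 %→90 % of amplitude on the upstroke, crossing times
  linearly interpolated between samples (so a linear upstroke of duration
  t_r yields 0.8·t_r).
* release rate — maximum smoothed-central-difference derivative during the
  upstroke.
* τ — least-squares fit of `B + A·exp(−(t−t₀)/τ)` from the first sample
  after the descending 90 %-of-amplitude crossing to the window end
  (≥8 samples), initialized by tail mean and log-linear regression;
  reuptake rate = 1/τ. Fits with τ larger than 5× the fitted span are
  flagged `tau_exceeds_window`: an exponential with τ much longer than the
  window is indistinguishable from a straight line, so such fits (e.g. on
  a linear decay) are reported as unconstrained rather than trusted —
  note R² alone cannot catch this, because the large-τ limit fits a line
  almost perfectly.
* beats with amplitude below 5× a robust noise estimate are flagged
  `no_upstroke` and excluded from averages (never NaN-propagated).

Beat windows come either from the pacing frequency (`[k/f, (k+1)/f)`), or
from detected peaks (prominence ≥ 30 % of range, refractory spacing 50 %
of the median period) walked back to the foot of the monotone upstroke —
on noise-free paced traces both segmentations agree to one sample.

Contraction: the motion signal is the pixel-mean absolute consecutive-
frame difference, baseline-subtracted by a rolling minimum (2 s window) —
the simplest operator consistent with a relative-motion readout; optical
flow is out of scope. The trace has T−1 samples but keeps the full
acquisition duration T/fps, so frequency = beats/duration is exact for
periodic beating (30 beats in 30 s → 1.0 Hz). Velocities are per-beat
extrema of the smoothed derivative, reported as magnitudes.
`average_cycles` collapses the cycle level within measurement × cell
groups (10 measurements × 10 cells → 100 averaged points per condition).

## Statistics and pipeline (`compare`, `pipeline`)

Group comparison is the two-tailed **equal-variance** Student's t-test
(Welch behind a flag), with means ± SEM (SD, n−1 denominator, over √n) and
stars at 0.05/0.01/0.001. No multiple-testing correction is applied by
default; Benjamini–Hochberg is available for users. Degenerate inputs are
explicit: identical constant groups give t = 0, p = 1; zero pooled
variance with unequal means gives the limiting p = 0 with a
`zero_variance` flag. The unit of analysis (cell vs replicate) is whatever
the caller feeds in; the demo uses replicates and records n in the report.

The pipeline derives every per-condition/replicate/stage seed from the
master seed via `numpy.random.SeedSequence`, rounds reported metrics to 10
decimals, and serializes the summary with sorted keys, so reruns are
byte-identical; timestamps appear only in the log file.

## Problem sizes

Chosen so the full suite runs in well under a minute of compute per
module: CSR calibration uses 100 patterns of n = 300 in a 2 × 2 µm torus
window; cluster-tightness ordering uses 100 paired seeds (σ = 20 vs
80 nm, 20 clusters of 25); spacing analysis 3 levels × 50 seeds with
max radius 400 nm; persistence oracle equivalence 200 clouds of n ≤ 12
against full-matrix reduction; detector recovery one 200-frame,
200 × 200 px stack with 50 emitters; τ recovery 100 noisy traces at
SNR ≈ 20; contractility one 1500-frame stack at 50 fps.

## Known limitations

* The generators emulate statistical structure, not microscopy physics:
  no shot noise, drift, aberration, axial structure, or emitter
  photophysics beyond scheduled blinking. Passing tests demonstrate the
  estimators recover known ground truth under these idealized conditions,
  not detector performance on real acquisitions.
* All spatial analysis is 2-D; no inhomogeneous or bivariate K; no H2 or
  higher homology, persistence images/landscapes, or bottleneck tests.
* Rips/Čech discrepancy: reported H1 deaths can exceed the geometric
  circle-covering radius of a hole.
* No Fura-2 calibration to absolute calcium concentration, arrhythmia
  classification, or sarcomere tracking.
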