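# Methods

This note documents the models, algorithms and design choices behind
`actomotility`, in the order data flows through the package: mock-video
synthesis, image analysis, trace quality control, feature extraction,
condition statistics, and the coupled-myosin simulator.

## Mock motility videos

The generator scripts rigid, rod-like fluorescent filaments (0.3–3.25 µm)
moving at constant speed along straight or constant-curvature paths in a
2-D field of view, and renders each frame as a chain of point emitters
(default spacing 0.05 µm) splatted bilinearly at sub-pixel positions,
convolved with a Gaussian point-spread function, on a Gaussian-noise
camera background. Optional per-emitter brightness fluctuation
(multiplicative Gaussian) and per-emitter Brownian jitter emulate
fluorophore photophysics and thermal wobble. A truth table records
per-frame centroid, tip, length, speed and an `overlap` flag raised when
two filament backbones approach within 0.4 µm.

Optical defaults are chosen at the physically standard scale for
TRITC-phalloidin imaging on an intensified CCD: PSF σ = 0.9 px at
0.08 µm/px (≈ 0.072 µm, near the diffraction limit) and a 512×512 field.
Wider PSFs at coarser pixels make a 1–2 µm filament image as a blob whose
length/width ratio approaches 1, at which point the rectangle-equivalent
transformation (below) degenerates; the defaults keep the imaged filament
width near 0.25–0.3 µm so that lengths ≥ 0.6 µm yield real solutions. The
generator does not model bleaching kinetics or EMCCD gain.

The `crossing_scenario` script produces labelled training material for
quality control: pairs of filaments steered through a shared point at
mid-video (guaranteed crossing frames), clean movers, and
irregular movers with per-frame heading/speed jitter.

## Image analysis

1. **Preprocessing.** Native 30 fps frames are averaged in non-overlapping
   blocks to the analysis resolution Δt (default 1/3 s). At finer Δt the
   apparent-velocity noise floor of stationary filaments overlaps the
   sliding population; at 1/3 s the two populations separate (see
   "velocity cut" below). Each merged frame is background-corrected by
   subtracting a median-filtered copy (21 px kernel) and
   contrast-stretched against its 5th-brightest pixel — robust to hot
   pixels without flat-topping small objects, which a percentile bound
   does.
2. **Binarisation.** Threshold at a fraction of the frame's dynamic range
   (default 0.3). Filament width and length depend on the threshold;
   velocities must not (this robustness is asserted in the tests over
   0.2–0.45).
3. **Segmentation and geometry.** 8-connected components ≥ 5 px.
   Area and perimeter are measured on the sub-pixel marching-squares
   iso-contour of each component at the binarisation level; pixel-counting
   and chain-code perimeters under-measure few-pixel-wide filaments by
   ~15% and were rejected for that reason (the chain-code path remains as
   a fallback when no intensity image is available). Centroids are
   intensity-weighted.
4. **Rectangle-equivalent length.** Each object is mapped to the rectangle
   with the same area A and perimeter P: the edges are the roots of
   x² − (P/2)x + A = 0, the longer root being the filament length. A
   negative discriminant (very short filaments, where the imaged width is
   comparable to the length) collapses both edges to P/4 with a
   `complex_flag`; the estimate is continuous at zero discriminant and
   still orders objects by size.
5. **Tracking.** Greedy nearest-centroid linking between consecutive
   frames, candidate links sorted by distance and tie-broken by smallest
   relative area change; links beyond 1.2 µm or 50% area change are never
   formed. Unmatched objects start new traces.
6. **Kinematics.** v_f2f = centroid displacement per Δt. The tip is the
   major-axis endpoint leading the local displacement direction; the trace
   velocity is the summed tip path divided by the trace lifetime.

## Trace quality control

Traces crossing other filaments or moving irregularly must be removed
before feature extraction. Each trace (≥ 3 frames) is summarised by seven
features: Harris corner count along the rasterised trajectory (Gaussian
smoothing, kernel length 21, σ 2.5; at most 200 corners, sensitivity 0.2,
relative quality 0.15; corners at the free ends of the polyline are
suppressed since any open line ends in corner-like responses), the
coefficients of variation of speed, area and length, the fraction of
complex-length frames, the minimum same-frame distance to other traces,
and the count of close-approach frames. The feature list is a
reconstruction and is pluggable.

A 150-tree bagged decision-tree ensemble (random forest) scores traces;
out-of-bag error is tracked against tree count to confirm the plateau
reached well below 150 trees. The acceptance threshold minimises
5·FPR + 1·FNR on a validation set from a different generator seed
("different day"), and ROC curves report cross-day transfer. Training
labels come from mock-video truth tables; hand scoring plays this role
for real data.

## Motility features

Four features summarise each filament: mean frame-to-frame velocity,
motile fraction, mean stop time and mean run time.

* **Velocity cut.** A two-component Gaussian mixture (EM, deterministic
  quantile initialisation with the low component started on the noise
  floor) is fitted to the pooled v_f2f sample of the reference condition;
  the cut is the equal-posterior velocity between the component means. A
  separation below half the summed component widths flags the
  populations as not separable (the too-fine-Δt regime). The cut is
  fitted once per analysis on the baseline condition and shared across
  compared conditions — refitting per condition moves the cut with the
  condition's velocity distribution and contaminates run/stop fold
  changes.
* **Run/stop segmentation.** Maximal consecutive intervals above/below
  the cut; the motile fraction is the fraction of running intervals
  (time-fraction, not filament-fraction — consistent with defining the
  quantity from v_f2f time courses); run/stop times are segment
  durations. Stops shorter than one interval are unresolvable by
  construction.
* **Length windows.** Sliding windows over filament length, default
  0.3–3.25 µm, width 0.59 µm, 50 equally spaced windows (an alternate
  short-range grid with 25 windows over the lower half is used for the
  short-filament run-time analysis). Per window: the mean over filaments
  of per-filament mean v_f2f; the motile fraction from pooled intervals;
  run/stop times as means of pooled segment durations. Empty windows
  carry NaN and are excluded pairwise (fold changes) or globally (PCA).
* **Bootstrap.** B resamples with replacement at the filament level
  (chamber-level resampling is available as an option), giving replicate
  curves and percentile 95% bands. Filament-level resampling matches the
  emphasis on per-window filament counts.

A lightweight records-level generator (`synthetic_records`) emulates the
statistical structure of one condition's feature table — a few hundred
filaments, velocity rising gently with length, motile fraction saturating
with length, geometric run/stop segment durations at the analysis Δt. It
is used to validate the windowing/bootstrap statistics independently of
the mechanistic simulator; it does not emulate optical artifacts,
tracking errors, or chamber-to-chamber batch effects, so statistics
validated on it say nothing about those error sources.

## Condition statistics

All datasets (per condition: one main + B bootstrap) are assembled into
one matrix of concatenated length-resolved features (4 features ×
windows, feature-major), columns dropped where missing in any dataset and
standardised. PCA retains the first three components (deterministic sign
convention). Two conditions are significantly different when their 95%
confidence regions of bootstrap scores in PC1–3 are disjoint; regions are
Mahalanobis ellipsoids (χ²₃, 95%), and disjointness is decided by a
convex program (minimise the Mahalanobis distance to one cloud subject to
the other's ellipsoid). Ellipsoids were chosen over convex hulls because
the non-overlap criterion needs a well-defined confidence region; hulls
remain a rendering choice.

Agglomerative clustering uses Ward linkage on the bootstrap scores. The
cluster count is read off the linkage profile: the median of the three
finest merge heights sets the profile's noise scale, a merge counting as
structural when it costs at least 3× that scale, and k is one more than
the number of structural merges — the largest k whose formation still
involved a relatively large linkage reduction. Pure ratio-elbows proved
unstable here because independent replicas of one condition always sit
about √2 bootstrap-cloud-widths apart and can be resolved as
sub-structure; the noise-referenced rule selects the same k across
simulation seeds. Data whose profile never exceeds the noise scale
yield k = 1.

Scalar comparisons average a feature over the (possibly restricted)
window grid. The fold change is the ratio of the two conditions'
averages; significance follows the non-overlap rule applied to the two
percentile CIs of the window-averaged means, and the signed distance
between the facing CI limits (in fold units) is the margin tallied by the
type-I self-check. The joint two-feature test projects both conditions'
bootstrap (fold, fold) clouds onto the unit vector joining the condition
means and applies the same non-overlap rule to the projections — aligned
shifts too small per feature become detectable when the noise is
anti-correlated along the connecting direction. No multiple-testing
correction is applied across pairwise comparisons, matching the source
analysis design.

The type-I assessment draws two full-size with-replacement resamples of
one condition, runs the fold analysis for all four features and records
the margins; across 300 comparisons the margin distributions should sit
several widths below zero. Note that the non-overlap rule on two 95%
CIs retains an intrinsic false-positive rate of a few per mille per
comparison, so a handful of positive margins in 1200 null tests is the
expected behaviour of the procedure as implemented.

## Coupled-myosin simulator

### Model

A filament of length L exposes N = max(1, round(L/δ)) binding sites,
δ = 0.0355 µm (the actin helix repeat). Each site cycles
detached → pre-stroke → post-stroke → detached. The main power stroke
moves the motor's anchor by d_main and the secondary step, executed
immediately before detachment, by d_second. Bound motors are linear
springs of stiffness κ between anchor and the rigid filament; the
filament position z re-equilibrates instantly to the mean anchor after
every event (keeping the process Markovian), so a bound motor's state is
fully described by its strain s = z − a. Mechanical transition rates are
Boltzmann-modulated:

    rate = k₀ · exp(−c · ΔE / kT),

where ΔE is the elastic-energy change of executing the step (anchor
displacement plus filament re-equilibration) and c is the dimensionless
coupling impact. Three deliberate choices:

* **Step work only.** ΔE for the detachment transition is the work of
  the secondary step itself, not including the elastic energy released
  when the bond finally breaks. Including the bond-release term makes
  every freshly stroked motor detach quasi-instantly (its stored strain
  energy is large and released on unbinding), each stroke's displacement
  is immediately undone by the spring-back of the remaining motors, and
  the model loses its motile steady state at any realistic stiffness. A
  post-stroke motor whose anchor is ahead of the filament therefore
  detaches slowly and acts as a brake — the microscopic origin of
  arrests.
* **Thermal attachment strain.** A head binds wherever thermal
  fluctuation lets it reach, giving a Boltzmann-distributed initial
  strain (σ = √(kT/κ) ≈ 1.45 nm at the default stiffness). Without this
  spread all motors attach at exactly zero strain, the ensemble has no
  strain diversity, collective arrests deepen with motor count, and the
  motile fraction *falls* with filament length — opposite to
  observation. With it, large ensembles always hold a favourably
  strained motor and glide smoothly, while small ensembles arrest when
  their few draws are unlucky.
* **Two-phase attachment.** While at least one motor tethers the
  filament, heads rebind at k_attach per free site; a filament with no
  bound motor is only loosely confined near the surface and re-engages
  at the much slower total rate N·k_reengage. This makes run
  termination extinction-limited (all motors detaching ends a run),
  which is the only termination mechanism that slower detachment
  *delays* — required for the direction of the detachment-condition's
  run-time effect — and provides seconds-long stops after complete
  release. With uniform attachment no parameter regime reproduces that
  direction: runs are then ended by arrest entry, which slower
  detachment promotes.

Attachment is strain-independent in rate; detached heads are always
available (excess surface myosin). Gaussian measurement noise
(σ = 10 nm, matched to the stopped-population v_f2f width at Δt = 1/3 s)
is added at sampling only, so simulated velocity distributions carry the
same two-population structure as tracked videos. Exact next-event
(Gillespie) sampling with all event energetics reduced to closed forms in
the acting motor's strain and the bound count; the kernel is
numba-compiled, and single-filament closed forms (renewal cycle), N ≤ 3
master-equation occupancies and per-event energy bookkeeping serve as
brute-force oracles in the tests.

### Baseline calibration

The published record of this model prints its baseline rate constants
only in a figure that is not machine-readable, so the baseline here is a
reconstruction, calibrated once and shipped as a versioned config
(`data/baseline_params.yaml`): k_attach = 10 /s, k_reengage = 0.2 /s per
site, k_stroke = 1000 /s, k_detach = 185 /s, c = 1, d_main = 6 nm,
d_second = 4 nm, κ = 2 pN/nm, kT = 4.186 pN·nm (30 °C). Calibration
targets were (a) sliding velocity in the sub-µm/s range with a plateau in
L, (b) motile fraction rising steeply with L and saturating near 1,
(c) run/stop structure resolvable at Δt = 1/3 s, and (d) consistency of
the three published condition multiplier sets (all kinetic rates ×1.15;
coupling impact ×1.2; detachment ×0.75 with coupling ×0.8) with the
published condition-level fold changes they were reported to produce —
the baseline is underdetermined by (a–c) alone. The large unstrained
stroke rate is not a literal unloaded rate: strokes are elastically gated
(the self-work of stroking against partners is ≈ κd²/2 ≈ 8.6 kT at high
occupancy) and proceed through a strain relay, so the effective stroke
time is set by the gating, not by 1/k_stroke.

Under this baseline the simulated fold changes, extracted through the
identical feature pipeline (shared baseline cut, length-windowed
averages), are approximately: velocity ×1.14 for the rates condition;
motile fraction ×0.93 and stop time ×1.0 for the coupling condition; run
time ×1.5–1.8 (short filaments) and ×1.4–1.6 (whole range) for the
detachment condition — the model's contrast between the short-range and
whole-range run-time folds is weaker than observed experimentally. Known limitation: in this reconstruction the coupling impact
modulates how *often* the filament stalls (and the sliding speed), not
how *long* individual stops last — stop durations at the 1/3 s
resolution sit near the single-interval floor and respond to coupling
only weakly, so the published stop-time elevation of the coupling
condition is not reproduced. Candidate remedies (deeper arrest states
whose escape is collectively gated) were explored and either froze the
motile state or inverted the length dependence; resolving this requires
rate expressions beyond what the available description specifies.

### Problem sizes

Simulated comparisons use 300 filaments per condition (lengths uniform
over 0.3–3.25 µm), 25 s traces at Δt = 1/3 s, and 150 bootstrap
replicates; the six-condition partition analysis uses 150 filaments and
B = 100, and the type-I assessment 300 comparisons at B = 200. These
sizes keep every fold estimate's seed-to-seed spread well inside the
tolerances used in the tests while the full suite runs in minutes.

## Numerical and degenerate-input conventions

Exponents of Boltzmann factors are clipped at ±50. A filament with no
events (no attachment possible) yields a flat trajectory, not an error.
Empty masks yield empty object tables. Mixture fits are
label-invariant (deterministic initialisation). Tracking ties are broken
by area change, then distance. Traces shorter than 2 frames are dropped
with a log entry; QC features require ≥ 3 frames. Bootstrap percentiles
ignore all-NaN windows. All stochastic components take explicit seeds;
every simulation, resampling and training routine reproduces bit-for-bit
under a fixed seed.
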