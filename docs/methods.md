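# Methods

`statedyn` implements a dynamic brain-state analysis for ROI-level BOLD
time series from a placebo-controlled crossover design (placebo PL vs
methylphenidate MP), together with a synthetic cohort generator that
plants known structure so every stage can be validated against ground
truth.

## The model

The analysis treats each kept fMRI frame as a point in ROI space and
assumes the brain visits a small set of recurrent co-activation states.
Frames from all subjects and both conditions are concatenated and
clustered by k-means under the correlation distance

    d(x, c) = 1 − r(x, c),

where r is the Pearson correlation of the two vectors across ROIs. The
semantics deliberately replicate the MATLAB `kmeans` `'correlation'`
contract as a compatibility requirement: frames are row-standardized
(zero mean, unit norm), assignment is to the maximum-correlation
centroid, and each centroid is the member mean re-centered to zero row
mean. Ties in assignment and in replicate selection break to the lowest
index; each restart initializes centroids at k distinct frames drawn
uniformly without replacement. Empty clusters are reseeded with the
frame farthest from its current centroid.

The number of states is chosen by the elbow of the explained-variance
curve EV(k) = 1 − Σ d(frame, centroid) / Σ d(frame, global centroid)
over k = 3..22: the smallest k whose next step gains less than 1
percentage point of EV (absolute gain < 0.01; a relative-gain variant
would divide by the current EV and is deliberately not used). If no gain
falls below the threshold the largest k is returned with a warning flag.
When the data are perfectly balanced (exact ± pattern pairs) the global
centroid is identically zero; every frame is then assigned distance 1 to
it, so EV remains well defined. At the chosen k, clustering is replicated
10 times and the replicate with the highest cumulative adjusted mutual
information (AMI, arithmetic average method) to the others is kept.

States are named by cosine similarity with eight resting-state network
templates (FPN, LIM, VAT, DAT, SOM, VIS, DMN, SUB): the centroid is split
into its positive part and the magnitude of its negative part, each part
is compared with every network indicator, and the single largest
similarity gives the name ("NET+" from the positive part, "NET−" from the
negative). Whole-centroid naming is available as an option
(`name_states(..., method="whole")`); the signed-part convention is the
default because demeaned centroids carry meaningful structure in both
signs. An average-linkage dendrogram on 1 − r between centroids provides
the two-group summary (association-dominant vs sensorimotor-dominant).

Per scan, four metrics summarize the label sequence restricted to kept
frames: fractional occupancy (share of kept frames per state), dwell time
(mean maximal-run length × TR, in seconds; 0 for absent states, so paired
tests keep full n), appearance rate (runs per minute of kept time), and
the row-stochastic transition matrix with persistence retained on the
diagonal (an off-diagonal-renormalized view is provided). A censoring gap
breaks temporal adjacency: runs never bridge a gap and gap-spanning frame
pairs contribute no transition count. Rows with no observed departure are
flagged undefined rather than NaN. For gap-free scans the identity
FO(s) = rate(s) × dwell(s) / 60 holds exactly and is property-tested.

## Postprocessing

The chain is detrend → band-pass → nuisance regression → censor → demean,
applied per scan:

- **Detrend**: per-ROI least-squares linear trend removal.
- **Band-pass**: 0.01–0.08 Hz order-2 Butterworth, zero phase
  (forward–backward). Edge transients are suppressed with Gustafsson
  initial conditions; the column mean is removed before filtering (the
  filter's DC gain is zero regardless). Contract: ≥ 90% RMS passage at
  0.04 Hz, ≤ 10% at 0.3 Hz on a 520-frame probe.
- **Nuisance regression**: OLS residualization on an intercept plus nine
  confounds (six rigid-body motion parameters, white matter, CSF, global
  signal). The confound columns are band-pass filtered with the data so
  the regression cannot reintroduce out-of-band energy; the raw confounds
  travel with the output so FD remains recomputable. A rank-deficient
  design raises an error naming the collinear columns.
- **Censoring**: framewise displacement in the Power convention (sum of
  absolute frame-to-frame parameter changes, rotations converted to arc
  length on a 50 mm sphere), DVARS as the RMS across ROIs of the
  frame-to-frame difference of the regressed series; frame t is censored
  iff FD > 0.5 mm or DVARS > 150 (strict inequalities; the first frame
  has FD = DVARS = 0 by convention). Censored frames are masked, not
  interpolated, and are dropped before clustering — excluded time points
  cannot carry state labels.
- **Demean**: per-ROI mean over kept frames subtracted.

Filtering precedes masking so the filter never sees gapped data; the
regression and global-signal ordering (regression after filtering) is one
documented choice among defensible ones. Re-applying the whole chain is
*not* numerically idempotent: a second pass re-applies the filter's
passband response and attenuates band-edge content again (~25% RMS change
on the synthetic signal). What the chain does guarantee — and what the
tests assert — is that the censor mask is reproduced exactly, the
non-filter stages are idempotent to 1e-9, and interior frames correlate
above 0.95 across re-application.

## Group statistics

MP-vs-PL contrasts are two-sided paired t tests on per-subject
differences, Benjamini–Hochberg corrected within each metric family (all
states of one metric; a global-correction option exists). Zero-variance
differences are handled explicitly (all-zero → t = 0, p = 1; constant
nonzero → p reported as the 0 limit with a warning).

Receptor–behavior associations use Pearson correlations with the
two-sided p from t = r√((n−2)/(1−r²)). IQ adjustment residualizes both
variables on an intercept plus the covariate and correlates the
residuals with df = n − 3. At the voxel level, per-voxel correlations
against a subject-level scalar are thresholded at uncorrected p < 0.05,
split by sign, reduced to 26-connected components, and filtered to
components of ≥ 30 voxels. Missing behavioral data are dropped pairwise
with the used n reported.

Mediation (x = D1R availability, m = MP-induced FPN+ dwell-time change,
y = MP-induced 2-ball response-time change) fits a (m~x), c (y~x) and
(c′, b) (y~x+m) by OLS with intercepts, so c = c′ + a·b holds to
numerical precision on a common sample. Inference on the indirect effect
a·b uses a subject-level nonparametric bootstrap (rows resampled jointly,
1,000 iterations by default) with a percentile 95% CI — not BCa — and the
tail-symmetric two-sided p = 2·min(#{ab* ≤ 0}, #{ab* ≥ 0})/n_boot floored
at 2/n_boot. Degenerate resamples (constant x, collinear design) are
redrawn and counted. Covariates can be removed from all three variables
first via `residualize_on`.

## The synthetic cohort

The generator emulates the study conditions: 37 subjects × 2 conditions,
232 ROIs (200 cortical in seven networks + 32 subcortical), 520 frames at
TR = 0.891 s, six latent states. No generative model is implied by the
analysis itself, so the simplest structure the clustering assumes is
adopted: a first-order Markov chain over centroid patterns with additive
AR(1) noise.

- **Templates**: the SUB network receives round(n_rois·32/232) ROIs, the
  seven cortical networks split the remainder evenly; assignment order is
  shuffled by the seed.
- **Centroids**: ± pairs over FPN, SOM and VIS — one centroid elevates a
  network's ROIs, its negation suppresses them; all centroids are exactly
  zero-mean, so naming recovers {FPN+, FPN−, SOM+, SOM−, VIS+, VIS−} and
  the dendrogram splits {FPN+, SOM−, VIS−} from {FPN−, SOM+, VIS+}.
- **Dynamics**: PL kernel has `base_persistence` = 0.95 on the diagonal
  (mean dwell ≈ 18 frames ≈ 16 s, within the range reported for
  co-activation states and above the period of the 0.08 Hz band edge)
  and the rest uniform. Under MP the FPN+ and VIS− self-transitions gain
  `sensitivity × mp_persistence_boost` and every row's entry into SOM+
  shrinks by the same relative amount, mass redistributed proportionally.
  The default boost 0.02 was sized by a power sweep on truth sequences so
  the paired contrast detects the FPN+ dwell-time effect in ≈ 90% of
  37-subject cohorts — a given state has only ~4 runs per scan, so the
  per-scan dwell estimator is far noisier than the geometric-law
  calculation suggests. Sensitivities are clipped so every kernel stays
  valid (|sensitivity × boost| ≤ 0.9·(1 − base_persistence)).
- **Signal**: frame t = amplitude × centroid[state_t] + AR(1) noise
  (coefficient 0.3, innovation sd 0.5 — the level at which ≥ 95% of raw
  frames still correlate best with their generating centroid) + a slow
  sinusoidal drift (period 300 s, well below the 0.01 Hz cutoff of an
  order-2 filter, with per-ROI loadings) + sparse spike artifacts
  (Bernoulli 0.02 per frame, amplitude 3× signal). The motion trace is a
  slow random walk plus a transient 0.8 mm displacement at every spike
  frame, so FD > 0.5 mm flags exactly those frames (and their
  successors); WM/CSF regressors are drift-locked and the global signal
  is the ROI mean. At the synthetic signal scale (~1) DVARS never
  approaches 150, so censoring is FD-driven in the cohort and the DVARS
  rule is exercised by unit tests on hand-built traces.
- **Subjects**: per-ROI striatal D1R = subject mean (Normal(2.0, 0.25))
  plus ROI noise (sd 0.1); sensitivity_i = 1 + mediation_a ·
  sensitivity_slope · z(mean D1R_i) + Normal(0, 0.3). The unit mean makes
  the average subject receive exactly the nominal boost; `mediation_a`
  (default 0.5) gates the a path — setting it to 0 severs the D1R link —
  and `sensitivity_slope` is an overall scaling (default 1). The 2-ball
  response-time change is −mediation_b × (true MP−PL FPN+ dwell-time
  difference) + Normal(0, 0.3 s) with mediation_b = 0.05, planting a
  negative indirect effect (higher D1R → larger dwell gain → faster
  responses); the 3-ball change carries no path, matching its null
  finding. Accuracy is 15 Bernoulli probes per task scan (3 cycles × 5
  response intervals) with success probabilities set to the reported
  group means (2-ball 0.903 PL / 0.970 MP; 3-ball 0.890 / 0.948), so
  values lie on the grid {0, 1/15, …, 1} and ceiling effects are
  reproducible. IQ ~ Normal(115, 12), independent of the mediation path.

All randomness flows from one root `SeedSequence` through a fixed
(templates, subjects, scans, behavior) spawning order; one integer seed
reproduces the cohort bit-for-bit.

What the generator does **not** emulate: hemodynamic-response
convolution, spatially structured noise, scanner harmonization, voxel-
level BOLD, PET kinetics, or realistic between-state transition
asymmetries. Passing tests therefore demonstrate correctness of the
pipeline's algorithms and its statistical calibration under the assumed
state-switching model — not performance on real scanner data.

## Numerical choices and scale

Zero-variance frames are rejected by name; correlation of anything with
an all-zero vector is treated as 0 in the voxel stage (constant voxels
are never significant). Lloyd iterations cap at 100 and stop at label
fixpoints. The elbow scan uses 10 restarts per k (50 in the single-k
pipeline default); the full-scale scan (≈ 37,000 kept frames × 232 ROIs,
k = 3..22) runs in under ten minutes on one CPU, and the statistical
recovery studies use truth sequences without BOLD synthesis
(`generate_cohort(..., include_bold=False)`), which makes hundreds of
replicate cohorts cheap. Problem sizes in the test suite were chosen to
keep the whole suite inside a coffee break while leaving every check at
the study's native n.

## Known limitations

- Dwell time uses the mean maximal-run convention; total-time-per-visit
  is a different statistic and is not provided.
- The percentile bootstrap can under-cover for strongly skewed indirect
  effects at small n; BCa is not implemented.
- The elbow rule with an absolute 1-point threshold is scale-dependent by
  construction; on data with much higher noise the curve may never gain
  1 point per step and the fallback (k_max + warning) applies.
- The ± pair centroid construction makes state patterns orthogonal in
  expectation; real co-activation states are oblique, which would lower
  AMI between replicates and soften the elbow.
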