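# Methods

This note documents the models, conventions and numerical choices behind
`axontune`, in the order the pipeline runs: synthetic data generation, GP
tuning characterization, population metrics, optogenetic suppression,
visuo-motor integration, and anatomical quantification.

## Synthetic sessions

All analyses are exercised on simulated sessions with known ground truth,
because the kind of in-vivo recordings this pipeline targets (axonal-bouton
calcium imaging in head-fixed mice) is rarely publicly deposited.

**Grating protocols.** The standard protocol crosses 5 octave-spaced
spatial frequencies (0.02–0.32 cycles/degree) with 5 octave-spaced temporal
frequencies (0.5–8 Hz) and 8 drift directions — 200 unique gratings,
shuffled independently within each of 6–8 repeat blocks. Timing: 1.2 s
static grating, then 2.15 s of drift. The optogenetic variant drops oblique
orientations (4 directions), crosses the remaining 100 gratings with a
laser on/off flag (again 200 conditions), drifts for 2.3 s, switches the
laser on 0.5 s after static onset for 2 s, and inserts 500 ms of gray
between trials.

**Tuned responses.** Each synthetic ROI has a log2-domain Gaussian SF x TF
tuning surface multiplied by a von Mises direction factor:

    r = baseline + gain * exp(-(log2 SF - mu_SF)^2 / 2 sigma_SF^2)
                        * exp(-(log2 TF - mu_TF)^2 / 2 sigma_TF^2)
                        * exp(kappa (cos(dir - dir_pref) - 1))

Laser trials scale the whole evoked response (baseline included) by a
multiplicative `laser_factor` in [0, 1], so the generative percent
suppression is exactly 100·(1 − laser_factor). Trial noise is Gaussian
(default SD 0.1 at gain 1 — a signal-to-noise regime in which a responsive
bouton is clearly detectable over 6 repeats, chosen once as realistic for
deconvolved bouton responses). Frame traces embed each trial response as a
boxcar over the drift window in baseline noise, so window-averaged
extraction recovers the tabled response. The log2 domain for SF/TF makes
synthetic preferences commensurate with the GP's log-domain predictors.

**Visuo-motor sessions.** Running speed (RS) and optic-flow speed (OF) are
*independent* processes — the uncoupled (replay) configuration in which
self-motion and visual motion can be dissociated. Each is a rectified
Ornstein–Uhlenbeck process (mean 8 and 10 cm/s, tau 2 s, sigma 6 cm/s
sqrt(s)) smoothed with a 0.5 s moving average; the resulting
autocorrelation makes lagged cross-correlation non-trivial and keeps
median running speed comfortably above the 3 cm/s session-inclusion gate.
ROI activity is a lagged linear readout, `w_RS·RS(t−lag) + w_OF·OF(t−lag)
+ noise`. Because these traces are linear couplings rather than
transient-rich calcium signals, the session pipeline accepts
`responsiveness="all"` to bypass the skewness gate, which is meaningful
only for dF/F-like traces (and is tested on burst-like traces separately).

**What the generator does not emulate:** calcium-indicator dynamics, spike
inference errors, neuropil contamination, slow drift, correlated noise
across ROIs, or any dependence of visual responses on running speed.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to every artifact of real
two-photon data.

## GP tuning model

Trial responses are modeled as a zero-mean Gaussian process over five
predictors: log2 SF, log2 TF, drift direction, trial-averaged running speed
as log(1+s), and the binary laser flag. The kernel is a single product
squared-exponential with a periodic direction distance,

    k(x_i, x_j) = sigma_k^2 exp(-[ dSF^2/2l_SF^2 + dTF^2/2l_TF^2 +
                  d_per^2/2l_th^2 + ds^2/2l_s^2 + dL^2/2l_L^2 ])
                  + sigma_eps^2 delta_ij,

with d_per(th_i, th_j) = 2 sin(|dth| π/360)·(180/π), periodic with period
360°. The direction distance lives on a degree-like scale (maximum ≈
114.6), so fitted l_th values are naturally tens of units.

**Predictor units** are the single most consequential convention here:
SF/TF enter in log2 units (the stimuli are octave-spaced, and the 0.25
lower bound on a length scale is only meaningful on a log grid) and
running speed as log(1+s). Both transforms are isolated in
`gp.transform_features`.

**Hyperparameter estimation.** L-BFGS-B on log-parameters maximizes the
exact marginal likelihood plus independent Gamma(2,1) log-priors
(log l − l) on the five length scales, applied on their natural scale.
l_SF, l_TF, l_s are bounded below at 0.25; l_th and l_L are positive but
otherwise unconstrained. Five seeded starts (one data-driven, four drawn
from the prior) guard against local optima; total non-convergence flags
the fit rather than failing silently. Convergence tolerances: ftol 1e-9,
gtol 1e-6 on the objective.

Because protocols repeat each stimulus 4–8 times, the marginal likelihood
is evaluated exactly on the collapsed set of G distinct predictor rows:
with per-row trial counts m and means ybar, and within-row residual sum
RSS,

    log p(r) = -1/2 [ (n-G) log s_e^2 + RSS/s_e^2 + log|A| +
               ybar' A^-1 ybar + sum log m + n log 2π ],
    A = K_signal(U, U) + s_e^2 diag(1/m),

which reduces an n=1200-trial fit to a G=200 system (tested against a
dense textbook implementation to 1e-8). A stabilizing jitter of
1e-6·sigma_k^2 is folded into the effective noise variance so the
collapsed and dense models are identical. Analytic gradients use the
standard trace identity.

**Predictive variance convention.** Reported variances are predictive
(posterior-function variance plus sigma_eps^2), so SNR =
r_best/sqrt(var_best) behaves like response amplitude over noise SD and
the prior bound var ≤ sigma_k^2 + sigma_eps^2 holds everywhere.

**Derived quantities.**
- *Responsiveness*: SNR > 2 and fit R² > 0.1 (R² computed on trial-level
  predictions).
- *Preferred stimulus*: Nelder–Mead simplex from 8 starts seeded at the
  strongest training conditions, over (log2 SF, log2 TF, direction), with
  running speed at the training median and the laser flag fixed (0 for
  control, 1 for laser preferences). SF/TF are clipped inside the search
  to the presented ranges [0.02, 0.32] and [0.5, 8]; direction is
  periodic. Ties between equal-mean optima break toward lower predicted
  variance.
- *Modulation along a dimension*: best minus 0.66 predicted SD must exceed
  worst plus 0.66 SD (a 1.33 SD separation), best/worst searched on a
  dense 1-D grid with other predictors at the preferred point.
- *Preferred speed* = preferred TF / preferred SF (deg/s).
- *Tuning width*: FWHM in octaves of the 1-D predicted curve, the half
  level midway between the curve minimum and maximum within the presented
  range (the minimum, not zero, is the baseline — the model has no
  explicit baseline parameter), with linearly interpolated crossings. A
  side that never reaches half level is measured to the range edge and
  flagged censored rather than dropped.

## Population metrics

Trial responses are Z-scored per ROI against the mean and SD of that ROI's
whole inferred-rate trace. The population response matrix averages, per
(SF, TF) cell, each responsive ROI's mean Z-response at the grid direction
nearest its preferred direction — repeats are averaged within ROI first, so
ROIs (not trials) carry equal weight. Matrix similarity is the Pearson
correlation over paired finite cells. Group comparisons are two-sided
Wilcoxon rank-sum tests (exact for small untied samples, normal
approximation otherwise) at the ROI level and on per-session medians, with
Bonferroni adjustment for an explicitly declared family size — the family
is never inferred from the data at hand.

## Optogenetic suppression

Stimuli driving an ROI are those grid conditions whose GP-predicted
response (laser off) has SNR > 2 and amplitude at least 2/3 of the best
response. Control and laser trials of those conditions are pooled
(unpaired) into a two-sided rank-sum test; an ROI is *suppressed* iff
p < 0.05 and its laser mean is below its control mean. This literal
reading of the convention means the null classification rate is about
α/2 ≈ 0.025, and calibration tests assert exactly that (alongside the
two-sided test's own rate of ~0.05). Percent change is
100·(control − laser)/control; the session-level "mean amplitude
decrease" averages each ROI's laser/control ratio first and ROIs second.
Centered tuning curves require SNR > 2 at the preferred stimulus in both
laser conditions and are predicted at the control-preferred direction and
complementary frequency, indexed in octaves around the control peak.

## Visuo-motor integration

ROIs are gated by dF/F skewness > 1 (transient-rich traces). For each
responsive ROI, Pearson correlations between inferred rate and each
behavioral variable are computed at every lag of a ±1 s grid —
frames −⌊fr⌋ … +⌊fr⌋−1, i.e. exactly 60 lags at 30 Hz and 30 at 15 Hz
(the positive endpoint is the one excluded, fixed for determinism).
Positive lag means activity follows behavior. The population median of
per-ROI best (max-|r|) lags defines m_Lag per variable; R_RS and R_OF are
the mean coefficients in a 250 ms window centered on m_Lag, endpoints
inclusive. ROIs with |R| = sqrt(R_RS² + R_OF²) ≥ 0.1 enter the angle
analysis.

The interaction angle is the full-quadrant angle of the (R_RS, R_OF)
vector — atan2(R_OF, R_RS) in [0°, 360°) — so 0° means positively
RS-coupled only, 90° positively OF-coupled only, 180° and 270° their
negative counterparts. The per-session angle is the angle of the
(median R_RS, median R_OF) vector. The selectivity index is
(|R_OF| − |R_RS|)/(|R_OF| + |R_RS|): −1 running-only, +1 optic-flow-only,
0 balanced. Sessions with median running speed below 3 cm/s are excluded
(exactly 3 cm/s is included).

**Circular common-median test.** Multi-group angle comparisons use
Fisher's nonparametric common-median test: count, per group, the
observations on the negative side of the pooled circular median and refer
P = N²/(M(N−M)) Σ m_i²/n_i − NM/(N−M) to chi-square with k−1 degrees of
freedom; a label-permutation p-value is available as a cross-check. The
chi-square reference is approximate for a discrete statistic: measured
type-I error is ≈0.054 at 30–60 angles per group and drifts mildly
(0.03–0.06) outside that range. Calibration tests use 40 angles per group.

## Anatomical quantification

Cell tables carry micrometer coordinates in an isotropic 10 μm atlas.
White-matter cells strictly closer than 50 μm to the cortical border
(Euclidean distance transform at voxel resolution, so effectively a
5-voxel threshold; no sub-voxel precision) are reassigned to layer 6b of
the nearest cortical area; ties at exactly equal distance resolve to the
distance transform's deterministic nearest-voxel choice. The operation is
idempotent. Counts per region are reported as fractions of detected cells
per brain (summing to 1 per brain). Density maps divide per-bin
normalized counts by bin volume: dorsal maps use 20 x 20 μm bins times
the local layer thickness (zero-thickness bins are masked NaN), so a bin
holding 1 of 100 cells in 20 x 20 x 250 μm reads (1/100)/1e-4 mm³ = 100;
transverse maps use 10 x 10 x 200 μm slabs upsampled to 5 μm pixels with
linear interpolation. Density x volume summed over bins equals the binned
cell fraction exactly (a conservation law the tests assert). Averaging
across brains normalizes each brain before averaging. The bundled atlas is
a procedural three-region slab (two 6-layered cortical areas, white
matter, one subcortical block) — sufficient for every rule above without
any external atlas download.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; session-level master
seeds spawn per-ROI streams, so results are bit-reproducible. Test and
acceptance problem sizes — 50 ROIs for preference recovery, 2,000
simulated ROIs for suppression calibration, 2,000 null simulations per
statistical-calibration check, 10-minute sessions at 30 Hz for
visuo-motor recovery — were chosen once as the smallest scales at which
the targeted effects are unambiguous. The acceptance script averages
interaction angles over 10 replicate sessions because a single 10-minute
session leaves ~3° of finite-sample correlation noise between the
independent RS/OF processes.

## Known limitations

- The GP's running-speed predictor is exercised structurally (constant or
  trial-averaged speeds) but the generator never couples visual responses
  to running, so speed-modulated tuning is untested against ground truth.
- Amplitude distributions of real bouton responses are unknown; generator
  defaults are plausible placeholders exposed in configuration.
- The chi-square reference of the circular median test is approximate for
  small or very large groups (see above); use the permutation method when
  exactness matters.
- Reward-anticipation behavior is not modeled; only the running-speed
  session gate is implemented.
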