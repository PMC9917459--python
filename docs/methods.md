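# Methods

`gluquant` estimates quantal parameters of glutamatergic transmission from
optical recordings: fluorescence movies (or dF/F time series) of
glutamate-sensor responses at synapses, acquired while action potentials
are evoked in trains under several extracellular calcium concentrations.
This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## The release model

A region of interest (ROI) covers one or a few synapses containing `N`
independent release sites. On each stimulus, site `i` releases at most one
vesicle with probability `P_R` (per-site release probability, set by the
calcium concentration). Each released vesicle adds a fixed fluorescence
increment `q` (the quantal size, in dF/F units). The per-stimulus response
amplitude is therefore `k·q` with

- `k ~ Binomial(N, P_R)` under the binomial model, or
- `k ~ Poisson(lambda)`, `lambda = N·P_R`, under the Poisson model,

plus measurement noise. A stimulus with `k = 0` is a *failure* and is
recorded as exactly 0 by design (this stabilises the downstream histogram
fits; the price is that failures contribute no symmetric peak around 0,
which the fitting model accounts for by treating the `k = 0` component as
a point mass in the first histogram bin).

## Pipeline stages

1. **ROI detection** (`gluquant.roi`). The field is divided into 4x4-pixel
   tiles. A tile is accepted when its mean-intensity time series contains
   more than 20 stimulus-aligned positive transients, each with
   dF/F >= 0.10 and SNR >= 3. Accepted tiles that touch edge-to-edge
   (4-connectivity; the corner-only case is deliberately *not* merged) are
   merged into composite ROIs. Per-tile SNR uses the robust noise SD
   (1.4826 x MAD) computed on quiet frames only — with 5-Hz trains and a
   ~0.4-s sensor decay, response tails occupy most of the recording and
   would otherwise contaminate the noise estimate. Tiles on the grid
   remainder at the field edge are discarded so tile statistics stay
   homogeneous; tiles are screened by their maximum dF/F before the
   per-tile baseline fit, which keeps a 256x256x1500-frame scan at a few
   seconds.

2. **Trace extraction** (`gluquant.traces`). The background signal is the
   frame-wise mean of the dimmest 1-um circular region whose time series
   shows no stimulus-locked modulation (fallback to the global minimum
   with a warning). Background subtraction is frame-wise rather than
   scalar so slow illumination drift cancels. `F0` is the median
   background-subtracted fluorescence over the pre-stimulus window (all
   frames before the first stimulus by default; 10 frames before each
   train for the per-trial baseline-stability diagnostic), and
   `dF/F_j = (F_j - F0)/F0`. ROIs with `F0 <= 0` are flagged invalid and
   excluded downstream.

3. **Baseline and peaks** (`gluquant.peaks`). Slow drift is removed with
   asymmetric least squares (ALS): a second-difference-penalised least
   squares baseline with weight `asymmetry` (default 0.01) for points
   above the baseline and `1 - asymmetry` below, smoothness 1e4 (squared
   frames), 10 reweighting iterations. The defaults leave 5-Hz transients
   untouched while tracking drift with time constants of seconds; the
   pentadiagonal system is solved with a banded solver, so cost is linear
   in trace length. Peak candidates come from the continuous-wavelet
   ridge-line detector with an SNR >= 3 amplitude filter; detections are
   snapped to the local maximum and merged within 2 frames, and a headless
   curation hook (`curate_peaks`) replaces the interactive step of GUI
   suites.

   Per-stimulus amplitudes are extracted at template locations taken from
   the across-ROI mean waveform. Within a 5-Hz train, responses summate on
   the residual of earlier transients, so the extractor first estimates
   the carried-over level from the two frames preceding the search window,
   extrapolated forward with the decay kernel (time constant fitted to the
   post-train tail of the mean waveform, default 0.4 s). The amplitude is
   then a matched-filter estimate: the carry-over-subtracted window is
   projected onto the exponential decay kernel, and the best alignment
   within +/- 2 frames is taken. This estimator is exact on noise-free
   traces (including summating trains) and approximately unbiased under
   noise, whereas a plain windowed maximum inherits a selection bias of
   roughly 0.6-0.9 noise SD — 13-17% of `q` at an event SNR of 5 — which
   would dominate the quantal spacing; the windowed maximum remains
   available as `method="window_max"`. Responses below 2x the amplitude
   noise SD are failures, recorded as exactly 0. ROIs are excluded for
   median event SNR < 3 ("low SNR") or a last-decile/first-decile
   amplitude ratio < 0.5 ("rundown"); the first response in 4 mM calcium
   can optionally be ignored (off by default).

4. **Quantal inference** (`gluquant.quantal`), two routes:

   **CV route.** For each ROI and each train of five responses, the SD is
   paired with the mean; per-ROI points are averaged over trains, and the
   coefficient of variation is the slope of the SD-vs-mean line through
   the origin over ROIs (`CV = sigma/mu` implies proportionality; an
   unconstrained variant is available). For binomial release
   `CV^2 = (1 - P_R)/(N·P_R)`, inverted exactly as
   `P_R = 1/(1 + N·CV^2)` for each candidate integer `N`. With one CV per
   condition every `N` reproduces the data equally well (as many unknowns
   as observations), so `N` is chosen as the smallest integer keeping the
   low-calcium `P_R` below 50% — a deliberately conservative rule; the CV
   route yields a rank order of release probabilities rather than a
   unique `(N, P_R)` pair.

   **Histogram route.** Per ROI, amplitudes are pooled over all conditions
   and binned (default width `q̂/3`, minimum 0.01 dF/F) from 0 so failures
   land in the first bin. An initial spacing estimate `q̂` comes from
   fitting equally spaced Gaussians with free non-negative weights over a
   spacing grid (NNLS per candidate), preferring the largest spacing
   within 10% of the best residual — sub-harmonics (`q/2`, `2q/3`, ...)
   carry more components and buy slightly smaller residuals without being
   the right spacing, so the preference acts as a coarse complexity
   penalty. If fewer than two modes are discernible the median non-failure
   amplitude is used instead. The global fit then optimises, jointly over
   conditions, the quantal size `q`, a component width, a common scale
   factor, and one `P_R` (binomial) or `lambda` (Poisson) per condition;
   component `k >= 1` is a Gaussian at `k·q` with weight given by the
   release-model PMF, and the `k = 0` weight is a point mass in the first
   bin. Binomial components share one width; Poisson component widths grow
   as `sigma_1·sqrt(k)` and the component count is truncated at 99.9%
   cumulative mass. The objective is weighted least squares on binned
   counts with Poisson-variance weights floored at one count; an
   amplitude-ordered objective was considered and rejected as less robust
   to the failure atom. The optimiser is bounded trust-region least
   squares with an analytic Jacobian and 5 jittered restarts
   (deterministic given the seed).

   Goodness of fit is a Kolmogorov–Smirnov comparison of the empirical
   amplitude distribution with the model's mixed CDF (failure atom plus
   weighted Gaussian CDFs), evaluated tie-aware on both sides of every
   sample point so the atom at 0 is handled correctly; p-values use the
   asymptotic Kolmogorov distribution. Because parameters are estimated
   from the same data, these p-values are relative fit scores, not
   calibrated test levels — exactly how they are used.

   **Site-count selection.** `N` is found by brute force over 1..12.
   Candidates whose reachable range `N·q̂` falls clearly below the largest
   observed amplitude are skipped (the site count cannot be below the
   observed quantal level). Among the fitted candidates the score is the
   minimum per-condition K–S probability; because this score is noisy and
   plateaus once `N` covers the observed levels — the binomial family at
   large `N` with small `P_R` can mimic almost any count distribution —
   the *smallest* `N` scoring at least 60% of the best score is selected
   (`plateau_tol`, exposed as a parameter; 1.0 reproduces a strict
   argmax). On the synthetic study conditions this parsimony rule roughly
   doubles true-`N` recovery relative to the strict argmax, which
   systematically overestimates `N` through max-selection bias over ~6
   correlated K–S scores. The scan runs 2 initialisations per candidate
   and refits the winner with the full 5; the per-`N` table is always
   returned in place of a manual check. Model classification prefers the
   release model with the larger minimum per-condition K–S probability,
   with the margin reported and exact ties flagged.

## The synthetic-data generator

`gluquant.synthetic` is the package's test bed and defines the default
study conditions: `N = 5` sites, `q = 0.09` dF/F, `P_R = 0.1/0.4/0.7` at
0.5/2/4 mM calcium, additive amplitude noise SD 0.03, 25-Hz imaging, and
10 trains of 5 stimuli at 5 Hz per condition (50 stimuli per condition,
150 per ROI). Transients rise instantaneously and decay with a single
exponential (default 0.4 s, the order of the slow sensor decay), so 5-Hz
trains summate exactly as the extractor assumes; drift is one slow
exponential plus a linear term; rundown multiplies amplitudes per train;
movies render each ROI as a 2-D Gaussian spot (narrow 0.3 um for targeted
sensors, diffuse 1.5 um) on a constant background with optional Poisson
shot noise. An optional per-vesicle amplitude variability (`quantal_cv`,
default 0) makes the dispersion of the `k`-quantum level grow as
`sqrt(k)`; it is off in the headline recovery conditions (fixed quantal
amplitude) and set to the physiological ~0.33 when data are generated
from the Poisson observation model, whose definition includes
`sqrt(k)`-growing component widths. One master seed drives everything,
with per-ROI substreams derived deterministically.

What the generator does *not* emulate: sensor binding kinetics and
saturation, motion, bleaching, structured (non-Gaussian) backgrounds,
spontaneous release, and spatial overlap of synapses beyond Gaussian
footprints. Passing benchmarks therefore demonstrates the correctness and
statistical behaviour of the analysis chain under the stated model, not
robustness to every artefact of real recordings.

## Benchmark problem sizes

The standard experiments (`gluquant.experiments`, also run by
`scripts/acceptance.py`) use: 20 replicates x 60 ROIs x 150 stimuli for
parameter recovery (~5 min on one core); 50 replicates per arm at 150
events for model classification; one 256x256x1500-frame movie with 10
narrow and 10 broad planted spots for detection; 40 drift-plus-train
traces at event SNR 5 for extraction bias; and two identical small runs
for byte-level determinism. These sizes give stable medians and modal
counts while keeping a full validation run in the tens of minutes.

## Known limitations

- The K–S-based site-count score cannot bound `N` from above on its own;
  the plateau-parsimony rule (and the CV route's explicit conservative
  rule) are design choices, not consequences of the likelihood.
- With 50 events per condition, release-model classification is
  intrinsically noisy: the binomial family at large `N` approximates the
  Poisson closely, and the measured preference rates (binomial arm ~100%,
  Poisson arm ~75%) reflect that asymmetry.
- The mixed-Gaussian model ignores the truncation of near-threshold
  events that the failure-pinning rule introduces; at the study noise
  level this biases the fitted low-calcium `P_R` down by a few hundredths,
  well inside the reported tolerances.
- The mini-event (NBQX) correction implements a frequency-weighted
  amplitude difference; the weighting convention is isolated in
  `correct_minis` so an alternative reading changes one function.
- Line-profile widths are reported both as Gaussian sigma and FWHM
  (2.355 sigma) since width conventions differ between studies.
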