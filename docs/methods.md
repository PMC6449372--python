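# Methods

`wakewatch` implements the computational chain linking a man-made
tidal-structure wake to a predictable seabird foraging hotspot.  Four largely
independent strands — aerial-video bird tracking, ADCP wake
characterisation, tidal-state count modelling, and particle-transit
simulation — share a common set of seeded synthetic-data generators so every
stage can be scored against known ground truth.  This note records the
models, the tunable parameters with their defaults and units, the numerical
choices, and what the synthetic generators do and do not emulate.

## Synthetic scenes (video)

A scene is a stack of 8-bit grey frames over a textured sea-surface
background (Gaussian noise smoothed with sigma 3 px, SD 6 counts on a level
of 60).  Three object classes are rendered additively:

* **Terns** — 2-D Gaussian blobs (sigma = `bird_size_px`/3, default 5 px,
  contrast 90 counts) following correlated random walks: fixed step length
  `bird_speed`·dt (default 6 m/s) with normal turning increments whose SD is
  a monotone function of `bird_sinuosity` (sqrt(2·(s−1)); 1 = straight
  flight).  Headings reflect at the frame boundary.
* **Foam** — larger textured patches (default 26 px, raised-cosine windowed
  smooth noise) advecting downstream at `advection_speed` (default 1.2 m/s)
  and deforming slowly by sliding the sampling window through a per-patch
  noise field.  With `shedding_frequency` > 0 (eddies per minute) patches
  are spawned from a shed line near the upstream edge, alternating sides of
  the street centreline like the eddies of a von Kármán vortex street.
* **Glint** — single-frame 1–2 px speckles, Poisson(`glint_rate`) per frame.

The ground truth lists every rendered object per frame in metre coordinates
(the `ground_sample_distance`, default 0.25 m/px, is a free parameter since
the footage scale is configuration, not physics).  Generators are
bit-reproducible under a fixed seed.

What the scenes do **not** emulate: photorealistic sea surface and wave
motion, perspective or rolling-shutter distortion, plumage detail, lighting
changes, and camera jitter.  Passing detection/tracking tests therefore
demonstrates the correctness of the algorithms under their stated appearance
model, not field-readiness for arbitrary footage.

## Detection

Frame-to-frame differencing (|current − reference| > `diff_threshold`,
default 25 counts) with an optional Gaussian pre-smoothing, restricted by
default to pixels that brightened so the detection sits on the target's
current position.  `frame_lag` chooses the reference frame: 1 for fast small
targets, larger lags (≈2 s) make slowly drifting extended foam stand out.
Segmentation is 8-connected labelling; a 3×3 opening is available but off by
default for bird-sized targets (the area gate already removes 1–2 px glint,
and opening can erode the few-pixel difference lobe of a small mover); a
binary closing (`closing_size`) merges the fragments of large textured
features.  The size filter keeps areas in [min, max]; defaults derive from
the nominal bird blob area ([0.25×, 4×] of pi·(size/2)²).  Centroids are
refined over a padded window weighted by background-subtracted intensity
(floor at 2.5 robust SDs) to remove the forward bias of the
positive-difference lobe; this brings single-target position error to ~0.5 px
RMS.

## Bag-of-features classification

Chips (square crops, rescaled to [0, 1]) are described by a dense grid of
4×4 px cells; each cell contributes an L2-normalised 8-bin
signed-orientation gradient histogram plus one log-compressed gradient-energy
channel.  The energy channel is essential: orientation statistics alone
barely separate a smooth bright blob from foam texture, while local contrast
structure separates them almost perfectly.  Descriptors are quantised
against a k-means vocabulary (k = 200, k-means++ with a fixed seed, single
run) into L1-normalised occurrence histograms and classified by a linear
SVM (squared hinge, L2, C = 1, deterministic primal solver).  Reported
accuracy is the macro (per-class mean) validation accuracy.  Degenerate
chips with no gradient energy encode to the uniform histogram and are
flagged.

## Tracking

Constant-velocity Kalman filter per target (state x, y, vx, vy in metres;
white-acceleration process noise, default intensity 1 m²/s³; observation SD
0.05 m for bird-sized targets).  Association is gated, globally
cost-minimal one-to-one assignment (Hungarian algorithm on Euclidean
distances, default gate 2 m); unmatched detections spawn tracks and tracks
close after `max_misses` (default 5) consecutive misses.  Tracks below the
duration threshold are dropped with a strict inequality (duration > 2 s).
Metrics: path length, net displacement, sinuosity = path/chord (infinite
chords flagged), mean speed, and signed turning angles at interior vertices.
The shedding-frequency estimator counts distinct foam-class tracks crossing
a cross-stream line at least once (re-entries count once) per minute of
observation.

## ADCP processing

Volume backscatter per beam and bin follows the working sonar equation for
Workhorse-class broadband instruments:

    Sv = C + 10 log10((Tx + 273.16) R²) − 10 log10(L) − P_DBW + 2 α R
         + Kc (E − Er)

with slant range R = (B + (L+D)/2 + (n−1)D + D/4)/cos(beam angle), 1-based
bin indexing, and bins beyond 40 excluded.  Defaults: 600 kHz, 20° beams,
1 m bins, transducer at 1.15 m; the instrument constant defaults to
−139.3 dB (a typical Workhorse-class value) and should be overridden with a
calibrated value; Kc and Er are per-beam, and when Er is not configured it
falls back to the per-beam profile minimum.  Seawater absorption α is the
Francois & Garrison (1982) model (boric acid + MgSO4 + pure water, pH fixed
at 8), evaluated at each bin's mid-depth.  None of the headline quantities
depend on the unknown instrument constants: linearity in counts (slope Kc)
and the backscatter anomaly (a difference of Sv values) are constant-free.

True water velocity is measured velocity minus the bottom-track reading
(the seabed's velocity relative to the instrument, i.e. minus boat
velocity); ensembles with invalid bottom track are excluded.  Sections are
bin averages on a regular (y, z) grid with per-cell sample counts.  The
wake-deficit extent takes the depth-averaged speed profile, a reference
speed (default: mean of the outer 20% of the profile), and returns the width
of the contiguous interval around the deficit peak where the deficit is at
least `fraction` (default 0.5) of its maximum, linearly interpolated at the
edges.

The synthetic transect writes the wake as a raised-cosine velocity-deficit
bump; its `deficit_width` parameter is defined as the bump's full width at
half maximum (the quantity the extent estimator measures), with base width
twice that.  Defaults mirror the field setting: 45 m FWHM, peak deficit half
of a 5 m/s upstream flow, +10 dB backscatter anomaly inside the wake,
velocity noise 0.1 m/s and count noise 2 counts per sample.  Echo counts are
produced through the inverse sonar equation so the forward computation
round-trips exactly when noiseless.

## Hurdle count model

Per-minute foraging counts are zero-heavy and overdispersed, so they are
modelled in two parts: presence (binomial, logit link) and abundance given
presence (zero-truncated negative binomial NB2, log link).  Both parts use
site intercepts plus a per-site cyclic smooth of tidal state (hours after
high water).  The smooth is a cyclic cubic regression spline on six evenly
spaced knots over a 12.4 h period (the M2 semidiurnal cycle; the period is
configurable), built by the standard construction (periodic natural-cubic
interpolation gives knot second derivatives m = B⁻¹D·β and curvature
penalty D'B⁻¹D), reparameterised by a fixed sum-to-zero constraint computed
on a dense uniform grid so the same coefficients mean the same curve for
the generator and the fitter.

Presence is fitted by penalized IRLS; the smoothing parameter is chosen by
GCV (n·deviance/(n − edf)²) over a log-spaced grid — GCV rather than REML
because the working-model GCV is exact for this solver.  Abundance is fitted
by penalized maximum likelihood in (β, log θ) with L-BFGS, an AIC-style
score over the same grid, and a numeric Hessian for the covariance; θ is
capped at 10⁴ (fits with all-equal positive counts are flagged degenerate).
Serial correlation is handled by an iterated AR1 working-correlation: ρ is
estimated from lag-1 working/Pearson residuals within surveys, working data
are quasi-differenced (presence) or the covariance deflated by
(1+ρ)/(1−ρ) (abundance), to convergence (≤10 iterations, tol 1e-6).
Covariances are the Bayesian penalized-Hessian form.  The full hurdle
log-likelihood decomposes exactly into the presence log-likelihood plus the
truncated-count log-likelihood, and that identity is tested.

Term tests are Wald-type F statistics on coefficient blocks (site: equality
contrasts; smooths: block = 0) with numerator df = block rank and
denominator df = n − edf.  Under GCV the null smooth is shrunk, which makes
the test conservative by construction; the calibration simulation therefore
runs with the penalty disabled — the claim being calibrated is the F
machinery, not the smoothing.  At roughly 1000 observation minutes per site
the empirical size is at the nominal 5%.

The count generator draws presence from the logit model (optionally with
AR1 latent noise on the link scale, since the field model applies AR1 to
residuals within locations), and positive counts from the zero-truncated NB
by inverse CDF above the zero mass.  Observation minutes follow the
vantage-point protocol: counts at alternating 2/3-minute spacing within
15-min blocks separated by 5-min rests, survey lengths ~N(129, 41²) min,
with a random tidal phase per survey.  One caveat surfaced rather than
resolved: the field protocol describes eight tidal-state bins of "1 h
20 min", which implies a 10 h 40 min cycle and is inconsistent with a
12.4 h period; `bin_tidal_state` defaults to period/8 (= 1 h 33 min) and
the bin width is configurable.

## Particle transit

Passive particles are trickle-released (defaults: 200 particles every
5 min, at 10 m depth, flood-gated by a boolean function of time) into a
steady channel flow with a log-law vertical profile u(h) = (u*/κ)·ln(h/z0)
(clamped at z0, κ = 0.41).  Integration is Euler–Maruyama with dt = 5 s:
horizontal advection plus sqrt(2·Dh·dt) noise, vertical sqrt(2·Dv·dt) noise
with mirror reflection at surface and bed.  Defaults: Dv = 0.01 m²/s
(constant), Dh = scaling × 0.01 m²/s with scaling 1.0 — the contract accepts
any Dh(x, z) field where an eddy-viscosity field is available.  First
crossings of the downstream target are timed by linear interpolation within
the step to avoid dt-granular bias.  Particle counts are conserved exactly
and no particle ever leaves [0, depth].

## Problem sizes used by the test and acceptance runs

Chosen as the package's own desk-scale study conditions: classifier runs at
the study's stated 806+806 training / 3764 validation chips; the shedding
scene is 5 min at 4 frames/s and 12 eddies/min; diffusion-law recovery uses
10⁴ particles over 10 checkpoints of 100 s; the wake transect is 201 pings
over 200 m; hurdle parameter recovery uses 100 replicates at ~2000
observation minutes per site (3-SE coverage aggregated per coefficient);
F-test calibration uses 500 null replicates at ~1000 minutes per site.

## Known limitations

* The appearance model is deliberately minimal; classifier accuracy on the
  synthetic task bounds nothing about real imagery beyond the pipeline's
  correctness.
* The AR1 treatment is a working-correlation approximation, not a full
  mixed-model (GAMM) fit; smoothing-parameter uncertainty is ignored in the
  covariances, as is usual for penalized-likelihood fits.
* The flow model is a steady 1-D channel; transit times through a real
  tidal narrows require an external hydrodynamic model and are out of scope.
* PD0 (raw RDI binary) ingestion and beam-to-earth attitude transformation
  are not implemented; ensembles arrive earth-referenced.
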