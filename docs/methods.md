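# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `dielpath`, in the spirit of a statistical methods
appendix. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and scales

Transcript abundances are relative quantities normalized to a single midday
reference sample, hence unitless and strictly positive. All models operate
on log2 abundance: observed diel fold changes in field transcript data span
roughly 1.3x to over 1,000x, so additive Gaussian errors are only plausible
on a log scale, and log2 keeps effect sizes readable as fold changes. Zeros
are floored at half the smallest positive observed value before the
transform. Missing replicate cells are masked, never imputed; every
likelihood skips masked cells.

Clock time is the primary time coordinate; hours relative to solar dawn are
computed on demand from per-day dawn/dusk metadata. High-frequency
environmental records (5-min default) are paired with transcript samples by
a trailing 60-min mean over the half-open window `(t - 60 min, t]` — the
pairing rule is configurable because no single convention is canonical; a
trailing window avoids using future conditions to explain a present sample.
Whether irradiance should be log-transformed before regression is left to
the caller; the default regresses on raw irradiance after z-scoring.

## State-space engine

Both trend models are linear-Gaussian state-space models and share one
engine: exact Kalman filtering/smoothing, forward-filter backward-sampling
(FFBS), and a Gibbs sampler. Inference is Gibbs-with-FFBS rather than
generic HMC because every model here is linear-Gaussian, so the exact
conditional updates exist and each component is testable against closed
forms (the test suite checks the filter against dense joint-Gaussian
computations and the sampler against the smoother).

Priors (the field data conventions leave them open): inverse-gamma
IG(0.01, 0.01) on every variance — chosen conjugate so the Gibbs variance
updates are exact draws — Normal(0, 10^2) on regression coefficients, and
diffuse Normal(0, 10^2) on initial states. Conditional variances are floored
at 1e-12; near-singular conditional covariances in the backward pass fall
back to an eigenvalue-clipped square root. Default sampling: 4 chains,
1,000 warmup, 1,000 kept iterations; split-Rhat above 1.1 flags
non-convergence (variances are diagnosed on the log scale). The calibration
studies in the tests and acceptance script use 2 chains x (500 warmup + 750
kept) per fit — with conjugate updates and joint state draws the chains mix
within a few dozen iterations, and the reduced size changes only the
Monte-Carlo precision of interval endpoints.

## Smooth trend model (STM)

The baseline condition's latent log2 trend follows a second-order random
walk, `mu[t] = 2 mu[t-1] - mu[t-2] + N(0, s2_mu)`; each further condition
adds a difference component `delta` with the same dynamics, so its trend is
`mu + delta` exactly, draw by draw. A second-order walk penalizes curvature
rather than level, which is what "smooth trend" denotes; a first-order
(local-level) variant is available via `trend_order=1`. The observation
variance is shared across conditions within one fit — replicate noise comes
from the same assay — and significance is pointwise: a timepoint is flagged
when the 95% credible interval of `delta` excludes zero. Multiplicity across
timepoints is acknowledged, not corrected, matching how shaded credible
bands are read in practice; the null-calibration study quantifies the
resulting pointwise false-positive rate (measured well below the 10% bound
at the default settings because smoothing correlates neighboring
timepoints). Residual diagnostics report replicate-mean minus
posterior-median fits and normal Q-Q coordinates at plotting positions
`(i - 0.5)/n`.

## Local level model with exogenous variables (LLMX)

One diel trend `mu[t]`, a first-order random walk indexed by time of day, is
shared by all condition-series in a fit; each series' fitted level adds
linear effects of jointly z-scored drivers (ambient temperature, total
irradiance, upstream transcript log2 replicate mean):

    alpha[s,t] = mu[t] + b_T z(T[s,t]) + b_L z(L[s,t]) + b_U z(U[s,t]).

Joint z-scoring makes the coefficient magnitudes comparable on one panel;
the constants are stored on the fit and reused verbatim for counterfactuals
and prediction. The upstream regressor enters at the same timepoint by
default — transduction delays are the cross-mapping module's question — and
a lag option exists.

The regression coefficients are carried as constant, noise-free state
components so FFBS draws them *jointly* with the trend. This matters: an
upstream driver that itself oscillates is nearly collinear with the shared
diel trend, and a two-block Gibbs scheme (states, then coefficients) mixes
poorly along that ridge (effective sample sizes of a few in our experiments);
the joint draw restores Rhat ~ 1.00.

Counterfactuals clamp one driver at its grand mean (z = 0) in every
posterior draw. Cross-year prediction standardizes new drivers with the
stored constants and maps the fitted trend onto the new grid by clock
time-of-day, linearly interpolated and treated as periodic when the fitted
span covers a full day; identical sampling schedules reuse the knots
directly. Prediction bands quantify posterior uncertainty of the latent
level given the *observed* drivers; measurement noise in the upstream
regressor is not propagated, so coverage of a latent target is nominal only
when the upstream driver is precisely measured (the test suite demonstrates
both regimes).

## Convergent cross-mapping (CCM)

Delay embedding with tau = 1 sample (2 h); embedding dimension selected by
leave-one-out simplex self-forecast at horizon 1 over E = 1..10 (smallest E
on ties; a low maximal skill triggers a warning). Cross-map prediction uses
the E+1 nearest neighbors with exponential weights `exp(-d_i/d_1)`, a
Theiler window excluding |dt| <= E, and distance ties broken by time index,
so results are bit-reproducible under a fixed seed. Multi-condition inputs
are concatenated with segment boundaries recorded; embedding vectors never
span a boundary while neighbor search spans all segments. Library sizes run
from E+2 to all valid points in >= 8 steps, 100 random subsets per size.

Significance at each time-to-prediction tp: the full-library skill must
exceed the 97.5th percentile of skills obtained when the cause series is
replaced by diel surrogates — per time-of-day slot means kept, residuals
permuted over the whole series (unrestricted rather than within-slot: the
null should preserve the diel oscillation and destroy residual ordering).
The convergence flag additionally requires skill to increase from the
smallest to the largest library. Negative tp means the manifold predicts the
cause's past, i.e. the cause leads; a transduction delay of one sample shows
up at tp = -1, smeared by up to E-1 further samples because the embedding
vector spans a window. For aperiodic benchmark systems (the coupled logistic
map) `samples_per_day=1` reduces the surrogate to a plain residual shuffle,
which is the appropriate null when there is no diel cycle to preserve.

## Rhythmicity statistics

The rhythmicity test compares all observations (replicates individually)
against cosine references of a single 24-h period over candidate phases at
the sampling resolution. With tied reference values the Kendall S statistic
is a Jonckheere–Terpstra statistic over reference-ordered groups, whose
exact null pmf is the convolution of Mann–Whitney pmfs over cumulative group
sizes; the test suite verifies it against the exhaustive 8! permutation
distribution to 1e-12. Two multiplicity conventions for the phase scan are
provided. The default multiplies the minimum exact p by the number of
*distinct* two-sided hypotheses (antipodal phases give sign-flipped
references and identical two-sided tests, so 12 phases collapse to 6); this
is the classic convention and is conservative, because neighboring phases
remain positively correlated — a minimum over correlated tests cannot be
uniform under the null. Where calibrated p-values matter (e.g. feeding BH
across many genes), `phase_adjust="permutation"` ranks the observed minimum
p against its Monte-Carlo permutation null (cached per sampling layout;
resolution floor 1/(n_calibration+1)), which is uniform under the null by
construction. BH q < 0.05 defines the rhythmic set; the diel fold change is
the peak/trough ratio of replicate means; the temperature screen correlates
replicate-mean expression of rhythmic genes with aligned temperature and
counts |R| > 0.5.

## Synthetic study conditions

The generator emulates a two-season field campaign on the three-gene
cascade: 2-h sampling over 24–48 h, 6 replicate plants per condition,
log-normal observation noise (sd 0.25 log2 units per replicate).
Environments combine a diel temperature sinusoid (cool profile ~0–14 °C,
warm >17 °C, afternoon peak) with an AR(1) synoptic anomaly (stationary sd
~1 °C, ~2 h correlation time) and a half-sine irradiance curve under
temporally correlated log-normal cloud noise, zero at night. The cascade's
latent log2 levels are

    C = A cos(2 pi (h_dawn - phase)/24) + b_TC z(T) + eta,
    S = b_TS z(T) + b_LS z(L) + b_US C(t - lag1),
    P = [b_TP z(T) + b_UP S(t - lag2)] * gate,

with defaults A = 2 (16-fold diel change), b_TC = +0.4, b_TS = -0.5
(cold-induced mid gene), b_LS = +0.2, b_US = +0.8, b_TP = +0.5, b_UP = +0.8,
lags of one sample, and a light gate zeroing the downstream latent at night
(chloroplast transcription requires light). `eta` is an intrinsic AR(1)
clock wander (sd 0.8 log2 units, per-sample persistence 0.9): field clock
transcripts show large day-to-day amplitude variation, and this aperiodic
component is what distinguishes genuine cross-mapping of the cause from
merely reproducing its diel profile — without it, a diel surrogate band can
never be exceeded, because the cause contains nothing beyond its time-of-day
mean. Multi-condition fixtures z-score drivers jointly across the panel
(`gen_cascade_panel`), so between-season contrasts carry signal. The
coefficient-recovery fixture simulates the mid gene directly from the
regression model on panel-z-scored drivers (same-timepoint coupling,
precisely measured upstream), so the generating coefficients coincide
exactly with the model's estimands; its clock keeps per-series AR(1)
wander, because an upstream driver identical across series is collinear
with the shared trend and its coefficient would be identified only through
the prior (we measured a ~20% downward bias in that degenerate design —
between-series driver variation is what makes recovery well-posed).

What the generator does *not* emulate: assay-specific qPCR error structure,
plant-to-plant latent heterogeneity (replicate noise is iid around one
latent), humidity/precipitation drivers, photoperiod change across seasons,
and mechanistic transcription kinetics. Passing tests therefore demonstrate
correctness and calibration of the estimators under their assumed noise
model, not robustness to every field artifact.

## Problem sizes

Calibration studies use 20 seeded replicate fits (13 timepoints, 6
replicates, 2 conditions each) at 2 chains x (500 + 750) iterations;
coefficient recovery uses 4-series panels at 2 chains x (400 + 600); the
CCM benchmark uses the coupled logistic map at n = 400 with 1,000
surrogates, and the cascade CCM three 48-h conditions (75 samples) with
1,000 surrogates; the rhythmicity null uses 1,000 white-noise genes. These
sizes keep the full suite to a few CPU-minutes while leaving Monte-Carlo
error well inside the asserted margins.

## Known limitations

- Significance conventions are pointwise (STM bands, CCM per-tp bands,
  coefficient CIs); no familywise control across timepoints or tp values.
- The LLMX treats the upstream transcript as an error-free regressor;
  attenuation from replicate noise is second-order here but real.
- CCM on short, strongly periodic series has limited power against the
  diel-surrogate null; detection depends on the aperiodic signal-to-noise
  ratio, and a shared-driver confound can inflate skill (the shuffled-cause
  negative control guards the obvious failure mode).
- The exact rank-test null assumes no ties among observations; replicate
  data on a continuous scale make ties measure-zero, but heavily rounded
  input would need a tie-aware null.
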