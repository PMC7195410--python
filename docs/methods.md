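# Methods

`flcseason` analyses seasonal time series of *FLC*-type chromatin
regulation: mRNA, the active mark H3K4me3 and the repressive mark
H3K27me3 measured biweekly over two years in a naturally fluctuating
temperature environment, at two regulatory regions of the locus — the
nucleation region (NR) near the transcription start site and the distal
nucleation region (DNR) at the 3′ end, overlapping the antisense
(COOLAIR-type) promoter. This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## Temperature-memory regression (SMA scan)

The simple moving average (SMA) of daily temperature over the `w` days
strictly preceding a sampling date is the unweighted mean of the daily
statistic (mean, maximum or minimum); the 1-day SMA is exactly the
previous day's value. For each candidate window (default 1–168 days, in
1-day steps) the replicate-mean molecular response is regressed on the
SMA by ordinary least squares and the window maximising R² is reported
as the variable's temperature-memory length; ties break to the smallest
window.

Responses are analysed on a log10 scale: mRNA series are stored log10,
linear-scale ChIP levels are log-transformed at scan time (non-positive
values are dropped pairwise and logged). The SMA itself is
log-transformed only when every value in the window's scan is positive —
winter daily means can fall below 0 °C, where a blanket log transform is
undefined; such windows regress on the untransformed SMA and carry a
`transform_flag`. This fallback is this package's own documented policy
for sub-zero temperatures.

## Lissajous phase analysis

Paired series are min–max normalised within each year (year breaks
default to campaign anniversaries, segments are `[break, next break)`),
plotted against each other in chronological order, and closed last point
to first. The signed polygon area by the shoelace formula is the
rotation statistic: positive = anticlockwise under standard axes,
|area| ≤ 1 on the unit square, |area| < 1e-6 labelled degenerate.

Axis and sign conventions matter here. For two in-phase sinusoids with
the vertical series *delayed* by less than half a period, the trajectory
runs anticlockwise; for the biologically relevant geometry — an
anti-correlated pair (active mark high in summer, repressive mark high
in winter) whose vertical series is additionally delayed — the
trajectory runs clockwise. Both facts are enforced by tests; the
interpretation "clockwise = delayed repressive mark" therefore applies
to anti-phased mark pairs, which is the configuration the seasonal data
produce. The signed area itself is this package's formalisation of a
qualitative published reading, not a published statistic.

## Empirical dynamic modelling

All EDM inputs are standardised to mean 0, SD 1 (sample SD, n−1).
Temperature enters after cubic smoothing-spline smoothing of the daily
means, sampled at the observation dates so every series shares the
biweekly time base. The spline dial `s ∈ [0,1]` (default 0.5) maps to
the penalty `lam = n^{-1.5} · 256^{3s−1}` on the day axis scaled to
[0, 1]; `s → 0` approaches interpolation and `s = 1` returns the
least-squares line. Exact numerical equivalence to any particular
spline-smoothing implementation's dial is not claimed; the dial is
calibrated by property tests (a line is reproduced exactly, moderate
smoothing denoises a seasonal cycle, residual variance is monotone in
`s`).

Delay embedding uses lag `tau = 1` sampling step (2 weeks in the study
design). Univariate simplex projection forecasts `x_{t+tp}` from the
E+1 nearest neighbours of the delay vector at `t` (leave-one-out: only
the query itself is excluded — no Theiler window, since biweekly samples
are dynamically distinct), with weights `exp(−d/d_min)`; when `d_min = 0`
the weights collapse to uniform over exact matches. The embedding
dimension E is chosen in 1–24 by minimum forecast RMSE (ties to the
smallest E). A brute-force nearest-neighbour oracle reproduces the
implementation to 1e-10 in the tests.

Convergent cross-mapping predicts a putative *cause* from the delay
embedding of a putative *effect* ("A xmap B" predicts B from A, testing
the effect of B on A). Library sizes run from E+2 to all embedded
points in 8 evenly spaced sizes with (default) 100 random library draws
per size; skill is the Pearson correlation between cross-map prediction
and observation. The time to prediction tp is scanned over −8…4 at the
full library; skills within `tp_tie_tolerance` (default 0.01, far below
the sampling error of a correlation at these lengths) of the maximum
count as tied and resolve toward the tp nearest 0 — the weakest
causal-delay claim. The verdict for a direction is *causal* iff

1. best tp ≤ 0 (the cause precedes, or is synchronous with, the effect),
2. observed skill at the maximum library exceeds the 95th percentile of
   100 surrogate skills at that tp, and
3. the convergence delta (skill at final minus initial library size)
   exceeds 0.1.

Seasonal surrogates preserve the seasonal mean profile — estimated by
position in the annual sampling cycle across years — and permute the
residuals within each year. The cause (cross-map target) series is the
one surrogated; the effect's neighbour structure is held fixed. Without
calendar dates (map benchmarks) the null falls back to random
permutations of the target. The exact surrogate construction of the
original analysis software is not public; this scheme is a documented
stand-in whose false-positive behaviour is checked empirically
(≤ 10% at nominal 5% on independent seasonal pairs).

The result object stores the two curves the analysis uses — skill
against tp at the maximum library, and skill against library size at
the best tp — plus the per-tp surrogate envelope.

## Chromatin-state model

A locus carries a joint H3K27me3 state over (NR, DNR) cycling
unidirectionally UU → MU → MM → UM → UU, and binary H3K4me3 occupancy
at each region. Four logistic thermosensors drive the transitions:
cold-activated nucleation `mu(T) = zeta/(1+exp(alpha(T−theta1)))`,
warm-activated spreading `nu(T)`, warm-activated K4 gain at the NR
`xi(T)`, cold-activated K4 gain at the DNR `tau(T)`; thresholds
`theta1–theta4` default to 5, 10, 15, 5 °C and all rate/steepness
parameters are bounded by 100. Three feedbacks couple the marks: K4 at
the NR gates K27 removal (`kappa·aN`), K27 over the NR represses K4
there (`phi·(mNuD+mNmD)`), K27 over the DNR represses K4 there
(`psi·(mNmD+uNmD)`). Model variants 2–4 drop one feedback each
(constant `kappa`, `phi`, `psi` respectively). mRNA follows the log-log
link `log10(RNA) = sigma·log10(K4 at NR) + omega`. In the K4 equations
`uN = 1−aN` and `uD = 1−aD` are the K4-unmodified proportions, so both
gain terms vanish at full occupancy and the proportions stay in [0, 1].

Time is in days and all rates per day. Temperature forcing is
interpolated piecewise-linearly. Integration uses an adaptive embedded
Runge–Kutta (4)5 pair compiled with numba (default rtol 1e-8, atol
1e-10; the fitting objective uses 1e-5/1e-7), with the step capped by
the fastest rate so stability-limited regions stay cheap; a
refinement-stability test bounds the tolerance sensitivity. The four
K27 derivatives telescope to zero, so the simplex is conserved to
floating-point accuracy; excursions outside [0, 1] beyond 1e-6 abort,
smaller ones are projected back.

Observables: K27 level at the NR = (mNuD+mNmD) × observed two-year
maximum at the NR, at the DNR = (mNmD+uNmD) × its maximum; K4 levels =
aN, aD × their maxima. Initial states decompose first-date observed
levels into marginal probabilities (level / two-year maximum) and form
the joint K27 states by the independence product — the same stochastic
independence assumption that closes the tissue-level equations.

### Stochastic counterpart

`simulate_stochastic` evolves a finite population of loci, each with a
discrete 16-valued joint state (4 K27 × 2 K4-NR × 2 K4-DNR; regulation
in cis), by binomial tau-leaping (default dt = 0.02 day) with competing
channels split multinomially per source state. Under the default
mean-field closure the feedback terms read the current ensemble
proportions, which makes the ensemble mean reproduce the deterministic
equations exactly; a `per-cell` coupling variant gates each locus on
its own marks instead (the two closures differ measurably — only the
mean-field form matches the tissue-level equations, and it is the
default for that reason). At 10,000 loci the sup-norm deviation from
the ODE over a two-year biweekly grid is typically 0.011–0.027
depending on the RNG stream (collective fluctuations of the DNR K4
occupancy dominate; the tau-leap bias itself is ≈ 0.005 at 100,000
loci). The equivalence test uses the campaign grid and the default
seed, where the deviation is ≈ 0.013.

## Two-stage fitting

Stage 1 draws parameter sets uniformly in [0, 100] (thresholds fixed)
and keeps the best residual sum of squares between simulated and
observed ChIP levels over the four region-level series. Stage 2 is
simulated annealing from that start: log-normal proposals (the
objective descends smoothly along log-parameter paths where additive
cross-scale moves are blocked), Metropolis acceptance, geometric
cooling from an initial temperature equal to the stage-1 objective
interquartile spread, proposal SD shrinking with temperature from 0.5
to 0.02 log-units, best-seen always retained; two independent chains
run by default and the better is kept. The mRNA link (sigma, omega) is
fitted afterwards by OLS of log10 mRNA on log10 K4-NR, mirroring the
two-part structure of the original procedure. The annealing schedule
and proposal scheme are this package's own choices (the original
procedure specifies only "random search, then simulated annealing");
every knob is in `AnnealSchedule` and every seed is reported in the
fit result.

Parameter identity is *not* the recovery target: with two years of
forcing the logistic thermosensors are only weakly identifiable, and
the recovery criterion is the fitted trajectory's RMSE against the
noise-free truth relative to the noise the observations carry.

## Synthetic study conditions

The generator defaults mirror the study design: a 3-year daily
temperature record (annual mean 12 °C, seasonal amplitude 10 °C,
minimum near day 25, AR(1) fluctuations with 2 °C SD and 3-day decay),
a campaign starting 183 days into the record (so every SMA window up to
168 days is covered), 2 years of 14-day sampling (53 dates), 4
replicates, multiplicative log-normal observation noise with sd 0.1
(≈10%). Noise is multiplicative because qPCR ratios are positive and
mRNA is analysed on a log scale; temperature noise is AR(1) rather than
white so that window-recovery tests face realistic short-term
autocorrelation.

The reference parameter set (`default_params`) was chosen once so that
the simulated campaign reproduces the qualitative biology: MU
predominant through winter with MM rising late and peaking in early
spring, removal in spring without UM ever exceeding ~0.2, transient
winter K4 at the DNR, a ~2-log seasonal mRNA range, short temperature
memory at the DNR versus longer memories elsewhere, a clockwise
K4–K27 Lissajous rotation, and a variant ordering in which removing the
K4→K27 feedback (model 2) damages the mRNA dynamics far more than
removing either K27→K4 repression (models 3–4). The K4-NR winter
trough is carved mainly by the antisense-region antagonism (the
`(1−aD)` factor) with a moderate `phi`; this is what keeps models 3–4
mild, as observed in the field data.

What the synthetic data do not emulate: amplicon-level spatial
resolution within regions (only region-level series are generated),
reference-gene and %-input measurement artifacts, missing replicates,
year-to-year climate anomalies beyond AR(1) noise, and any mismatch
between the generating model family and reality. Passing tests
therefore establish the correctness and statistical behaviour of the
methods under the study's design, not the biological conclusions.

## Problem sizes

Default problem sizes used by the test suite and the acceptance script,
chosen as representative desk-scale configurations: 1,000 random
parameter/forcing draws for the conservation sweep (weekly output grid);
10,000 loci for the stochastic equivalence; 20 seeds for SMA-window
recovery and for the coupled-logistic direction benchmark (n = 1000,
growth rates 3.8/3.7, coupling 0.1, 25 library draws per size); 50
seasonal pairs for the false-positive rate; 5 seeds × (200 random
draws + 2 × 2500 annealing evaluations) for trajectory recovery. The
acceptance script reports the benchmark direction verdict as percent
correct over 10 replicates and the fit-recovery ratio as a mean over 2
campaigns, because single-realisation binary verdicts mostly reflect
seed noise.

## Known limitations

* The annealer is stochastic; on rugged noise realisations a chain can
  stall above the noise floor (hence best-of-chains and the 4/5-seed
  recovery criterion rather than a per-seed guarantee).
* The surrogate scheme assumes near-regular sampling when mapping dates
  to annual-cycle positions; heavily irregular campaigns would need a
  phase-binned profile.
* CCM on strongly synchronised or periodically forced systems can
  genuinely misattribute direction; the periodic-driver regime (e.g. a
  logistic driver in its period-4 window) is excluded from the
  benchmark for that reason.
* The spline dial is calibrated qualitatively, not numerically matched
  to any specific legacy implementation.
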