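# Methods

This note documents the models implemented in `ptfsim`, the parameter
conventions, the numerical choices, what the synthetic input distributions
do and do not emulate, and the known limitations. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Units and time grid

Time advances in 5-minute frames (12 per hour); all rates (`r`, noise
scales) are per frame. OCT4 levels are in arbitrary fluorescence units
(a.f.u.). A 68-hour observation window therefore spans frames 0..816,
i.e. 817 frame times. Real-valued cycle durations are reconciled with the
grid by rounding division times *up* to the next frame, so a mother's last
frame and her daughters' first frame coincide exactly.

## Fractional Gaussian noise

Anti-persistence is the empirical signature the whole framework is built
around: per-cell OCT4 increments have a Hurst exponent near 0.38, so plain
Brownian noise (H = 0.5) is the wrong driver. All stochastic terms are
unit-variance fGn streams with autocovariance

    γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).

Generation uses circulant embedding (Davies–Harte), which is exact in law
for every H ∈ (0, 1): the covariance sequence is embedded into a circulant
matrix of order 2n, its eigenvalues obtained by one FFT, and a coloured
complex Gaussian vector transformed back. Negative eigenvalues cannot
occur for a valid fGn covariance; if they ever did (beyond round-off) the
generator raises rather than clipping. One exact method serves the whole
H range, instead of separate sub- and super-diffusive algorithms — the
output distribution is identical in law, and a single code path is easier
to validate (the test suite compares empirical autocovariances at lags
0–5 against γ(k) within four Bartlett standard errors for
H ∈ {0.2, 0.38, 0.5, 0.8}).

### Hurst estimation

Two estimators are provided; both take the *level* series (an OCT4 trace
or fBm path) and difference it once internally:

* **DFA** (default): the increment profile is linearly detrended over
  log-spaced window sizes from 6 to n/4 (forward and backward sweeps so
  trailing points are used) and H is the log–log slope of the RMS
  fluctuation. DFA is the default because it is markedly less biased on
  short, anti-persistent series.
* **R/S**: the classical rescaled-range statistic. It carries the
  well-known small-sample bias towards 0.5, visible at H = 0.38 on
  1000-point series; it is included for comparison, not for calibration.

Series of 50 frames or fewer are rejected outright, mirroring the
inclusion rule used for experimental traces; the exact window/detrending
configuration used on the original data is not published, so the ensemble
spread of estimates partly reflects estimator choice, not only biology.
With the defaults, the ensemble-mean DFA estimate over 1000-point exact
fBm paths recovers the generating H within ±0.05 (tested at H = 0.38 and
0.7).

## Per-cell dynamics

* **fBm walk**: `O(t) = O(0) + σ_A B_H(t)`. σ_A ≈ 90 a.f.u. per frame is
  the pooled SD of one-frame increments seen in colony data. Optional
  boundaries at 0 and 2500 a.f.u. (the level below which 99.9% of observed
  values fall): *absorbing* ends the series at the first crossing (the
  cell is removed and does not divide), *reflecting* folds the value back
  (v → 2·bound − v, iterated).
* **SLE, additive noise**: `dO/dt = r O (1 − O/K) + σ_A ξ`, explicit Euler
  in O. Below 0 the drift is negative and O diverges, so the series is
  absorbed at 0 — absorbed cells do not divide.
* **SLE, log-space family**: X = ln O with
  `X' = X + r(t)(1 − e^X/K(t)) g(t) + [additive] + σ_M(t) ξ₂`.
  The σ_M term makes fluctuations in O proportional to O (state-dependent,
  "multiplicative" noise, responsible for the positive skew of pooled
  expression at later times). The additive term is the O-space σ_A ξ
  carried through the substitution; to first order it is σ_A e^{−X} ξ.
  **Numerical choice**: that linearisation diverges as O → 0 (kicks of
  order σ_A/O), which is precisely where the Allee model operates, so the
  integrator applies the additive contribution exactly in O-space
  (O' = e^X + σ_A ξ, floored at 10⁻¹²) after the drift and multiplicative
  steps. This is the same model with a stable discretisation; with it, no
  published preset ever reaches the overflow guard (X is capped at
  ln(10⁶ a.f.u.) with a `RuntimeWarning` — hitting the cap is treated as a
  modelling failure, never silent).
* **Allee effect**: `g = (e^X − A)/K(t)` once t ≥ the switch-on time (the
  moment the differentiation agent is added, 43 h in the presets).
  Zero-noise equilibria sit at O ∈ {0, A, K}: A is unstable, 0 and K
  attract. With noise, cells whose expression fluctuates below A after
  switch-on collapse to zero at cell-specific times — differentiation
  becomes a stochastic outcome rather than a label fixed in advance. The
  deterministic prefactor is implemented as r·O·(1 − O/K)·(O − A)/K.

Integration is explicit Euler–Maruyama at dt = 1 frame, matching the
5-minute cadence the rates are quoted in; no sub-stepping. With zero noise
the logistic variants track the closed form
O(t) = K O₀ e^{rt}/(K + O₀(e^{rt} − 1)) within 1% for r ≤ 0.03 per frame.

### Schedules and presets

`r`, `K`, `σ_A`, `σ_M` are right-continuous piecewise-constant schedules
(value of the latest breakpoint ≤ t), which is how all published regimes
are expressed: the additive→multiplicative noise switch at 20 h, the
carrying-capacity drop 1500 → 1000 a.f.u. at 25 h, the differentiated
group's collapse to K = 300 a.f.u. (with r stepped 0.015 → 0.008) at 43 h,
and the Allee switch-on at 43 h with r = 0.025, K = 1290, σ_A = 35,
σ_M = 0.035, A = 1000. The `preset()` factory returns these parameter
sets verbatim and they serialise unchanged through the JSON config format.
One garbled printed table (the differentiation-by-K regime) was
reconstructed from the adjacent text: pluripotent r = 0.015 throughout
with K 1500 → 1000 at 25 h; differentiated K 1100 → 1000 → 300 with
r = 0.008 after 43 h.

## Colony base model

1. Start N₀ cells (the presets assume 14 pro-pluripotent and 2
   pro-differentiated, the published colony's classified starting
   composition).
2. Draw each cell's initial OCT4 and cycle duration from the samplers.
3. Asynchronous mode draws an elapsed-phase fraction ~ U(0,1), so the
   first division happens after (1 − phase)·duration; synchronised mode
   starts everyone at phase 0 (useful to demonstrate division clustering).
   A cell starting mid-cycle is simulated only over its remaining frames.
4. Simulate the cell's series with the dynamics model bound to its fate.
5. At division, both daughters start exactly at the mother's final value
   (symmetric inheritance; asymmetric partitioning is a non-goal) with
   freshly drawn cycle durations from the *same* distribution throughout
   the run — the post-differentiation shortening of cycle times seen in
   experiments is deliberately ignored, as colony growth does not affect
   how each series is generated.
6. Repeat until the division-event budget is spent. The budget counts
   mitoses, not frames: E events from N₀ cells leave N₀ + E cells alive
   (N₀ + 2E lineage records). Excess simulated time is removed afterwards
   by truncating to the window of interest.

Reproducibility: a single root seed drives everything. Per-cell noise
streams and per-cell sampler draws are seeded by hashing
(root seed, cell id, stream index) through `numpy.random.SeedSequence`,
so results are independent of queue iteration order, and noise is
independent across cells — anti-persistence is a within-cell property;
whether it survives division is not constrained by available data.

## Input samplers

Real colony inputs would be kernel-density fits to measured
distributions; `kde_sampler` (Gaussian kernels, Silverman bandwidth,
rejection back into the support) plus `load_empirical` provide that path
for users with data columns. The built-in stand-ins match only the
published summary anchors:

* **Cycle durations**: Gamma truncated to [0.25, 30] h with shape and
  scale solved numerically (via regularised incomplete-gamma moments) so
  the *post-truncation* mean and SD equal 10.3 h and 4 h. Draws invert
  the CDF on [F(low), F(high)], so truncation is exact.
* **Initial OCT4**: lognormal with median 1290 a.f.u. (the carrying
  capacity anchor) and CV 0.25. The CV is not anchored by any published
  summary — 0.25 is a realistic dispersion for fluorescence levels and is
  the single most arbitrary default in the package, exposed prominently in
  `FixtureConfig`.

Both families are positive-support and right-skewed like the real curves,
but they are stand-ins: a green test establishes that the machinery
recovers its own calibration anchors, not that these shapes match the
experimental CDFs (which are not available as data).

## Analysis conventions

* `increment_sd`: sample SD (ddof = 1) of within-cell one-frame
  differences; mother→daughter joins are continuity points (difference 0
  by construction) and are excluded as a simulation artefact.
* `estimate_K`: median of all values in a time window (the convention by
  which K = 1290 and the 1500/1100 pre-25 h values were derived).
* Histogram modes and per-frame mode tracks use the argmax of a Gaussian
  KDE (Silverman bandwidth) rather than a histogram argmax, which is a
  bin-width artefact.
* Time bins default to the [0, 43] h pre-differentiation window in four
  equal bins; the published binning is not printed, so edges are
  configurable everywhere.
* Two-sample KS tests use the asymptotic p-value and reject at p < 0.05;
  repeated pairwise comparisons are reported without multiplicity
  correction, matching common usage (callers can Bonferroni-correct the
  reported p-values themselves).
* Allee fate classification: terminal cells with final OCT4 < A are
  differentiated, the rest pluripotent; ancestors inherit the label when
  all their leaf descendants agree and are `unknown` otherwise (the
  threshold is configurable; A is the natural default since it separates
  the basins of attraction).

## Known limitations

* No spatial structure, motility, contact effects or cell death; fates
  interact with dynamics only through per-fate parameter sets (or the
  Allee mechanism).
* The R/S estimator is biased on short anti-persistent series; use DFA
  for anything quantitative.
* Euler at 5-minute steps is the modelling convention, not a convergent
  discretisation of an underlying continuous SDE driven by fBm (whose
  rigorous integration theory is a research topic of its own); rates are
  defined per frame.
* High-OCT4 differentiation routes and noisy-parameter variants (random
  r or K) are out of scope, as are Gillespie-style chemical simulations
  and formal Bayesian model comparison.
* The additive O-space model absorbs at 0; whether rare negative
  excursions should instead be clipped or reflected is not determined by
  available evidence.
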