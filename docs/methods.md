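# Methods

`aadkit` tracks the attentional focus of a listener in a two-speaker
("cocktail party") scene from a single-trial neural response. The
pipeline has three stages — streaming sparse regression, attention-marker
extraction, and Bayesian fixed-lag smoothing — plus a generative
simulation that provides ground-truth trials for validation. This note
records the models, the parameters that matter, the numerical choices,
and the known limitations.

## 1. Dynamic encoding/decoding estimation

At sampling rate `fs`, with speech envelopes `s_t^(1)`, `s_t^(2)` and a
neural response `e_t` (single channel or a weighted auditory component),
the data are cut into consecutive windows of `W` samples (`W/fs` is the
temporal resolution; 0.25 s at the defaults). Per window k the
coefficients solve the exponentially weighted l1-regularized problem

    theta_k = argmin_theta  sum_{j<=k} lambda^(k-j) ||y_j - X_j theta||^2
              + gamma ||theta||_1 .

*Decoding* reconstructs one speaker's envelope from the response and its
`L_d` future samples (design row `[1, e_t, ..., e_{t+L_d}]`), solved
separately per speaker. *Encoding* predicts the response from both
speakers' lagged envelopes (`L_e` past samples each, shared intercept).
Pre-trial samples are zero; a finished trial's trailing decoding windows
are completed by zero-padding the future so K = floor(T/W) windows exist
(the streaming interface instead signals "window not complete").

The forgetting factor `lambda` sets the effective data length
`W/(1-lambda)` samples (5 s at `lambda = 0.95`, `W = 50`, `fs = 200`;
10 s at `lambda = 0.975`, `W = 16`, `fs = 64`). `gamma` trades fit
against sparsity; the study conditions use 0.001 (simulation decoding),
0.4 (EEG-like decoding) and 1 (MEG-like encoding with the Gaussian
dictionary). Sufficient statistics `(A, b, c)` are updated recursively
(`A <- lambda A + X'X`, ...), so the per-window cost is independent of
history; the quadratic part of the objective is exactly
`theta'A theta - 2 b'theta + c`.

Smooth temporal response functions (TRFs) are represented in an
overcomplete basis of Gaussian kernels (std 20 ms, means every 5 ms over
0–0.4 s lag; 81 columns per speaker, assembled as `diag(1, G0, G0)`).
The l1 penalty is applied in dictionary coordinates (`X -> XG`, report
`G theta`).

### Solver

Each window is solved by forward-backward splitting (proximal gradient):
gradient step on the quadratic, soft-thresholding prox of the l1 term,
Nesterov momentum with restart on objective increase, a
Barzilai–Borwein step initialization and backtracking against the local
majorization. Windows are warm-started at the previous solution
(`theta_0 = 0`).

Stopping uses the first-order optimality residual (the largest
violation of the subgradient conditions), not the objective decrement:
with warm starts the optimum drifts slowly between windows, and an
objective-change test stalls at the warm start after one iteration,
leaving the coefficients permanently stale (the decoder then never
"forgets" a no-longer-attended speaker). The default criterion is
`residual <= tol * max(residual_at_warm_start, gamma)` with `tol = 0.01`
and `max_iter = 500`; an absolute residual target is available for
high-accuracy validation against a coordinate-descent reference. A is
diagonally regularized by `1e-10 * trace(A)/dim` only if its Cholesky
factorization fails (small effective sample sizes can make it singular).

## 2. Attention markers

A marker maps window-k estimates to a positive scalar `m_k^(i)` per
speaker, designed so its distribution differs between the attended and
unattended speaker:

* **correlation** — `|corr(y_k, X_k theta_k^(i))|`, the reconstruction
  quality of that speaker's decoder (shift-invariant, so the intercept
  is irrelevant);
* **l1** — `||theta_k^(i)||_1` excluding the intercept; an attended
  decoder concentrates significant components at auditory latencies
  while an unattended one stays small;
* **m100** — the magnitude of the most negative local minimum of the
  (dictionary-smoothed) TRF within the 60–160 ms lag band, ties within
  2% of the deepest broken toward 100 ms: the M100 deflection is larger
  for the attended talker. If no negative minimum exists the negated
  in-band minimum (floored) is returned.

Markers are floored at `1e-6` so the Log-Normal observation model stays
defined. An *exactly floored* value is an imputed placeholder (e.g. the
correlation of a zero-variance reconstruction in the first warm-up
window), not an observation; downstream, the supervised fit excludes
such values and the state-space model treats them as missing (zero
evidence). Feeding `log(1e-6) = -13.8` into a Gaussian fit in log-space
would otherwise collapse the fitted precision, and the far-tail density
ratio of two fitted laws would assign such placeholders almost surely to
whichever law is wider — both effects were observed to flip the
attended/unattended labeling on occasional seeds.

## 3. Fixed-lag state-space smoother

The attentional state follows a logistic random walk,
`p_k = sigma(z_k)`, `z_k = c0 z_{k-1} + N(0, eta_k)`,
`eta_k ~ Inverse-Gamma(a0, b0)` with `a0 = 2.008`, `b0 = 0.2016`
(mean 0.2, variance 5: weakly informative, favoring small state
variances so the estimate resists marker fluctuations); `c0 = 1` by
default. Given the attended speaker `n_k`, markers are Log-Normal with
(precision, log-mean) `(rho_a, mu_a)` / `(rho_u, mu_u)` under conjugate
Gamma–Normal priors (shape–scale convention for the Gamma factor; the
prior on `mu | rho` has precision `kappa0 * rho`).

Inference runs on an active window of `K_A = K_B + K_F + 1` instances
(15 s worth at the defaults, `K_F` = 1.5 s): at position k0 the estimate
at `k* = k0 - K_F` is emitted and frozen; earlier estimates anchor the
chain (`z_0` of each window is the frozen estimate preceding it; the
first window uses `z_0 = 0`, and startup runs on the growing partial
window). The built-in delay is `(L_d + K_F W)/fs` for decoding and
`K_F W / fs` for encoding (1.9 s, 1.75 s and 1.5 s for the three study
geometries). Trajectories are reported on the attributed time axis
(instance k at `t = kW/fs`), which is exactly the delay-calibrated
display; the transition delay after an abrupt switch is measured on this
axis as the first crossing of p = 0.5.

Two nested EM loops estimate everything per window (20 outer with 1
inner sweep in real time; 20/20 in batch mode):

* **E-step.** Responsibilities `P(n_k = 1 | m, z)` in log-space via the
  antisymmetric contrast `sigma(z + d)`, then the MAP of `z_{1:K_A}`
  given the soft labels by damped Newton on the concave chain objective
  (tridiagonal Hessian, banded Cholesky solves; max 50 steps, gradient
  tolerance 1e-8). Posterior variances come from the inverse curvature
  (Laplace/Gaussian approximation); 90% intervals are
  `sigma(z ± 1.645 sqrt(var))`.
* **Inner M-step.** Conjugate Inverse-Gamma posterior mode per state
  variance: `eta_k = (b0 + v_k/2)/(a0 + 3/2)` with
  `v_k = E[(z_k - c0 z_{k-1})^2]` under the Laplace posterior including
  the chain cross-covariance.
* **Outer M-step.** Gamma–Normal updates of `(rho, mu)` from
  responsibility-weighted log-marker moments, evaluated at the
  responsibilities of the *updated* state (using the stale,
  pre-E-step responsibilities would let the initialization rather than
  the data break the mixture symmetry). The precision update is the
  Gamma posterior mean `alpha_n / rate_n`, which reduces exactly to
  weighted maximum likelihood under a non-informative prior; precisions
  are capped at 1e8 for degenerate pools.

### Supervised initialization and label identity

The Log-Normal laws are initialized by a supervised fit on labeled data
(a separate 15 s constant-attention sample trial in simulation; the
first 15 s of a trial in a recording-like workflow). The priors are then
re-centered on the fits with variances inflated 10x beyond the
estimators' sampling variances — weakly informative, but enough to pin
which law is "attended". Their pseudo-counts are stored relative to the
fit's pool size and rescaled to the active window's data mass at use, so
the anchor keeps the same (1/10) relative influence whether the window
holds 60 instances or a whole trial; a fixed-count anchor would vanish
against long batch windows and lose exactly the identity-pinning role it
exists for.

The whole-trial (batch) posterior is bimodal — a label-swapped mirror
solution always exists — and EM from a neutral start can converge to the
lower mode on weakly separated trials. `batch_estimate` therefore runs
three EM starts (zeros, and ± a block-smoothed state built from the
supervised-fit responsibilities) and keeps the solution with the highest
joint log posterior. The sliding realtime estimator needs no multistart:
its incremental anchoring locks the orientation while windows are small.

## 4. Synthetic study conditions

The decoding-model generator produces
`e_t = w^(1)_t (s^(1)*h)_t + w^(2)_t (s^(2)*h)_t + mu + u_t` with causal
convolution, `mu = 0.02` and `u_t ~ N(0, 2.5e-5)`. The TRF kernel `h`
places +0.5 at 50 ms, −1.0 at 100 ms, +0.2/−0.2 at 150/200 ms, smoothed
by a unit-area Gaussian of std 10 ms. The noiseless weights are
piecewise constant with a step exchange at each switch (speaker 1
attended first) at three separation levels — (0.40, 0.10), (0.30, 0.20),
(0.26, 0.24) for Cases 1–3 — plus `N(0, 4e-4)` noise. The
encoding-model analogue drives the response with attention-modulated
TRFs: the unattended kernel's 100 ms component is −0.4 instead of −1.0.

Envelopes stand in for real speech: rectified low-pass-filtered Gaussian
noise (4th-order Butterworth, 8 Hz cutoff) rescaled to std 0.05 plus a
0.05 floor — non-negative, temporally correlated, with modulation energy
concentrated below 10 Hz and an amplitude scale giving a realistic
response signal-to-noise ratio against the stated noise variances.

What the generator does **not** emulate: the two envelopes are
statistically independent, whereas real concurrent speech envelopes are
mutually correlated and share syllabic rhythm; there are no pauses, no
multichannel noise topography, and no non-stationarity beyond the
attention switch. Consequences observed: correlation markers cross over
within ~1 s of a switch (reconstruction quality follows the *data*
immediately when the competing envelope is independent), so the
realtime estimator's median transition delay on Case-1 trials is
~0.7–0.8 s here, whereas the same generative model driven by real,
mutually correlated speech envelopes exhibits delays around 2–3 s —
the delay measurement is faithful, but the stand-in envelopes make the
task easier in precisely this respect.
Passing the synthetic suite shows algorithmic correctness, not
real-data performance.

## 5. Problem sizes used in validation

Tests and the acceptance script use: 60 s trials at `fs = 200`
(`K = 240` instances), 20 seeded Case-1 trials for delay/classification
statistics, 12 encoding-model trials for the M100 separation test, 10
Case-2 seeds × 11 forward lags (0–5 s) for the forward-lag sweep, 100
random instances (dim ≤ 20) for solver-oracle equivalence, and dense
grid searches on chains of length ≤ 5. A full Case-1 pipeline run takes
a few seconds on one core; the complete suite runs in well under half an
hour.

## 6. Known limitations

* Real M/EEG recordings are out of scope; channel weights for a
  multichannel auditory component are accepted as user input, never
  estimated (offline source-separation is a preprocessing concern).
* Envelope extraction from acoustic mixtures is not provided; clean
  per-speaker envelopes are assumed.
* Exactly two speakers; the mixture link and markers are two-class.
* The Laplace/EM inference is approximate (no particle or exact
  non-Gaussian smoothing); its MAP trajectory is validated against
  exhaustive dynamic-programming grid search on small chains.
* Hyperparameters `a0`, `b0`, `c0` are fixed, not adapted online.
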