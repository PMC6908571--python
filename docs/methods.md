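# Methods

## The data model

All analyses operate on a `PopulationPETH`: a dense nonnegative array of
firing rates indexed (neuron, condition, time) on a uniform grid, one
smoothed peri-event time histogram (PETH) per neuron per condition. The
default grid is −50 to 550 ms in 10-ms bins (61 samples), the analysis
window used throughout. No trial-level (spike) data exist in this model;
trial-to-trial variability, directional tuning, and any other specifically
motor-cortical response feature are deliberately out of scope.

## The simulator

Each simulated PETH is a Gaussian bump

    r(t) = a · exp(−(t − τ)² / w)

with kernel width parameter w = 50 ms² (standard deviation √(w/2) = 5 ms)
and amplitude a drawn once per (neuron, condition) uniformly from
[0.2, 1.2) — the semantics of a unit uniform deviate plus 0.2. Amplitudes
are independent across neurons and conditions, so no pair of neurons has
correlated response strength. The bump center is

    τ(i, c) = onset(group(c)) + (i − 1) · lag

— a per-neuron lag creates a wave of activity running through the
population, and per-condition-group onsets create across-condition
variability. The default population is 218 neurons × 108 conditions to
match the shape of the public monkey dataset the simulations emulate.

Two lag values appear in the canonical configurations because both are
quoted for the original experiments: 1 ms per neuron for the
rotational-dynamics experiments (218 neurons spanning ~217 ms), and 10 ms
per neuron for the order-recovery experiment, where one grid bin of lag per
neuron makes the ordering resolvable by argmax. With 10-ms lags, 218
neurons would overrun the 600-ms window, so the order-recovery
configuration uses 50 neurons (peaks at 0…490 ms); lag is an ordinary
config parameter, and sub-bin lags are honored in the continuous kernel
before sampling (peak measurement for sub-bin lags uses the rate-weighted
centroid, since grid argmax cannot resolve them).

What the simulator does *not* emulate: realistic tuning, multiphasic
responses, noise correlations, non-Gaussian response shapes, or any
trial-level structure. Tests passing on these simulations therefore show
what structure is *sufficient* for the analyzed effects — a consistent
temporal sequence — not that real data contain only that structure.

## Preprocessing and conditioning diagnostics

Two preprocessing steps serve different analyses. *Standardization*
(z-scoring each neuron's condition-appended series, population SD) precedes
plain PCA trajectory plots. *Cross-condition mean subtraction* — removing
each neuron's across-condition average PETH from every condition — is the
skew-fit pipeline's default preprocessing and the origin of its
ill-conditioning.

The `ConditioningReport` carries two numbers:

- `residual_fraction`: ‖data after mean subtraction‖/‖data before‖. It is
  ~0 only when conditions are literally identical.
- `rescaling_residual_fraction`: the residual after additionally removing,
  per (neuron, condition), the best scalar multiple of that neuron's mean
  profile. With the simulator's independent amplitudes, a single-onset
  wave has a large plain residual (~0.38 — pure amplitude jitter) yet a
  rescaling residual at machine precision: the residual conditions are
  random rescalings of one temporal profile and contain no
  condition-specific temporal structure for a dynamical fit to explain.

The degenerate flag is raised when either fraction falls below 1e−8. The
second diagnostic exists because amplitude-only variability is exactly the
degeneracy observed in practice (shuffled or single-group data), while the
plain norm ratio stays far from zero there. A degenerate report never
aborts the pipeline — the fit runs and returns its (noise-dominated)
result — but it is propagated onto the rotation summary and logged.

## The skew-symmetric dynamical fit

Given per-condition k-dimensional PCA trajectories (k = 6 by default,
chosen to match the standard usage of the method), derivatives are formed
by forward first differences, Ẋ(t) ≈ (X(t+Δ) − X(t))/Δ, with the state
taken at the left sample; all conditions' (X, Ẋ) pairs are pooled into one
regression, since "all conditions rotate alike" is a single-fit property.
The first-order scheme's frequency bias is O((ωΔt)²) and is covered by a
convergence test.

M_skew minimizes ‖Ẋ − X·Mᵀ‖_F over skew-symmetric M. The solver
parameterizes M in the k(k−1)/2 elementary skew basis matrices and solves
one ordinary least-squares problem in the coefficients; antisymmetry is
exact by construction. Tests verify the solution against two independent
oracles: the stationarity (Sylvester/Lyapunov-type) equation
M·(XᵀX) + (XᵀX)·M = ẊᵀX − XᵀẊ, and direct numerical minimization for
k = 3. The unconstrained least-squares matrix M_best is fitted alongside;
goodness of fit is reported as uncentered R² = 1 − ‖residual‖²/‖Ẋ‖² for
both (derivatives are essentially centered already), and r2_skew ≤ r2_best
always.

Rotation planes come from the eigendecomposition of M_skew: conjugate pairs
±iω, sorted by ω descending, each yielding a real orthonormal 2-basis from
the real and imaginary parts of one eigenvector (QR, deterministic sign
fix). Per-condition projections are scored by the sign of the summed cross
product of consecutive states; *direction consistency* is the majority
fraction across conditions (1.0 = all conditions rotate the same way,
~0.5 = chance). The plane is oriented so the majority rotates
counter-clockwise, for reproducible plots. If the fitted dynamics have no
nonzero rotation frequency (numerically all-zero M_skew, as happens for
synchronous populations without mean subtraction), the pipeline summarizes
the leading PC plane with ω = 0 instead of failing.

Thresholds used by the acceptance tests — r2_skew/r2_best ≥ 0.5 and
direction consistency ≥ 0.95 for "rotational", chance-level by binomial
test (α = 0.01) for "non-rotational" — are constants of this package's
test harness, not quantities estimated from data.

## Canonical simulation experiments

- **Single-onset wave** (onset 50 ms, 1-ms lag): all conditions
  statistically identical; with mean subtraction the conditioning
  diagnostic fires and the fit returns noise.
- **Two-/three-onset waves** (onsets 50/200 ms over conditions 1–54 and
  55–108, or 50/150/200 ms over thirds): the same wave with modest
  across-condition variability; mean-subtracted fits produce consistent
  rotations (consistency 1.0 at the default seed).
- **Synchronous population** (no lag, three onsets): no temporal sequence;
  no preprocessing variant produces consistent rotation.
- **Mean subtraction off**: every temporally-spread dataset — including
  per-neuron condition-shuffled data — rotates consistently; the
  synchronous one does not.

## Lissajous regression

Targets are x = cos 2πt/T, y = sin 2πt/T (circle) or y = sin 4πt/T
(figure-eight), with t measured from window start and T equal to the
600-ms window, so the circle closes once per trial. x and y are fitted as
two independent OLS regressions (intercept included, switchable) on the
design with one row per appended time sample of the training conditions
and one column per neuron; generalization uses the even/odd condition
split. Rates enter raw (no standardization), and R² is the conventional
centered coefficient of determination.

The regression experiments use a wave whose sequence *tiles* the window
(onset −50 ms, lag 600/218 ≈ 2.75 ms), because a readout can only
synthesize the target where regressors are active — mirroring how real
populations' peak latencies spread across the trial. Its three condition
groups have onsets one grid bin apart (−50/−40/−30 ms), emulating small
movement-initiation jitter. This choice matters structurally: with a
single onset group, per-neuron condition shuffling only permutes i.i.d.
amplitudes and changes nothing statistically, while with large (≥100 ms)
onset separations the *original* data are the harder regression problem —
coherent group shifts defeat a single fixed readout more than neuron-wise
mixing does — and shuffling would paradoxically improve the fit. Small
coherent jitter keeps all conditions servable by one readout (circle
r2_train ≈ 0.95, held-out r2 ≈ 0.96 at the default seed) while shuffling
scrambles cross-neuron timing coherence and measurably degrades the
figure-eight prediction, the pattern the experiments are designed to show.

## Numerical choices and edge cases

- Peak time = grid argmax of the (already smoothed) PETH; ties break to the
  earliest time, then the lowest neuron index; all-constant rows are
  flagged degenerate and assigned the window start.
- Subpopulation split sizes use ceil-first allocation (218 → 73/73/72);
  group averages are always computed on raw rates — the display
  normalization (subtract mean, divide by peak) is for plotting only.
- Pairwise correlation defaults to Pearson on across-condition average
  PETHs; condition-appended time courses can be passed instead. Zero-
  variance rows yield NaN with a warning.
- PCA uses the SVD of the column-centered (appended time × neurons)
  matrix; loadings are sign-fixed (largest-magnitude entry positive) for
  backend-independent output.
- Rank-deficient regressions (skew fit, Lissajous fit) fall back to
  minimum-norm least squares with a logged warning rather than failing;
  underdetermined Lissajous designs likewise interpolate with a warning.
- The forward shift requires a positive multiple of the grid step; padding
  uses each PETH's own first sample, and the shifted-out tail is dropped.
- All stochastic operations (amplitude draws, shuffles, random splits) take
  explicit integer seeds; identical seeds give bit-identical arrays.

## Known limitations

- The simulator's Gaussian-bump responses are narrow (5-ms SD) relative to
  the 10-ms grid; off-grid bump centers are therefore under-sampled, which
  is faithful to the generating equation but means sampled peak values can
  undershoot drawn amplitudes for sub-bin lags.
- Direction consistency is a sign statistic; it does not measure curvature
  magnitude, and near-linear trajectories produce arbitrary signs (handled
  by the chance-level null, not by a magnitude threshold).
- The optional reader for external per-condition MAT-style containers is
  intentionally untested plumbing; the package's claims are established on
  synthetic data only.
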