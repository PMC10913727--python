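# Methods

This note documents the model, the estimators, the numerical choices and
the design decisions behind `mssid`, in the spirit of a methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The multiscale dynamical model

A single latent linear-Gaussian state `x[t] ∈ R^{n_x}` drives two
observation streams: Gaussian continuous features `y[t] = C_y x[t] + r_y`
(e.g. band-power features of field potentials) and Poisson spike counts
`N[t] ~ Poisson(exp(C_z x[t] + d_z))`, where `z = C_z x + d_z` is the latent
log firing rate per bin. The structural assumptions are those required by
the causal multiscale filter: the log rate carries no additive Gaussian
noise (`R_z = 0`), the spike and field observation noises are uncorrelated
(`R_zy = 0`), and state noise is uncorrelated with observation noise
(`S = 0`). Counts are modeled as Poisson (any nonnegative integer per bin),
not as a binary point process. Two equivalent parameterizations are used
throughout: the noise form `{A, C_y, C_z, Q, R_y, d_z}` (consumed by the
filter) and the covariance form `{A, C_z, C_y, G_z, G_y, Λ0, d_z, Σ_x}`
(produced by identification and used for evaluation), related by the
stationary identities `Σ_x = A Σ_x A' + Q`, `(G_z G_y) = A Σ_x C'`,
`Λ0 = C Σ_x C' + blockdiag(0, R_y)`.

`exp(z)` is a per-bin rate; the physical bin width (default 10 ms) is
carried as metadata only and enters nothing but the Hz↔per-bin conversion
in the simulator.

## Moment transformation

The log rate is latent, so its second-order statistics are obtained from
the observable count moments through the closed-form Poisson/log-normal
relations (for channels i, j and means μ of the counts):

    μ_z[i]       = 2 log μ[i] − ½ log(Var[N_i] + μ[i]² − μ[i])
    Var[z_i]     = log(Var[N_i] + μ[i]² − μ[i]) − log(μ[i]²)
    Cov[z_i,z_j] = log(Cov[N_i,N_j] + μ[i]μ[j]) − log(μ[i]μ[j])
    Cov[z_i,y_j] = Cov[N_i,y_j] / μ[i]

The `− μ` correction applies only when both sides are the same channel in
the same bin (the Poisson noise term); at nonzero lags, and across
channels, the plain cross relation is used. Sampling noise can push a log
argument nonpositive; arguments are floored at `1e-6 · μ_i μ_j`
(`clip_eps`), and a warning is emitted when more than 1% of entries hit the
floor, which indicates the series is too short for reliable transformation.

## Moment estimation for multirate data

The identification statistics are the stationary lag covariances
`Λ_k = Cov[·_{t+k}, ·_t]` of counts and features. When the continuous
modality is only observed every `M`-th bin, the default estimator never
interpolates the series; each statistic uses only actually observed
samples:

- spike–spike lags, every bin of the recording;
- spike–field lags at *any* integer lag, using the bins where the field is
  observed as anchors (one observed endpoint suffices);
- field–field lags at multiples of `M`, where both endpoints fall on the
  observed grid.

The future–past cross-covariance (Hankel) matrix is then laid out with
field offsets at stride `M`: its row factor stacks
`C_z, C_z A, …, C_z A^{h_z−1}` over `C_y, C_y A^M, …, C_y A^{(h_y−1)M}`,
and its column factor stacks `G_z, A G_z, …` beside
`Ã_y, A^M Ã_y, …` with `Ã_y = A^{M−1} G_y`. Every cell of this matrix is a
directly estimated lag covariance, and the factorization `H_w = O_w C_w`
remains exact. At `M = 1` this reduces to the standard single-rate layout.

The joint shift-invariance least squares over both modalities' row blocks
then estimates the `M`-step transition `F = A^M` (using `M`-step shifts of
the spike blocks alongside one-block shifts of the field blocks), and the
per-bin `A` is the principal real matrix `M`-th root of `F`. The principal
branch is the correct one whenever every mode angle is below `π/M`; the
slow oscillatory dynamics modeled here (angles ≤ 0.0316 rad, `M = 5`) are
two orders of magnitude inside that bound. A warning flags a non-negligible
imaginary part in the root, which would indicate angle aliasing. `G_y` is
recovered from the first field column block by solving
`A^{M−1} G_y = Ã_y`.

Why not interpolate? Covariances of an interpolated series are biased in
two ways that subspace identification is maximally sensitive to: the
interpolation filter spreads the white observation noise of each observed
sample across its neighbors (at unit-order SNR this roughly doubles the
short-lag field autocovariances), and above-Nyquist signal power folds into
the band. Both distortions are smooth, damped-oscillatory functions of lag
— exactly what the shift-invariance step reads as additional dynamical
modes — and neither shrinks with more data. A zero-phase FIR interpolator
(`interpolate_continuous`, Kaiser-windowed sinc with per-phase
normalization, cutoff `π/M`, four-original-sample half-length, edge
replication) and a stacked-window covariance estimator are nevertheless
provided and tested (`MultiscaleSID(moment_estimator="stacked")`): training
on interpolated data is the conventional procedure, is exact at `M = 1`,
and is useful for comparison, but the lag-domain estimator is the default
because it is unbiased at every `M`.

All sample covariances use the `1/(n−1)` estimator with global (per-channel
stationary) means. In the stacked path, one common anchor set
`t ∈ [h+1, T−h+1]` (1-based, `h = max(h_z, h_y)`) is used for all moments
so cross-covariances are over paired windows; a brute-force oracle test
pins the streamed implementation to the naive stacked covariance exactly.

## Channel-scale balancing

Log-rate variances (≈ 0.2–1) and field-feature variances (tens) live on
very different scales, and the rank-`n_x` SVD truncation of an unbalanced
Hankel buries spike-dominated directions under the field blocks. The Hankel
is therefore symmetrically scaled to unit per-channel zero-lag variance
before the SVD, and the extracted factors are unscaled afterwards. The
operation is exact in population (the noiseless-identifiability test covers
it) and corresponds to the common practice of z-scoring features before
covariance-based identification; it can be disabled with
`balance_channels=False`. A separate, user-facing `zscore` option
standardizes the continuous channels of the data themselves (statistics
from the training set, inverted at prediction time).

## Valid noise statistics

Covariance-based SID gives no guarantee that the implied `Q` and `R_y` are
positive semidefinite, and the multiscale filter additionally needs the
structural zeros `R_z = R_zy = S = 0`. Writing all noise statistics as
affine functions of the stationary state covariance `Σ_x`, the package
solves

    min_{Σ_x} ‖S(Σ_x)‖_F + ‖R_z(Σ_x)‖_F + ‖R_zy(Σ_x)‖_F
    s.t.      Σ_x ⪰ 0,  Q(Σ_x) = Σ_x − A Σ_x A' ⪰ 0,
              R_y(Σ_x) = Λ0^yy − C_y Σ_x C_y' ⪰ 0,

a convex problem (sum of norms of affine maps under concave
minimum-eigenvalue constraints). Solver design:

1. The *unconstrained* least-squares minimizer of the squared objective is
   available in closed form (a linear solve over the `n_x(n_x+1)/2` free
   entries of `Σ_x`). When it already satisfies the PSD constraints — the
   typical case with well-estimated statistics — it is returned directly
   and the objective at that point is reported (`status:
   "least-squares"`).
2. Otherwise `scipy.optimize.minimize(method="trust-constr")` minimizes a
   smoothed objective (`√(‖·‖² + 1e−14)` per term, analytic gradients)
   under minimum-eigenvalue constraints with analytic eigenvector
   gradients, started from the eigenvalue-clipped least-squares point. The
   PSD constraints carry a small slack (`1e−9` × the trace scale) to avoid
   failures at exact-boundary optima.
3. If that fails, a penalized quasi-Newton fallback parameterizes
   `Σ_x = L L'` and minimizes the objective plus squared hinge penalties on
   negative eigenvalues of `Q` and `R_y` (`status: "fallback"`,
   approximate).

The returned `Q`, `R_y`, `Σ_x` are eigenvalue-clipped at zero and
symmetrized, so the output is PSD regardless of input noise. Unit weights
are used on the three objective terms. The minimizer need not be unique;
tests assert the objective value and PSD-ness except in the scalar instance,
where the optimum is unique and known in closed form. Afterwards the model
is *finalized*: `S`, `R_z`, `R_zy` are set to exactly zero and `G_z`,
`G_y`, `Λ0` recomputed from `Σ_x`, which makes the two parameterizations
exactly consistent. The raw (pre-finalization) cost terms are kept in the
fit diagnostics; their norms, normalized by the corresponding total
covariances, are the constraint-satisfaction diagnostics reported by the
evaluation module (with `‖R_y‖/‖Λ0^yy‖` as the control that is *not* in the
cost and should not shrink with more data).

## The multiscale filter

Prediction is linear (`x⁻ = A x, P⁻ = A P A' + Q`); the update maximizes
the joint log posterior combining the Gaussian prior at `x⁻`, the Poisson
likelihood of the bin's counts, and — only at bins where the field is
observed — the Gaussian feature likelihood, via Newton–Raphson (≤ 25
iterations, gradient tolerance `1e−9`, initialized at `x⁻`), with the
filtered covariance the inverse negative Hessian at the mode. Spike and
field updates are applied jointly in one objective, not sequentially. With
no spike channels the objective is quadratic and the update *is* the Kalman
filter (pinned to `1e−10` against an independently coded KF); with no field
channels it is the Laplace point-process filter. Initialization is the
stationary prior `x[1|0] = 0`, `P[1|0] = Σ_x`; when the learned `A` is
unstable (possible on short data — no stabilization is applied, since
silently projecting eigenvalues would corrupt mode-error evaluation), the
filter warns and initializes with `Q`. Non-converged Newton steps fall back
to the predicted mean with a warning. The availability mask is
authoritative: values stored at missing bins are never read, and no
interpolation is performed at inference time.

One-step predictions are `y[t|t−1] = C_y x[t|t−1]`,
`z[t|t−1] = C_z x[t|t−1] + d_z`, and the probability of at least one spike
`p = 1 − exp(−exp(z[t|t−1]))`.

## The simulator

`generate_random_model` draws ground-truth models with a controlled mode
structure; its defaults are the standard study conditions used throughout
the validation:

| parameter | default | meaning |
| --- | --- | --- |
| mode layout | 2 shared + 1 spike-only + 1 field-only, all complex | `n_x = 8` |
| eigenvalue magnitude `r` | U[0.950, 0.999] | slow decay (0.2–10 s at 10 ms bins) |
| eigenvalue angle `θ` | U[0, 0.0316] rad | ≤ 0.5 Hz oscillations |
| bias firing rate | U[5, 10] Hz | sets `d_z = log(f_bias · Δ)` |
| max firing rate | U[40, 50] Hz | sets the +2σ rate of `exp(z)` |
| field SNR | U[0.8, 1.2] | `diag(C_y Σ_x C_y') / diag(R_y)` |
| bin width Δ | 0.010 s | metadata / rate conversion |
| `M` | 5 | field features every 5th bin |

`A` is block diagonal with 2×2 rotation blocks `r·R(θ)` (fully general up
to similarity); `Q` is diagonal with `|N(0,1)|` entries; `C_z`, `C_y`
entries are U(−1, 1) before scaling. Distinct modes are created by zeroing
the excluded modality's loading columns; the modes contributing to a
modality are then column-scaled to equal contributions
`cntrb_i = trace(C̄_i Σ̄_{x,i} C̄_i')`, and rows of `C_z` are rescaled so
each neuron's bias and +2σ rates match the drawn Hz targets (row scaling
perturbs the column equalization slightly; the zero contributions of
excluded modalities are preserved exactly). `R_y` is diagonal from the
per-channel SNR draws. Simulation starts at `x[0] = 0` (so the first few
hundred bins are a sub-stationary transient), generates `y` at every bin
and discards off-grid bins as missing (NaN plus an authoritative boolean
mask), and draws counts elementwise. A log rate above 50 aborts with a
rate-explosion error naming the channel.

What the generator does *not* emulate about real recordings: non-Poisson
count dispersion, nonlinear or nonstationary dynamics, cross-channel
observation-noise correlations, electrode geometry, and the spectral
structure of real field-potential features (the simulated features are a
low-pass latent signal plus white noise). Passing the validation suite
therefore demonstrates correctness of the estimators under the model
class, not performance on any particular real dataset.

## Evaluation

Latent models are only identified up to an invertible change of basis, so
before parameter comparison the learned model is aligned to the truth by
the transform minimizing `‖O_w^learned T − O_w^true‖_F` (extended
observability matrices built at stride 1 with horizon
`min(10, 2⌈n_x / min(n_y, n_z)⌉)`); a condition number above `1e8` triggers
a warning. Errors are `‖ψ^id − ψ^true‖_F / ‖ψ^true‖_F` for
`ψ ∈ {eig(A), C_z, C_y, G_z, G_y, Λ0, d_z}`; `Σ_x` is excluded because it
is not identifiable even up to similarity. The normalized mode error
matches learned to true eigenvalues by minimum total complex distance
(Hungarian assignment; the cost is conjugation-symmetric, so the optimal
value respects conjugate pairs) and can be restricted to a subset of true
modes (shared / spike-only / field-only), using rectangular assignment.

Prediction metrics: mean per-channel Pearson correlation for continuous
predictions; prediction power `PP = 2·AUC − 1` of the spike-event
probability against the at-least-one-spike indicator (single-class channels
are skipped with a warning). Behavior decoding is ordinary least squares
from filtered states with an intercept, `L = B X'(X X')^{−1}`, with a tiny
ridge fallback if `X X'` is singular; decoding operates at the fast (bin)
timescale. Cross-validation uses contiguous equal blocks (remainder to the
last block); state-dimension selection fits each candidate on the first 80%
of the training block and keeps the candidate with the best behavior CC on
the remaining 20%, ties to the smallest dimension.

## Numerical choices

- PSD checks: eigenvalues ≥ −1e−8 relative to the largest magnitude;
  covariances are re-symmetrized (`(M + M')/2`) after every computation.
- Lyapunov equations: direct Schur-based solver (`scipy`).
- Pseudoinverses and SVD truncation: relative cutoff `1e−12`; the top
  `n_x` singular values are kept with no gap heuristic (`n_x` is user
  supplied; data-driven selection lives in `select_state_dim`).
- Horizons default to `h_z = h_y = 10`; a warning fires when a horizon is
  at or below `⌈n_x / n_channels⌉` for its modality (observability
  guidance). The multirate layout additionally needs `h_z > M` for the
  spike blocks to contribute to the `A^M` estimate.
- Problem sizes in the validation suite were chosen to exercise the
  method's reported operating points while keeping the suite quick: the
  long-run study uses 3 models at 10^6 bins, the session-scale study 5
  models at 5×10^4 bins, and the fusion study 10 seeds at 2×10^4 bins with
  6 + 6 channels.

## Known limitations

- Linear, time-invariant dynamics only; no adaptive or switching variants.
- The `A^M`-root construction assumes all mode angles are below `π/M`;
  faster oscillations relative to the slow modality's rate would alias.
- The moment transformation needs strictly positive mean counts and enough
  data for the log arguments to be positive; very sparse channels dominate
  the loading-matrix errors at moderate `T`.
- No stabilization of the learned `A`: short-data fits can be unstable, in
  which case conversion to the covariance form fails loudly and filtering
  falls back to a non-stationary prior.
- `Σ_x` (and therefore `Q`, `R_y`) is reported as *a* valid solution of the
  constrained problem, not a unique one.
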