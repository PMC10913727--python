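# mssid — multiscale subspace identification for spike/field dynamics

`mssid` learns latent linear dynamical models of *multimodal* neural
population activity — discrete spike counts recorded every time bin together
with continuous field-potential features that may only be available every
M-th bin — using a non-iterative, covariance-based subspace identification
(SID) algorithm. It is aimed at computational neuroscientists and
neural-engineering researchers who need fast, repeatable model fitting for
spike–field recordings (e.g. for brain–machine interfaces or analyses of
shared vs. modality-specific population dynamics), but applies to any
discrete–continuous time-series pair with Poisson and Gaussian observations.

## Model

The multiscale dynamical model couples one latent linear state to both
modalities:

    x[t+1] = A x[t] + q[t],                 q ~ N(0, Q)
    y[t]   = C_y x[t] + r_y[t],             r_y ~ N(0, R_y)
    z[t]   = C_z x[t] + d_z
    N[t]   ~ Poisson(exp(z[t]))

with `x ∈ R^{n_x}` the latent state, `y ∈ R^{n_y}` the continuous features,
`z ∈ R^{n_z}` the latent log firing rate and `N` the spike counts. The
*dynamical modes* are the eigenvalues of `A` (a real eigenvalue or a complex
conjugate pair per mode); modes may be shared between the modalities or
distinct to one of them.

Learning is analytical rather than iterative:

1. The moments of the unobservable log rate are obtained from the observable
   count moments through closed-form Poisson/log-normal relations, e.g.
   `Cov[z_i, z_j] = log(Cov[N_i, N_j] + μ_i μ_j) − log(μ_i μ_j)`.
2. The future–past cross-covariance `H_w = Cov[w_f, w_p]` of the stacked
   (log-rate; field) vectors factorizes as observability × reachability,
   `H_w = O_w C_w`; a rank-`n_x` SVD recovers the factors, slices give
   `C_z, C_y, G_z, G_y`, and a joint shift-invariance least squares gives `A`.
3. Valid noise statistics are enforced by a convex constrained optimization
   over the stationary state covariance `Σ_x`:
   minimize `‖S(Σ_x)‖_F + ‖R_z(Σ_x)‖_F + ‖R_zy(Σ_x)‖_F` subject to `Σ_x`,
   `Q(Σ_x) = Σ_x − A Σ_x A'` and `R_y(Σ_x) = Λ0^yy − C_y Σ_x C_y'` all PSD —
   this is what makes the learned model usable inside a causal filter.

Inference uses the multiscale filter (MSF): a Kalman-style predictor with a
Laplace-approximated joint update for the Poisson and Gaussian likelihoods.
It handles the multirate missingness directly (no interpolation at test
time) and reduces exactly to the Kalman filter (`n_z = 0`) or the
point-process filter (`n_y = 0`).

## Worked example

```python
import numpy as np
from mssid import (MultiscaleSID, SimConfig, generate_random_model, simulate_data,
                   pset_from_nset, evaluate_identification, prediction_cc,
                   prediction_power)

# ground truth: 4 oscillatory modes (2 shared, 1 spike-only, 1 field-only),
# 10 spike + 40 field channels, 10 ms bins, field features every 5th bin
cfg = SimConfig(n_z=10, n_y=40, M=5, seed=0)
truth, modes = generate_random_model(cfg)
data = simulate_data(truth, T=100_000, M=5, seed=1)

est = MultiscaleSID(n_x=8, h_z=10, h_y=10).fit(data)

report = evaluate_identification(est.cov_params_, pset_from_nset(truth), modes)
print("normalized mode error: %.2f%%" % (100 * report.mode_error))
for name, err in report.param_errors.items():
    print(f"  {name:8s} error: {100 * err:5.2f}%")

test = simulate_data(truth, T=10_000, M=5, seed=2)
out = est.filter(test)
print("one-step field CC:  %.3f" % prediction_cc(test.y[test.mask], out.y_pred[test.mask]))
print("one-step spike PP:  %.3f" % prediction_power(test.N, out.p_event))
```

Output:

```
normalized mode error: 0.22%
  eig_A    error:  0.22%
  C_z      error: 23.02%
  C_y      error:  6.10%
  G_z      error: 14.72%
  G_y      error: 19.42%
  Lambda0  error:  3.98%
  d_z      error:  0.96%
one-step field CC:  0.593
one-step spike PP:  0.433
```

The mode (eigenvalue) error is the normalized distance between the learned
and true spectra of `A` after optimal matching — here well under 1% from
10^5 bins (about 17 minutes of 10 ms bins). Loading-matrix errors are
reported after similarity-transform alignment of the latent bases and are
dominated by the sparsest channels; they fall below 6% as the training
length grows toward 10^6 bins (see the reproduction script below). The
prediction numbers are one-step-ahead accuracies on held-out data: mean
Pearson correlation for the field features and prediction power
(2·AUC − 1; 0 = chance, 1 = perfect) for spike-event occupancy.

A command-line interface mirrors the library:

```sh
mssid simulate --nz 10 --ny 40 --t 50000 --m 5 --seed 1 \
      --data-out data.h5 --truth-out truth.h5
mssid fit --input data.h5 --nx 8 --output model.h5
mssid predict --model model.h5 --input data.h5 --output states.h5
mssid evaluate --model model.h5 --truth truth.h5 --data data.h5 --report report.json
mssid reproduce --scale smoke --out-dir tables/
```

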