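"""From raw multimodal data to the transformed second-order statistics.

Subspace identification needs the future-past cross-covariance of the stacked
log-rate / continuous vector, but the log firing rate z is latent: only the
Poisson counts N are observed.  This module (i) interpolates the slow
continuous modality to full rate, (ii) computes empirical means and
covariances of the stacked future-past count and continuous vectors, (iii)
maps the count moments to log-rate moments through the closed-form
Poisson/log-normal relations

    mu_z[i]       = 2 log mu_N[i] - 1/2 log(S_NN[i,i] + mu_N[i]^2 - mu_N[i])
    S_zz[i,i]     = log(S_NN[i,i] + mu_N[i]^2 - mu_N[i]) - log(mu_N[i]^2)
    S_zz[i,j]     = log(S_NN[i,j] + mu_N[i] mu_N[j]) - log(mu_N[i] mu_N[j])
    S_zy[i,j]     = S_Ny[i,j] / mu_N[i]

and (iv) assembles the Hankel-style future-past cross-covariance H_w and the
zero-lag covariance Lambda0 consumed by the identification step.

The stacking convention: the future window of an anchor t covers
t .. t+h-1 and the past window covers t-1 .. t-h; valid anchors are
t in [h, T-h] (0-based) with h = max(h_z, h_y), one common anchor set for
all moments so that cross-covariances are over paired samples.  Sample
covariances use the 1/(n-1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .params import symmetrize
from .simulate import MultimodalData

__all__ = [
    "EmpiricalMoments",
    "LagMoments",
    "TransformedMoments",
    "Standardizer",
    "interpolate_continuous",
    "compute_empirical_moments",
    "compute_lag_moments",
    "transform_lag_moments",
    "transform_moments",
    "assemble_hankel",
    "assemble_hankel_from_lags",
    "standardize_continuous",
    "SilentChannelError",
    "MomentTransformError",
]

#: relative floor for the log arguments in the moment transformation
CLIP_EPS = 1e-6


class SilentChannelError(ValueError):
    pass


class MomentTransformError(ValueError):
    pass


@dataclass
class EmpiricalMoments:
    """Directly computable moments of the stacked future-past vectors."""

    Sigma_yy: np.ndarray  # (2 h_y n_y)^2
    mu_y: np.ndarray
    Sigma_NN: np.ndarray  # (2 h_z n_z)^2
    mu_N: np.ndarray
    Sigma_Ny: np.ndarray  # (2 h_z n_z) x (2 h_y n_y)
    h_z: int
    h_y: int
    n_z: int
    n_y: int
    n_samples: int


@dataclass
class TransformedMoments:
    """Moments of the latent log rate obtained by moment transformation."""

    mu_z: np.ndarray  # stacked mean of z^fp, length 2 h_z n_z
    Sigma_zz: np.ndarray
    Sigma_zy: np.ndarray
    H_w: np.ndarray  # (h_z n_z + h_y n_y) square future-past cross-covariance
    Lambda0: np.ndarray  # (n_z + n_y) square zero-lag covariance of (z; y)
    h_z: int
    h_y: int
    n_z: int
    n_y: int
    clip_fraction: float = 0.0
    #: stride of the field offsets in the Hankel layout (1 = single-rate)
    M: int = 1


# ---------------------------------------------------------------------------
# interpolation of the slow continuous modality


def _interp_taps(M: int, half_len: int, beta: float) -> np.ndarray:
    t = np.arange(-half_len * M, half_len * M + 1)
    taps = np.sinc(t / M) * np.kaiser(2 * half_len * M + 1, beta)
    # normalize each polyphase component: exact DC gain and exact passthrough
    # of the observed samples (phase 0 reduces to a unit impulse)
    for r in range(M):
        phase = taps[(t % M) == r]
        taps[(t % M) == r] = phase / phase.sum()
    return taps


def interpolate_continuous(
    y_sparse: np.ndarray,
    M: int,
    half_len: int = 4,
    kaiser_beta: float = 5.0,
) -> np.ndarray:
    """Fill the period-M missing bins of a continuous series by FIR interpolation.

    ``y_sparse`` is (T, n_y) with the observed samples on the period-M grid
    (first bin observed) and anything elsewhere ignored.  A symmetric
    Kaiser-windowed lowpass interpolator with cutoff pi/M and ``half_len``
    original-sample half-length is applied zero-phase, with edge padding by
    replication.  ``M = 1`` returns the input unchanged.
    """
    y_sparse = np.asarray(y_sparse, dtype=float)
    if y_sparse.ndim == 1:
        return interpolate_continuous(y_sparse[:, None], M, half_len, kaiser_beta)[:, 0]
    T = y_sparse.shape[0]
    if M == 1:
        return y_sparse.copy()
    y_obs = y_sparse[::M]
    if not np.all(np.isfinite(y_obs)):
        raise ValueError("observed (on-grid) samples contain non-finite values")
    if y_obs.shape[0] < 2 * half_len + 1:
        raise ValueError(
            f"only {y_obs.shape[0]} observed samples but the interpolation filter "
            f"spans {2 * half_len + 1}; use a shorter filter (half_len) or fall "
            "back to linear interpolation"
        )
    taps = _interp_taps(M, half_len, kaiser_beta)
    padded = np.pad(y_obs, ((half_len, half_len), (0, 0)), mode="edge")
    up = np.zeros(((padded.shape[0] - 1) * M + 1, padded.shape[1]))
    up[::M] = padded
    conv = signal.fftconvolve(up, taps[:, None], mode="full", axes=0)
    out = conv[2 * half_len * M : 2 * half_len * M + T]
    # observed bins pass through the unit-impulse phase; enforce exactly
    out[:: M] = y_obs
    return out


# ---------------------------------------------------------------------------
# empirical moments of stacked future-past vectors


def _windowed_grams(C: np.ndarray, h: int, n: int) -> dict[int, list[np.ndarray]]:
    """Windowed lag Gram matrices.

    For lag k >= 0 and window start j, ``G[k][j] = sum_{s=j}^{j+n-1}
    C[s]' C[s+k]`` (a d x d matrix).  The base window is one matmul; shifted
    windows follow by rank-1 updates, so the cost is O(h T d^2) and the
    memory O(h^2 d^2) instead of materializing the (T, 2 h d) stacked design.
    """
    grams: dict[int, list[np.ndarray]] = {}
    for k in range(2 * h):
        n_starts = 2 * h - k  # starts j = 0 .. 2h-1-k
        g = C[:n].T @ C[k : k + n]
        out = [g]
        for j in range(1, n_starts):
            g = g - np.outer(C[j - 1], C[j - 1 + k]) + np.outer(C[j - 1 + n], C[j - 1 + n + k])
            out.append(g)
        grams[k] = out
    return grams


def _block(grams, h: int, a: int, b: int) -> np.ndarray:
    """Gram block between offsets a and b: sum_t C[t+a]' C[t+b] over anchors."""
    k = b - a
    if k >= 0:
        return grams[k][h + a]
    return grams[-k][h + b].T


def compute_empirical_moments(
    data: MultimodalData, h_z: int = 10, h_y: int = 10
) -> EmpiricalMoments:
    """Sample moments of the stacked future-past count and continuous vectors.

    ``data.y`` must already be full rate (interpolated when M > 1).  All
    moments share one anchor set t in [h, T-h] (0-based, h = max(h_z, h_y)),
    so the count/continuous cross-covariance is over paired windows.
    """
    T, n_z, n_y = data.T, data.n_z, data.n_y
    h = max(h_z if n_z else 0, h_y if n_y else 0)
    if h < 1:
        raise ValueError("at least one modality with a positive horizon is required")
    if T < 2 * h + 2:
        raise ValueError(f"need T >= {2 * h + 2} samples for horizon {h}, got {T}")
    y = np.asarray(data.y, dtype=float)
    if n_y and not np.all(np.isfinite(y)):
        raise ValueError(
            "continuous series contains missing values; interpolate to full "
            "rate before computing moments"
        )
    C = np.concatenate([np.asarray(data.N, dtype=float), y], axis=1)
    d = C.shape[1]
    n = T - 2 * h + 1  # number of anchors

    grams = _windowed_grams(C, h, n)
    # windowed means per offset
    mus = {a: C[h + a : h + a + n].mean(axis=0) for a in range(-h, h)}

    # offset lists follow the future-past stacking order
    off_z = list(range(0, h_z)) + [-(j + 1) for j in range(h_z)] if n_z else []
    off_y = list(range(0, h_y)) + [-(j + 1) for j in range(h_y)] if n_y else []
    sl_z, sl_y = slice(0, n_z), slice(n_z, d)

    def cov(offs_r, sl_r, offs_c, sl_c):
        nr = len(offs_r) * (sl_r.stop - sl_r.start)
        nc = len(offs_c) * (sl_c.stop - sl_c.start)
        out = np.empty((nr, nc))
        br = sl_r.stop - sl_r.start
        bc = sl_c.stop - sl_c.start
        for i, a in enumerate(offs_r):
            for j, b in enumerate(offs_c):
                g = _block(grams, h, a, b)[sl_r, sl_c]
                out[i * br : (i + 1) * br, j * bc : (j + 1) * bc] = (
                    g - n * np.outer(mus[a][sl_r], mus[b][sl_c])
                ) / (n - 1)
        return out

    mu_N = np.concatenate([mus[a][sl_z] for a in off_z]) if n_z else np.empty(0)
    mu_y = np.concatenate([mus[a][sl_y] for a in off_y]) if n_y else np.empty(0)
    Sigma_NN = cov(off_z, sl_z, off_z, sl_z) if n_z else np.empty((0, 0))
    Sigma_yy = cov(off_y, sl_y, off_y, sl_y) if n_y else np.empty((0, 0))
    Sigma_Ny = (
        cov(off_z, sl_z, off_y, sl_y) if (n_z and n_y) else np.empty((len(mu_N), len(mu_y)))
    )

    if n_z and np.any(mu_N <= 0):
        silent = sorted({int(i) % n_z for i in np.flatnonzero(mu_N <= 0)})
        raise SilentChannelError(
            f"spike channels {silent} have zero mean count in the stacked "
            "windows; drop them before fitting"
        )
    return EmpiricalMoments(
        Sigma_yy=symmetrize(Sigma_yy),
        mu_y=mu_y,
        Sigma_NN=symmetrize(Sigma_NN),
        mu_N=mu_N,
        Sigma_Ny=Sigma_Ny,
        h_z=h_z if n_z else 0,
        h_y=h_y if n_y else 0,
        n_z=n_z,
        n_y=n_y,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# lag-based stationary moment estimation (default pipeline path)


@dataclass
class LagMoments:
    """Stationary lag covariances estimated directly from multirate data.

    All estimators are unbiased without interpolating the slow modality:
    spike-spike lags use every bin, spike-field lags use only the bins where
    the field is observed (one endpoint suffices), and field-field lags are
    estimated at multiples of M on the observed period-M grid (both
    endpoints).  The multirate Hankel is then laid out with field offsets at
    stride M, so every cell is a directly estimated lag covariance.  This
    keeps the Hankel free of the noise-coloring and aliasing bias that
    covariances of an interpolated series suffer (interpolation spreads the
    white observation noise across neighboring bins and folds
    above-Nyquist signal power into the band, both of which subspace
    identification would mistake for extra dynamics).
    """

    mu_N: np.ndarray  # (n_z,)
    mu_y: np.ndarray  # (n_y,)
    Lam_NN: dict[int, np.ndarray] = field(default_factory=dict)  # k >= 0
    Lam_Ny: dict[int, np.ndarray] = field(default_factory=dict)  # any sign of k
    Lam_yy: dict[int, np.ndarray] = field(default_factory=dict)  # k >= 0, all lags
    h_z: int = 0
    h_y: int = 0
    M: int = 1
    n_samples: int = 0

    @property
    def n_z(self) -> int:
        return self.mu_N.shape[0]

    @property
    def n_y(self) -> int:
        return self.mu_y.shape[0]


def _lag_cov(a: np.ndarray, b: np.ndarray, mu_a, mu_b) -> np.ndarray:
    n = a.shape[0]
    return (a - mu_a).T @ (b - mu_b) / (n - 1)


def compute_lag_moments(data: MultimodalData, h_z: int = 10, h_y: int = 10) -> LagMoments:
    """Estimate all lag covariances the multirate Hankel assembly needs.

    Required lags: spike-spike ``k = 0 .. 2 h_z - 1``; spike-field ``k`` from
    ``-((h_y - 1) M + h_z)`` to ``h_y M + h_z - 1``; field-field ``k = m M``
    for ``m = 0 .. 2 h_y - 1``.  Every estimate uses only actually observed
    samples of the slow modality.
    """
    T, n_z, n_y = data.T, data.n_z, data.n_y
    h = max(h_z if n_z else 0, h_y if n_y else 0)
    if h < 1:
        raise ValueError("at least one modality with a positive horizon is required")
    M = max(1, int(data.M)) if n_y else 1
    if T < 2 * h * M + 2:
        raise ValueError(f"need T >= {2 * h * M + 2} samples for horizon {h} at M={M}")
    N = np.asarray(data.N, dtype=float)
    y = np.asarray(data.y, dtype=float)
    mask = np.asarray(data.mask, dtype=bool)
    grid = np.flatnonzero(mask)

    lm = LagMoments(
        mu_N=N.mean(axis=0) if n_z else np.empty(0),
        mu_y=y[grid].mean(axis=0) if n_y else np.empty(0),
        h_z=h_z if n_z else 0,
        h_y=h_y if n_y else 0,
        M=M,
        n_samples=T,
    )
    if n_z and np.any(lm.mu_N <= 0):
        silent = np.flatnonzero(lm.mu_N <= 0).tolist()
        raise SilentChannelError(
            f"spike channels {silent} have zero mean count; drop them before fitting"
        )

    if n_z:
        for k in range(0, 2 * h_z):
            lm.Lam_NN[k] = _lag_cov(N[k:], N[: T - k], lm.mu_N, lm.mu_N)
    if n_z and n_y:
        for k in range(-((h_y - 1) * M + h_z), h_y * M + h_z):
            # Cov[N_{t+k}, y_t] over observed-field anchors t
            t = grid[(grid + k >= 0) & (grid + k < T)]
            if t.size < 3:
                raise ValueError(f"too few observed field bins for cross lag {k}")
            lm.Lam_Ny[k] = _lag_cov(N[t + k], y[t], lm.mu_N, lm.mu_y)
    if n_y:
        for m in range(0, 2 * h_y):
            k = m * M
            t = grid[grid + k < T]
            if t.size < 3:
                raise ValueError(f"too few observed field-bin pairs for lag {k}")
            # both endpoints on the observed grid: no interpolation enters
            lm.Lam_yy[k] = _lag_cov(y[t + k], y[t], lm.mu_y, lm.mu_y)
    return lm


def transform_lag_moments(
    lm: LagMoments, clip_eps: float = CLIP_EPS
) -> tuple[np.ndarray, dict, dict, float]:
    """Lag-wise count-to-log-rate moment transformation.

    At nonzero lags the Poisson noise is independent across bins, so every
    entry uses the cross-moment relation; the Poisson mean correction applies
    only on the zero-lag diagonal.
    """
    mu = lm.mu_N
    if mu.size == 0:
        return np.empty(0), {}, {k: v for k, v in lm.Lam_Ny.items()}, 0.0
    mumu = np.outer(mu, mu)
    floor = clip_eps * mumu
    n_clip = 0
    n_tot = 0

    def _log_ratio(arg):
        nonlocal n_clip, n_tot
        n_tot += arg.size
        n_clip += int(np.count_nonzero(arg < floor))
        a = np.maximum(arg, floor)
        if np.any(~np.isfinite(a)) or np.any(a <= 0):
            raise MomentTransformError("non-positive log argument after clipping")
        return np.log(a) - np.log(mumu)

    Lam_zz: dict[int, np.ndarray] = {}
    arg0 = lm.Lam_NN[0] + mumu
    arg0[np.diag_indices_from(arg0)] -= mu
    Lam_zz[0] = symmetrize(_log_ratio(arg0))
    mu_z = 2.0 * np.log(mu) - 0.5 * np.log(np.maximum(np.diag(arg0), floor.diagonal()))
    for k, lam in lm.Lam_NN.items():
        if k == 0:
            continue
        Lam_zz[k] = _log_ratio(lam + mumu)
    Lam_zy = {k: v / mu[:, None] for k, v in lm.Lam_Ny.items()}
    clip_fraction = n_clip / max(n_tot, 1)
    if clip_fraction > 0.01:
        warnings.warn(
            f"{100 * clip_fraction:.1f}% of count-moment log arguments were "
            "floored; the series is likely too short for reliable moment "
            "transformation",
            RuntimeWarning,
            stacklevel=2,
        )
    return mu_z, Lam_zz, Lam_zy, clip_fraction


def assemble_hankel_from_lags(
    lm: LagMoments, clip_eps: float = CLIP_EPS
) -> TransformedMoments:
    """Build H_w and Lambda0 by placing each lag estimate in its Hankel cells.

    Field offsets are taken at stride M (rows ``C_y A^{iM}``, columns
    ``A^{jM} A^{M-1} G_y``), so the factorization ``H_w = O_w C_w`` is exact
    while every cell is a directly observed lag covariance; at M = 1 this is
    the standard single-rate layout.
    """
    mu_z, Lam_zz, Lam_zy, clip_fraction = transform_lag_moments(lm, clip_eps)
    h_z, h_y, n_z, n_y, M = lm.h_z, lm.h_y, lm.n_z, lm.n_y, lm.M
    fz, fy = h_z * n_z, h_y * n_y
    H = np.zeros((fz + fy, fz + fy))
    for i in range(h_z):
        for j in range(h_z):
            H[i * n_z : (i + 1) * n_z, j * n_z : (j + 1) * n_z] = Lam_zz[i + j + 1]
    for i in range(h_z):
        for j in range(h_y):
            # Cov[z_{t+i}, y_{t-(j+1)M}]
            H[i * n_z : (i + 1) * n_z, fz + j * n_y : fz + (j + 1) * n_y] = Lam_zy[
                i + (j + 1) * M
            ]
    for i in range(h_y):
        for j in range(h_z):
            # Cov[y_{t+iM}, z_{t-1-j}] = Cov[z_{t'-iM-j-1}, y_{t'}]'
            H[fz + i * n_y : fz + (i + 1) * n_y, j * n_z : (j + 1) * n_z] = Lam_zy[
                -(i * M + j + 1)
            ].T
    for i in range(h_y):
        for j in range(h_y):
            # Cov[y_{t+iM}, y_{t-(j+1)M}]
            H[fz + i * n_y : fz + (i + 1) * n_y, fz + j * n_y : fz + (j + 1) * n_y] = (
                lm.Lam_yy[(i + j + 1) * M]
            )

    Lam0 = np.zeros((n_z + n_y, n_z + n_y))
    if n_z:
        Lam0[:n_z, :n_z] = Lam_zz[0]
    if n_z and n_y:
        Lam0[:n_z, n_z:] = Lam_zy[0]
        Lam0[n_z:, :n_z] = Lam_zy[0].T
    if n_y:
        Lam0[n_z:, n_z:] = lm.Lam_yy[0]

    mu_z_stacked = np.tile(mu_z, 2 * h_z) if n_z else np.empty(0)
    return TransformedMoments(
        mu_z=mu_z_stacked,
        Sigma_zz=np.empty((0, 0)),
        Sigma_zy=np.empty((0, 0)),
        H_w=H,
        Lambda0=symmetrize(Lam0),
        h_z=h_z,
        h_y=h_y,
        n_z=n_z,
        n_y=n_y,
        clip_fraction=clip_fraction,
        M=M,
    )


# ---------------------------------------------------------------------------
# moment transformation


def transform_moments(
    em: EmpiricalMoments, clip_eps: float = CLIP_EPS
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Map count moments to log-rate moments (mu_z, Sigma_zz, Sigma_zy).

    Arguments of the logarithms are floored at ``clip_eps * mu_N[i] mu_N[j]``;
    a warning is emitted when more than 1% of the entries hit the floor, which
    indicates the data are too short for reliable count covariances.
    """
    mu_N = em.mu_N
    if mu_N.size == 0:
        return np.empty(0), np.empty((0, 0)), np.empty((0, em.Sigma_yy.shape[0])), 0.0
    if np.any(mu_N <= 0):
        raise MomentTransformError("mu_N must be strictly positive")
    S = em.Sigma_NN
    mumu = np.outer(mu_N, mu_N)
    arg = S + mumu
    arg[np.diag_indices_from(arg)] -= mu_N  # Poisson correction on the diagonal
    floor = clip_eps * mumu
    clipped = arg < floor
    n_clip = int(np.count_nonzero(clipped))
    if n_clip:
        arg = np.maximum(arg, floor)
    clip_fraction = n_clip / arg.size
    if clip_fraction > 0.01:
        warnings.warn(
            f"{100 * clip_fraction:.1f}% of count-moment log arguments were "
            "floored; the series is likely too short for reliable moment "
            "transformation",
            RuntimeWarning,
            stacklevel=2,
        )
    if not np.all(np.isfinite(arg)) or np.any(arg <= 0):
        i, j = np.unravel_index(int(np.argmin(arg)), arg.shape)
        raise MomentTransformError(
            f"non-positive log argument at stacked entry ({i}, {j}) after clipping"
        )
    Sigma_zz = symmetrize(np.log(arg) - np.log(mumu))
    mu_z = 2.0 * np.log(mu_N) - 0.5 * np.log(np.diag(arg))
    Sigma_zy = em.Sigma_Ny / mu_N[:, None]
    return mu_z, Sigma_zz, Sigma_zy, clip_fraction


# ---------------------------------------------------------------------------
# Hankel and zero-lag assembly


def assemble_hankel(
    em: EmpiricalMoments,
    transformed: tuple[np.ndarray, np.ndarray, np.ndarray, float] | None = None,
) -> TransformedMoments:
    """Assemble H_w, Lambda0 and mu_z from (transformed) stacked moments.

    The future-past cross-covariance H_w is read off the stacked covariances:
    its z-z block is Cov[z^f, z^p] (the future-rows x past-columns block of
    Sigma_zz), the z-y block comes from Sigma_zy, the y-z block from the
    transpose relation on Sigma_zy, and the y-y block from Sigma_yy.  Lambda0
    is taken from the anchor-time (first future) positions.
    """
    if transformed is None:
        transformed = transform_moments(em)
    mu_z, Sigma_zz, Sigma_zy, clip_fraction = transformed
    h_z, h_y, n_z, n_y = em.h_z, em.h_y, em.n_z, em.n_y
    if n_z and (Sigma_zz.shape[0] != 2 * h_z * n_z):
        raise ValueError("transformed moments have inconsistent horizons")
    fz, fy = h_z * n_z, h_y * n_y

    H_zz = Sigma_zz[:fz, fz:]
    H_zy = Sigma_zy[:fz, fy:]
    H_yz = Sigma_zy[fz:, :fy].T
    H_yy = em.Sigma_yy[:fy, fy:]
    H_w = np.block([[H_zz, H_zy], [H_yz, H_yy]]) if (n_z and n_y) else (H_zz if n_z else H_yy)

    Lam = np.empty((n_z + n_y, n_z + n_y))
    Lam[:n_z, :n_z] = Sigma_zz[:n_z, :n_z]
    Lam[:n_z, n_z:] = Sigma_zy[:n_z, :n_y]
    Lam[n_z:, :n_z] = Sigma_zy[:n_z, :n_y].T
    Lam[n_z:, n_z:] = em.Sigma_yy[:n_y, :n_y]

    return TransformedMoments(
        mu_z=mu_z,
        Sigma_zz=Sigma_zz,
        Sigma_zy=Sigma_zy,
        H_w=H_w,
        Lambda0=symmetrize(Lam),
        h_z=h_z,
        h_y=h_y,
        n_z=n_z,
        n_y=n_y,
        clip_fraction=clip_fraction,
    )


# ---------------------------------------------------------------------------
# continuous-feature standardization


@dataclass
class Standardizer:
    mean: np.ndarray
    std: np.ndarray

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.std

    def inverse_transform(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.std + self.mean


def standardize_continuous(
    y_train: np.ndarray, y_apply: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, Standardizer]:
    """z-score each continuous channel by its training mean and SD.

    Missing bins (NaN) are ignored when computing the statistics and pass
    through the transform as NaN.
    """
    y_train = np.asarray(y_train, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(y_train, axis=0)
        std = np.nanstd(y_train, axis=0, ddof=1)
    if np.any(~np.isfinite(std)) or np.any(std <= 0):
        bad = np.flatnonzero(~(std > 0)).tolist()
        raise ValueError(f"continuous channels {bad} have zero or undefined variance")
    stats = Standardizer(mean=mean, std=std)
    out_train = stats.transform(y_train)
    out_apply = stats.transform(y_apply) if y_apply is not None else None
    return out_train, out_apply, stats
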