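"""Random model generation and multimodal data simulation.

Ground-truth models are drawn with a controlled dynamical-mode structure:
each mode is a real eigenvalue or a complex-conjugate pair of the state
transition matrix ``A`` (built block-diagonal, which is fully general up to a
similarity transform) and is either *shared* between the spike and field
modalities or *distinct* to one of them.  The presence of mode ``i`` in a
modality is quantified by its contribution

    cntrb_z[i] = trace(Cbar_z[i] Sigmabar_x[i] Cbar_z[i]')

(and analogously for the field modality), i.e. the total stationary variance
of that modality's latent readout generated by the mode.  Distinct modes have
exactly zero contribution in the excluded modality (their loading columns are
zeroed); contributing modes are scaled to equal normalized contributions.

Firing-rate calibration: with bin width ``dt`` seconds, the log-rate intercept
is ``d_z[i] = log(f_bias[i] * dt)`` and the rows of ``C_z`` are scaled so that
the +2-sigma per-bin rate equals ``f_max[i] * dt``.  Field channels are given
diagonal observation noise matching per-channel SNR
``diag(C_y Sigma_x C_y') / diag(R_y)`` drawn from the configured range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    MultiscaleParams,
    pset_from_nset,
    stationary_state_covariance,
    symmetrize,
)

__all__ = [
    "SimConfig",
    "ModeInfo",
    "MultimodalData",
    "generate_random_model",
    "simulate_data",
    "mode_contributions",
    "RateExplosionError",
    "DEFAULT_MODE_SPEC",
]

#: default mode layout: two shared, one spike-distinct, one field-distinct,
#: all complex (oscillatory) -> n_x = 8
DEFAULT_MODE_SPEC: tuple[tuple[str, bool], ...] = (
    ("shared", True),
    ("shared", True),
    ("spike-only", True),
    ("field-only", True),
)

_MODE_TYPES = ("shared", "spike-only", "field-only")

#: log-rate bound above which simulation aborts (rate exp(50) per bin is
#: unphysical and signals unstable dynamics or miscalibrated loadings)
_Z_MAX = 50.0


class RateExplosionError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Study conditions for random-model generation.

    Defaults reproduce the simulation protocol used throughout: eigenvalue
    magnitudes in [0.950, 0.999] and angles in [0, 0.0316] rad, spike bias
    rates 5-10 Hz and maximum (+2 sigma) rates 40-50 Hz, per-channel field
    SNR in [0.8, 1.2], 10 ms bins and field features available every M = 5
    bins.
    """

    n_z: int = 10
    n_y: int = 40
    mode_spec: tuple[tuple[str, bool], ...] = DEFAULT_MODE_SPEC
    r_range: tuple[float, float] = (0.950, 0.999)
    theta_range: tuple[float, float] = (0.0, 0.0316)
    max_rate_range_hz: tuple[float, float] = (40.0, 50.0)
    bias_rate_range_hz: tuple[float, float] = (5.0, 10.0)
    snr_range: tuple[float, float] = (0.8, 1.2)
    bin_width_s: float = 0.010
    M: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_range[0] <= self.r_range[1] < 1.0):
            raise ValueError("r_range must lie inside (0, 1)")
        if not (0.0 <= self.theta_range[0] <= self.theta_range[1] < np.pi):
            raise ValueError("theta_range must lie inside [0, pi)")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.bias_rate_range_hz[1] >= self.max_rate_range_hz[0]:
            raise ValueError("bias rate range must lie below the max rate range")
        for mtype, _ in self.mode_spec:
            if mtype not in _MODE_TYPES:
                raise ValueError(f"unknown mode type {mtype!r}")

    @property
    def n_x(self) -> int:
        return sum(2 if c else 1 for _, c in self.mode_spec)


@dataclass
class ModeInfo:
    """Per-mode bookkeeping for a block-diagonal ground-truth model."""

    eigenvalues: list[np.ndarray]  # per mode: (1,) real or (2,) conjugate pair
    blocks: list[np.ndarray]  # per mode: state indices (views into 1..n_x, 0-based)
    types: list[str]
    cntrb_z: np.ndarray = field(default_factory=lambda: np.empty(0))
    cntrb_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    ncntrb_z: np.ndarray = field(default_factory=lambda: np.empty(0))
    ncntrb_y: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_modes(self) -> int:
        return len(self.types)

    def eigenvalues_of(self, mode_type: str) -> np.ndarray:
        """All eigenvalues of modes of the given type, concatenated."""
        vals = [ev for ev, t in zip(self.eigenvalues, self.types) if t == mode_type]
        return np.concatenate(vals) if vals else np.empty(0, dtype=complex)


@dataclass
class MultimodalData:
    """Aligned spike-count and continuous series with period-M missingness.

    ``y`` holds NaN at unobserved bins; ``mask`` is the authoritative
    availability indicator (True where y is observed).  The latent record
    (``x``, ``z``) is retained when simulated, for testing only.
    """

    N: np.ndarray  # (T, n_z) nonnegative int counts
    y: np.ndarray  # (T, n_y) float, NaN at missing bins
    mask: np.ndarray  # (T,) bool, True where y observed
    M: int = 1
    bin_width_s: float = 0.010
    x: np.ndarray | None = None
    z: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.N.shape[0]

    @property
    def n_z(self) -> int:
        return self.N.shape[1]

    @property
    def n_y(self) -> int:
        return self.y.shape[1]


def _draw_modes(cfg: SimConfig, rng: np.random.Generator):
    """Draw eigenvalues and build block-diagonal A."""
    blocks, eigs, idx = [], [], 0
    A = np.zeros((cfg.n_x, cfg.n_x))
    index_blocks = []
    for _, is_complex in cfg.mode_spec:
        r = rng.uniform(*cfg.r_range)
        if is_complex:
            th = rng.uniform(*cfg.theta_range)
            A[idx : idx + 2, idx : idx + 2] = [
                [r * np.cos(th), -r * np.sin(th)],
                [r * np.sin(th), r * np.cos(th)],
            ]
            eigs.append(np.array([r * np.exp(1j * th), r * np.exp(-1j * th)]))
            index_blocks.append(np.arange(idx, idx + 2))
            idx += 2
        else:
            A[idx, idx] = r
            eigs.append(np.array([r + 0j]))
            index_blocks.append(np.arange(idx, idx + 1))
            idx += 1
    return A, eigs, index_blocks


def generate_random_model(cfg: SimConfig) -> tuple[MultiscaleParams, ModeInfo]:
    """Draw a random ground-truth multiscale model with the configured modes."""
    rng = np.random.default_rng(cfg.seed)
    n_x, n_z, n_y = cfg.n_x, cfg.n_z, cfg.n_y
    if n_z < 1 and any(t == "spike-only" for t, _ in cfg.mode_spec):
        raise ValueError("spike-only modes require n_z >= 1")
    if n_y < 1 and any(t == "field-only" for t, _ in cfg.mode_spec):
        raise ValueError("field-only modes require n_y >= 1")

    A, eigs, blocks = _draw_modes(cfg, rng)
    Q = np.diag(np.abs(rng.standard_normal(n_x)))
    Sigma_x = stationary_state_covariance(A, Q)

    C_z = rng.uniform(-1.0, 1.0, size=(n_z, n_x))
    C_y = rng.uniform(-1.0, 1.0, size=(n_y, n_x))
    types = [t for t, _ in cfg.mode_spec]

    # distinct modes: zero loading columns in the excluded modality
    for bl, t in zip(blocks, types):
        if t == "field-only":
            C_z[:, bl] = 0.0
        elif t == "spike-only":
            C_y[:, bl] = 0.0

    # equalize contributions across the modes present in each modality
    def _equalize(C: np.ndarray, active: list[int]) -> None:
        if C.shape[0] == 0 or not active:
            return
        cn = np.array(
            [np.trace(C[:, blocks[i]] @ Sigma_x[np.ix_(blocks[i], blocks[i])] @ C[:, blocks[i]].T) for i in active]
        )
        if np.any(cn <= 0):
            raise ValueError("infeasible contribution targets: a contributing mode has zero loading")
        target = cn.mean()
        for i, c in zip(active, cn):
            C[:, blocks[i]] *= np.sqrt(target / c)

    _equalize(C_z, [i for i, t in enumerate(types) if t in ("shared", "spike-only")])
    _equalize(C_y, [i for i, t in enumerate(types) if t in ("shared", "field-only")])

    # firing-rate calibration: d_z from the bias rate, row scale of C_z from
    # the +2 sigma max rate (rates in Hz, converted to per-bin via bin width)
    dt = cfg.bin_width_s
    f_bias = rng.uniform(*cfg.bias_rate_range_hz, size=n_z)
    f_max = rng.uniform(*cfg.max_rate_range_hz, size=n_z)
    d_z = np.log(f_bias * dt)
    sigma_target = (np.log(f_max * dt) - d_z) / 2.0
    var_z = np.einsum("ij,jk,ik->i", C_z, Sigma_x, C_z)
    if np.any(var_z <= 0):
        raise ValueError("infeasible configuration: a spike channel has zero log-rate variance")
    C_z *= (sigma_target / np.sqrt(var_z))[:, None]

    # field noise from per-channel SNR
    var_y = np.einsum("ij,jk,ik->i", C_y, Sigma_x, C_y)
    snr = rng.uniform(*cfg.snr_range, size=n_y)
    if n_y and np.any(var_y <= 0):
        raise ValueError("infeasible configuration: a field channel has zero signal variance")
    R_y = np.diag(var_y / snr) if n_y else np.empty((0, 0))

    p = MultiscaleParams(A=A, C_y=C_y, C_z=C_z, Q=Q, R_y=R_y, d_z=d_z, bin_width_s=dt)
    info = ModeInfo(eigenvalues=eigs, blocks=blocks, types=types)
    return p, mode_contributions(p, info)


def mode_contributions(p: MultiscaleParams, info: ModeInfo) -> ModeInfo:
    """Fill per-mode contributions ``cntrb`` and normalized ``nCntrb``.

    Requires the block-diagonal (canonical) mode structure recorded in
    ``info``; convert arbitrary models to canonical form first.
    """
    all_idx = np.concatenate(info.blocks) if info.blocks else np.empty(0, int)
    if sorted(all_idx.tolist()) != list(range(p.n_x)):
        raise ValueError(
            "mode blocks do not partition the state indices; convert the model "
            "to block-diagonal canonical form before computing contributions"
        )
    Sigma_x = pset_from_nset(p).Sigma_x
    cz, cy = [], []
    for bl in info.blocks:
        Sb = Sigma_x[np.ix_(bl, bl)]
        cz.append(float(np.trace(p.C_z[:, bl] @ Sb @ p.C_z[:, bl].T)) if p.n_z else 0.0)
        cy.append(float(np.trace(p.C_y[:, bl] @ Sb @ p.C_y[:, bl].T)) if p.n_y else 0.0)
    info.cntrb_z = np.array(cz)
    info.cntrb_y = np.array(cy)
    info.ncntrb_z = info.cntrb_z / info.cntrb_z.sum() if info.cntrb_z.sum() > 0 else info.cntrb_z
    info.ncntrb_y = info.cntrb_y / info.cntrb_y.sum() if info.cntrb_y.sum() > 0 else info.cntrb_y
    return info


def simulate_data(
    p: MultiscaleParams,
    T: int,
    M: int = 1,
    seed: int | np.random.Generator = 0,
    keep_latents: bool = True,
) -> MultimodalData:
    """Simulate multimodal spike/field data from a model.

    Starts from ``x[0] = 0`` (pre-sample state), recurses the state equation,
    generates the continuous features at every bin and then discards the bins
    off the period-M grid (first bin observed), and draws counts
    ``N[t] ~ Poisson(exp(z[t]))`` elementwise.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_x, n_y, n_z = p.n_x, p.n_y, p.n_z

    # state recursion; chol(Q) once, degenerate Q handled via eigendecomposition
    Qs = symmetrize(p.Q)
    w, V = np.linalg.eigh(Qs)
    Lq = V * np.sqrt(np.clip(w, 0.0, None))
    x = np.empty((T, n_x))
    q = rng.standard_normal((T, n_x)) @ Lq.T
    xt = np.zeros(n_x)
    A = p.A
    for t in range(T):
        xt = A @ xt + q[t]
        x[t] = xt

    z = x @ p.C_z.T + p.d_z if n_z else np.zeros((T, 0))
    if n_z and np.any(z > _Z_MAX):
        ch = int(np.argmax(np.max(z, axis=0)))
        raise RateExplosionError(
            f"log rate exceeded {_Z_MAX} on spike channel {ch}; the model is "
            "unstable or the log-rate loading is miscalibrated"
        )
    N = rng.poisson(np.exp(z)).astype(np.int64) if n_z else np.zeros((T, 0), np.int64)

    if n_y:
        w_y, V_y = np.linalg.eigh(symmetrize(p.R_y))
        Lr = V_y * np.sqrt(np.clip(w_y, 0.0, None))
        y = x @ p.C_y.T + rng.standard_normal((T, n_y)) @ Lr.T
    else:
        y = np.zeros((T, 0))
    mask = np.zeros(T, dtype=bool)
    mask[::M] = True
    y = y.copy()
    y[~mask] = np.nan

    return MultimodalData(
        N=N,
        y=y,
        mask=mask,
        M=M,
        bin_width_s=p.bin_width_s,
        x=x if keep_latents else None,
        z=z if keep_latents else None,
    )
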