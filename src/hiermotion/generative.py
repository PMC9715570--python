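"""Simulating structured motion from a tree of Ornstein-Uhlenbeck sources.

Each motion source follows ``ds_m = -s_m / tau_s dt + lambda_m dW_m``
independently per spatial dimension, giving the stationary distribution
``N(0, tau_s lambda_m^2 / 2)`` — a slow-velocity prior.  Observed velocities
are frame-sampled noisy sums of their ancestral sources,
``v_t ~ N(C s_t, sigma_obs^2 / dt * I)``; the ``1/dt`` scaling keeps the
information content of the stream independent of the frame rate.

Sources are integrated with the exact discrete OU transition (AR(1) with
factor ``exp(-dt/tau_s)`` and matched innovation variance), so stationary
statistics are unbiased at any frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import MotionTree


@dataclass
class GenerativeParams:
    """Parameters of the generative motion model.

    lam : per-component motion strengths ``lambda_m >= 0`` (speed/sqrt(time))
    tau_s : source time constant (s)
    sigma_obs : observation noise scale (speed * sqrt(time)); scalar or (K,)
    dt : frame interval (s)
    """

    lam: np.ndarray
    tau_s: float = 0.300
    sigma_obs: float | np.ndarray = 0.05
    dt: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if np.any(self.lam < 0):
            raise ValueError("lambda must be >= 0")
        if self.tau_s <= 0 or self.dt <= 0:
            raise ValueError("tau_s and dt must be > 0")
        if np.any(np.asarray(self.sigma_obs) < 0):
            raise ValueError("sigma_obs must be >= 0")


@dataclass
class ObservationStream:
    """Frame-sampled observed velocities.

    v : velocities, shape ``(..., T, K, D)`` (leading batch axes optional)
    times : frame timestamps, shape ``(T,)``
    obs_var : continuous-time observation noise variance ``sigma_k^2`` per
        input — the quantity the prediction error divides by.  Shape ``(K,)``
        or ``(T, K)`` for time-varying contrast.  The per-frame sampling
        variance of an ordinary input is ``obs_var / dt``.
    dt : frame interval (s)
    """

    v: np.ndarray
    times: np.ndarray
    obs_var: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.obs_var = np.asarray(self.obs_var, dtype=float)
        if self.v.ndim < 3:
            raise ValueError("v must have shape (..., T, K, D)")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocities must be finite")
        if np.any(self.obs_var <= 0):
            raise ValueError("obs_var must be > 0")
        dts = np.diff(self.times)
        if dts.size and not np.allclose(dts, self.dt, rtol=1e-6, atol=1e-9):
            raise ValueError("frames must be uniformly spaced at dt")

    @property
    def n_frames(self) -> int:
        return self.v.shape[-3]

    @property
    def n_inputs(self) -> int:
        return self.v.shape[-2]

    @property
    def n_dims(self) -> int:
        return self.v.shape[-1]

    @property
    def batch_shape(self) -> tuple[int, ...]:
        return self.v.shape[:-3]

    def obs_var_at(self, i: int) -> np.ndarray:
        """Per-input noise variance at frame ``i`` (shape ``(K,)``)."""
        if self.obs_var.ndim == 2:
            return self.obs_var[i]
        return self.obs_var


def simulate_sources(
    tree: MotionTree,
    params: GenerativeParams,
    T: float,
    seed: int | np.random.Generator,
    batch_shape: tuple[int, ...] = (),
    s0: np.ndarray | None = None,
) -> np.ndarray:
    """Sample latent source trajectories at frame resolution.

    Returns ``s`` with shape ``(*batch_shape, n_frames, S)`` where ``S`` is
    the number of source columns (translational components contribute one
    column per spatial dimension).  Sources with ``lambda = 0`` stay at (or
    decay deterministically from) their initial value.
    """
    rng = np.random.default_rng(seed)
    if params.lam.size != tree.n_components:
        raise ValueError("lam must have one entry per component")
    lam_col = tree.expand_lambda(params.lam)            # (S,)
    n_frames = int(round(T / params.dt))
    a = np.exp(-params.dt / params.tau_s)
    stat_var = params.tau_s / 2.0 * lam_col**2
    innov_sd = np.sqrt(stat_var * (1.0 - a**2))
    S = lam_col.size
    s = np.empty(batch_shape + (n_frames, S))
    if s0 is None:
        cur = np.sqrt(stat_var) * rng.standard_normal(batch_shape + (S,))
    else:
        cur = np.broadcast_to(np.asarray(s0, float), batch_shape + (S,)).copy()
    for i in range(n_frames):
        s[..., i, :] = cur
        cur = a * cur + innov_sd * rng.standard_normal(batch_shape + (S,))
    return s


def emit_observations(
    s: np.ndarray,
    tree: MotionTree,
    params: GenerativeParams,
    seed: int | np.random.Generator,
) -> ObservationStream:
    """Turn source trajectories into a noisy observation stream.

    One independent noise draw per frame, held constant within
    ``[t, t + dt)``; noise variance ``sigma_obs^2 / dt`` per input.
    """
    rng = np.random.default_rng(seed)
    if s.shape[-1] != tree.n_cols:
        raise ValueError("source array does not match tree columns")
    clean = tree.compose(s)                              # (..., T, K, D)
    sigma = np.broadcast_to(
        np.atleast_1d(np.asarray(params.sigma_obs, float)), (tree.n_inputs,)
    )
    frame_sd = sigma / np.sqrt(params.dt)
    v = clean + frame_sd[:, None] * rng.standard_normal(clean.shape)
    times = np.arange(s.shape[-2]) * params.dt
    obs_var = np.maximum(sigma, 1e-30) ** 2
    return ObservationStream(v=v, times=times, obs_var=obs_var, dt=params.dt)


def simulate_stream(
    tree: MotionTree,
    params: GenerativeParams,
    T: float,
    seed: int | np.random.Generator,
    batch_shape: tuple[int, ...] = (),
) -> ObservationStream:
    """Convenience: ``simulate_sources`` + ``emit_observations``."""
    rng = np.random.default_rng(seed)
    s = simulate_sources(tree, params, T, rng, batch_shape)
    return emit_observations(s, tree, params, rng)


def stationary_velocity_variance(
    tree: MotionTree, params: GenerativeParams
) -> np.ndarray:
    """Closed-form stationary variance of each observed velocity component.

    ``Var(v_kd) = sigma_obs_k^2 / dt + (tau_s / 2) sum_s C_kds^2 lambda_s^2``
    (per spatial dimension; returns shape ``(K, D)``).
    """
    lam_col = tree.expand_lambda(params.lam)
    sigma = np.broadcast_to(
        np.atleast_1d(np.asarray(params.sigma_obs, float)), (tree.n_inputs,)
    )
    source_part = params.tau_s / 2.0 * np.einsum(
        "kds,s->kd", tree.C_tensor**2, lam_col**2
    )
    return sigma[:, None] ** 2 / params.dt + source_part
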