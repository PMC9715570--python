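"""Online hierarchical inference: continuous-time EM with adiabatic filtering.

The model maintains a Gaussian posterior over the latent motion sources
(mean ``mu_t``, diagonal covariance ``Sigma_t``) and a point estimate of the
squared motion strengths ``lambda_t^2``, coupled through

    d(lambda_m^2)/dt = -lambda_m^2 / tau_lambda
                       + alpha_m * < mu^2 + f_Sigma(lambda^2) >_dims
                       + beta_m
    d(mu)/dt         = -mu / tau_s + f_Sigma(lambda^2) * C^T eps,
    eps_k            = (v_k - (C mu)_k) / sigma_k^2,

where ``f_Sigma`` is the closed-form adiabatic posterior variance (the
stationary solution of the per-source Riccati equation with off-diagonal
covariance terms dropped):

    Sigma_mm = sigma_obs^2 / (tau_s ||c_m||^2)
               * (-1 + sqrt(1 + tau_s^2 ||c_m||^2 lambda_m^2 / sigma_obs^2)).

With heterogeneous per-input noise the ratio ``||c_m||^2 / sigma_obs^2``
generalizes to ``g_m = sum_k C_km^2 / sigma_k^2`` (precision-weighted column
norm), which reduces to the expression above for uniform noise.

``<.>_dims`` averages the statistic over a component's source columns
(spatial dimensions), keeping ``lambda^2`` scale-consistent with the
per-dimension stationary source variance ``tau_s lambda^2 / 2``.

The constants ``alpha_m, beta_m`` carry the scaled-inverse-chi-squared prior
(``nu_m`` pseudo-observations of value ``kappa_m^2``):

    alpha_m = 2 / (tau_s^2 (2 + nu_m + tau_lambda / tau_s)),
    beta_m  = nu_m kappa_m^2 / (tau_lambda (2 + nu_m + tau_lambda / tau_s)).

Observations are held piecewise-constant within each frame; the state is
integrated between frames either with classic RK4 substeps (vectorized over
trial batches; the default) or with SciPy's adaptive RK45 restarted at each
frame boundary.  ``lambda^2`` is clipped at zero after every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .generative import ObservationStream
from .trees import MotionTree

__all__ = [
    "InferenceConfig",
    "InferenceState",
    "OnlineMotionModel",
    "OnlineMotionResults",
    "posterior_variance",
    "adiabatic_variance",
    "prior_constants",
    "rhs",
    "run_inference",
    "perceived_velocity",
]


@dataclass
class InferenceConfig:
    """Run configuration for the online inference model.

    tau_s, tau_lambda : time constants of source and strength dynamics (s);
        the model assumes ``tau_lambda >> tau_s`` (warns below 2x).
    dt : observation frame interval (s).
    lambda_init : initial motion strength ``lambda_m(0)`` (scalar or per
        component).
    sigma_obs : optional fallback noise scale used when a raw velocity array
        (rather than an :class:`ObservationStream`) is supplied.
    method : "rk4" (fixed substeps, batch-vectorized) or "rk45"
        (adaptive, restarted at each frame).
    fix_lambda : freeze the M-step (strengths held at their initial value);
        used for calibration checks against pure filtering.
    """

    tau_s: float = 0.300
    tau_lambda: float = 1.000
    dt: float = 1.0 / 60.0
    lambda_init: float | np.ndarray = 0.5
    sigma_obs: float | np.ndarray | None = None
    method: str = "rk4"
    n_substeps: int = 4
    rtol: float = 1e-6
    atol: float = 1e-8
    fix_lambda: bool = False
    store_stride: int = 1

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.tau_lambda <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be > 0")
        if np.any(np.asarray(self.lambda_init) < 0):
            raise ValueError("lambda_init must be >= 0")
        if self.tau_lambda < 2.0 * self.tau_s:
            warnings.warn(
                "tau_lambda < 2 tau_s: the adiabatic separation of time "
                "scales is questionable", stacklevel=2,
            )
        if self.method not in ("rk4", "rk45"):
            raise ValueError("method must be 'rk4' or 'rk45'")


@dataclass
class InferenceState:
    """Instantaneous state of the online model."""

    mu: np.ndarray          # (..., S) posterior means per source column
    lambda_sq: np.ndarray   # (..., M) squared motion strengths
    sigma_diag: np.ndarray  # (..., S) adiabatic posterior variances
    eps: np.ndarray | None = None  # (..., K, D) prediction error


def adiabatic_variance(
    lambda_sq: np.ndarray, g: np.ndarray, tau_s: float
) -> np.ndarray:
    """Adiabatic posterior variance from the precision-weighted column norm.

    ``g = sum_k C_km^2 / sigma_k^2``; solves
    ``lambda^2 - 2 Sigma / tau_s - Sigma^2 g = 0`` for ``Sigma >= 0``.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("dead component: zero precision-weighted norm")
    lam_sq = np.maximum(lambda_sq, 0.0)
    return (-1.0 + np.sqrt(1.0 + tau_s**2 * g * lam_sq)) / (tau_s * g)


def posterior_variance(
    lambda_sq: np.ndarray,
    column_norms_sq: np.ndarray,
    tau_s: float,
    sigma_obs: float,
) -> np.ndarray:
    """Closed-form posterior variance ``f_Sigma(lambda^2)`` (uniform noise).

    Monotone increasing in ``lambda^2`` with ``f_Sigma(0) = 0`` and
    large-``lambda`` asymptote ``sigma_obs lambda / ||c_m||``.
    """
    return adiabatic_variance(
        lambda_sq, np.asarray(column_norms_sq, float) / sigma_obs**2, tau_s
    )


def prior_constants(
    nu: np.ndarray,
    kappa_sq: np.ndarray,
    tau_s: float,
    tau_lambda: float,
    n_dims: int | np.ndarray = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass constants ``(alpha_m, beta_m)`` from the prior on lambda^2.

    ``n_dims`` is the number of source columns a component's strength
    governs (spatial dimensions for translational components).  Each
    dimension contributes an independent observation of ``lambda^2``, so in
    ``D`` dimensions the prior's weight relative to the data shrinks by
    ``1/D``: with the dimension-averaged statistic in the strength update,

        alpha_m = 2 / (tau_s^2 (2/D + nu_m + tau_lambda / tau_s)),
        beta_m  = nu_m kappa_m^2 / (tau_lambda (2/D + nu_m + tau_lambda/tau_s)).

    This is the bookkeeping under which ``nu = -2/D`` yields an exactly
    unbiased (uniform-prior) fixed point; for ``D = 1`` it reduces to the
    one-dimensional constants.
    """
    nu = np.asarray(nu, dtype=float)
    kappa_sq = np.asarray(kappa_sq, dtype=float)
    denom = 2.0 / np.asarray(n_dims, dtype=float) + nu + tau_lambda / tau_s
    if np.any(denom <= 0):
        raise ValueError("degenerate prior: 2/D + nu + tau_lambda/tau_s <= 0")
    alpha = 2.0 / (tau_s**2 * denom)
    beta = nu * kappa_sq / (tau_lambda * denom)
    return alpha, beta


class _Workspace:
    """Precomputed tree/noise arrays shared by all RHS evaluations."""

    def __init__(self, tree: MotionTree, config: InferenceConfig):
        self.tree = tree
        self.config = config
        K, D, S = tree.C_tensor.shape
        self.C_flat = tree.C_tensor.reshape(K * D, S)      # (KD, S)
        self.comp = tree.comp_of_col
        M = tree.n_components
        self.M, self.S, self.K, self.D = M, S, K, D
        # number of source columns per component (the <.>_dims divisor)
        self.cols_per_comp = np.bincount(self.comp, minlength=M).astype(float)
        self.alpha, self.beta = prior_constants(
            tree.prior_nu, tree.prior_kappa_sq, config.tau_s,
            config.tau_lambda, n_dims=self.cols_per_comp,
        )
        # mean-over-columns aggregation matrix: (S, M)
        self.agg = np.zeros((S, M))
        self.agg[np.arange(S), self.comp] = 1.0 / self.cols_per_comp[self.comp]
        self._noise_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def noise(self, obs_var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """``(g, inv_var_flat)``: precision-weighted column norms ``(S,)``
        and per-(input, dim) precisions flattened to ``(K*D,)``."""
        if self._noise_cache is not None and np.array_equal(
            self._noise_cache[0], obs_var
        ):
            return self._noise_cache[1], self._noise_cache[2]
        inv_var = 1.0 / obs_var                            # (K,)
        g = np.einsum("kds,k->s", self.tree.C_tensor**2, inv_var)
        inv_flat = np.repeat(inv_var, self.D)
        # Gershgorin row sums of C^T W C: bound on the coupled-mu Jacobian
        gram = self.C_flat.T @ (inv_flat[:, None] * self.C_flat)
        self._row_gram = np.abs(gram).sum(axis=1)          # (S,)
        self._noise_cache = (obs_var.copy(), g, inv_flat)
        return g, inv_flat

    def g(self, obs_var: np.ndarray) -> np.ndarray:
        return self.noise(obs_var)[0]

    def stiffness_rate(self, lam_sq: np.ndarray, obs_var: np.ndarray) -> float:
        """Upper bound on the fastest linear rate in the mu dynamics."""
        g, _ = self.noise(obs_var)
        sigma = adiabatic_variance(lam_sq[..., self.comp], g,
                                   self.config.tau_s)
        return 1.0 / self.config.tau_s + float(
            np.max(sigma * self._row_gram)
        )

    def comp_mean(self, col_stat: np.ndarray) -> np.ndarray:
        """Average a per-column statistic over each component's columns."""
        return col_stat @ self.agg


def rhs(
    lambda_sq: np.ndarray,
    mu: np.ndarray,
    v: np.ndarray,
    obs_var: np.ndarray,
    ws: _Workspace,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(d lambda^2, d mu)`` for the current frame.

    Shapes: ``lambda_sq (..., M)``, ``mu (..., S)``, ``v (..., K, D)``,
    ``obs_var (K,)``.
    """
    cfg = ws.config
    g, inv_flat = ws.noise(obs_var)
    sigma = adiabatic_variance(lambda_sq[..., ws.comp], g, cfg.tau_s)
    v_flat = v.reshape(v.shape[:-2] + (ws.K * ws.D,))
    resid = v_flat - mu @ ws.C_flat.T                       # (..., KD)
    eps = resid * inv_flat                                  # (..., KD)
    dmu = -mu / cfg.tau_s + sigma * (eps @ ws.C_flat)
    if cfg.fix_lambda:
        dlam = np.zeros_like(lambda_sq)
    else:
        stat = ws.comp_mean(mu**2 + sigma)                  # (..., M)
        dlam = -lambda_sq / cfg.tau_lambda + ws.alpha * stat + ws.beta
    return dlam, dmu


def _rk4_frame(lam_sq, mu, v, obs_var, ws, n_min):
    cfg = ws.config
    # stability-driven substep count: bound the stiffest mu rate by the
    # Gershgorin row sums of the precision-weighted Gram matrix (coupled
    # columns add up) and keep h * rate comfortably inside the RK4
    # stability region (~2.8), with margin for lambda growth within the
    # frame.
    rate = ws.stiffness_rate(lam_sq, obs_var)
    n_sub = max(n_min, int(np.ceil(rate * cfg.dt / 1.2)))
    h = ws.config.dt / n_sub
    for _ in range(n_sub):
        k1l, k1m = rhs(lam_sq, mu, v, obs_var, ws)
        k2l, k2m = rhs(lam_sq + 0.5 * h * k1l, mu + 0.5 * h * k1m,
                       v, obs_var, ws)
        k3l, k3m = rhs(lam_sq + 0.5 * h * k2l, mu + 0.5 * h * k2m,
                       v, obs_var, ws)
        k4l, k4m = rhs(lam_sq + h * k3l, mu + h * k3m, v, obs_var, ws)
        lam_sq = lam_sq + h / 6.0 * (k1l + 2 * k2l + 2 * k3l + k4l)
        mu = mu + h / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
        np.maximum(lam_sq, 0.0, out=lam_sq)
    return lam_sq, mu


def _rk45_frame(lam_sq, mu, v, obs_var, ws):
    cfg = ws.config
    shape_l, shape_m = lam_sq.shape, mu.shape
    nl = lam_sq.size

    def f(_t, y):
        dl, dm = rhs(y[:nl].reshape(shape_l), y[nl:].reshape(shape_m),
                     v, obs_var, ws)
        return np.concatenate([dl.ravel(), dm.ravel()])

    y0 = np.concatenate([lam_sq.ravel(), mu.ravel()])
    sol = solve_ivp(f, (0.0, cfg.dt), y0, method="RK45",
                    rtol=cfg.rtol, atol=cfg.atol)
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    y = sol.y[:, -1]
    lam_sq = np.maximum(y[:nl].reshape(shape_l), 0.0)
    return lam_sq, y[nl:].reshape(shape_m)


class OnlineMotionModel:
    """Online hierarchical inference model bound to an observation stream.

    Parameters
    ----------
    stream : ObservationStream
        Frame-sampled velocities (optionally batched over trials).
    tree : MotionTree
        The reservoir of motion components (the matrix ``C``).
    config : InferenceConfig, optional
        Time constants, initialization and integrator choices.

    ``fit()`` runs the coupled EM dynamics over the whole stream and returns
    an :class:`OnlineMotionResults` holding the state trajectories.
    """

    def __init__(
        self,
        stream: ObservationStream,
        tree: MotionTree,
        config: InferenceConfig | None = None,
    ):
        if config is None:
            config = InferenceConfig()
        if stream.n_inputs != tree.n_inputs or stream.n_dims != tree.n_dims:
            raise ValueError("stream and tree disagree on (K, D)")
        if abs(stream.dt - config.dt) > 1e-9 * config.dt:
            config = _replace_dt(config, stream.dt)
        self.stream = stream
        self.tree = tree
        self.config = config
        self.ws = _Workspace(tree, config)

    @classmethod
    def from_arrays(
        cls,
        v: np.ndarray,
        tree: MotionTree,
        config: InferenceConfig,
    ) -> "OnlineMotionModel":
        """Build from a raw velocity array using ``config.sigma_obs``."""
        if config.sigma_obs is None:
            raise ValueError("config.sigma_obs required for raw arrays")
        sigma = np.broadcast_to(
            np.atleast_1d(np.asarray(config.sigma_obs, float)),
            (tree.n_inputs,),
        )
        T = v.shape[-3]
        stream = ObservationStream(
            v=v, times=np.arange(T) * config.dt, obs_var=sigma**2,
            dt=config.dt,
        )
        return cls(stream, tree, config)

    def fit(self) -> "OnlineMotionResults":
        return run_inference(self.stream, self.tree, self.config)


def run_inference(
    stream: ObservationStream,
    tree: MotionTree,
    config: InferenceConfig | None = None,
) -> "OnlineMotionResults":
    """Run the online EM dynamics over a stream; states at every frame."""
    model_cfg = config or InferenceConfig()
    ws = _Workspace(tree, model_cfg)
    batch = stream.batch_shape
    M, S = ws.M, ws.S
    lam0 = np.broadcast_to(
        np.atleast_1d(np.asarray(model_cfg.lambda_init, float)) ** 2, (M,)
    )
    lam_sq = np.broadcast_to(lam0, batch + (M,)).astype(float).copy()
    mu = np.zeros(batch + (S,))
    T = stream.n_frames
    stride = max(int(model_cfg.store_stride), 1)
    idx_store = np.arange(0, T, stride)
    lam_traj = np.empty(batch + (idx_store.size, M))
    mu_traj = np.empty(batch + (idx_store.size, S))
    j = 0
    for i in range(T):
        if j < idx_store.size and i == idx_store[j]:
            lam_traj[..., j, :] = lam_sq
            mu_traj[..., j, :] = mu
            j += 1
        v = stream.v[..., i, :, :]
        obs_var = stream.obs_var_at(i)
        if model_cfg.method == "rk4":
            lam_sq, mu = _rk4_frame(lam_sq, mu, v, obs_var, ws,
                                    model_cfg.n_substeps)
        else:
            lam_sq, mu = _rk45_frame(lam_sq, mu, v, obs_var, ws)
        if not (np.all(np.isfinite(lam_sq)) and np.all(np.isfinite(mu))):
            raise FloatingPointError(
                f"non-finite inference state after frame {i} "
                f"(t = {stream.times[i]:.4f} s)"
            )
    # trajectories are the state *entering* each stored frame; append final
    return OnlineMotionResults(
        tree=tree, config=model_cfg, stream=stream,
        times=stream.times[idx_store], lambda_sq=lam_traj, mu=mu_traj,
        final_state=InferenceState(
            mu=mu, lambda_sq=lam_sq,
            sigma_diag=adiabatic_variance(
                lam_sq[..., ws.comp], ws.g(stream.obs_var_at(T - 1)),
                model_cfg.tau_s),
        ),
        _ws=ws,
    )


def perceived_velocity(
    mu: np.ndarray, tree: MotionTree
) -> np.ndarray:
    """Perceived velocities: sum of all inferred components except self-motion.

    ``v_perceived[..., k, d] = sum_{m != self} C_kdm mu_m``.
    """
    keep = ~tree.self_mask
    return np.einsum(
        "kds,...s->...kd", tree.C_tensor[..., keep], mu[..., keep]
    )


@dataclass
class OnlineMotionResults:
    """Trajectories and diagnostics from a fitted online inference run.

    Attributes
    ----------
    times : stored frame times, shape ``(T,)``
    lambda_sq : squared motion strengths, ``(..., T, M)``
    mu : posterior source means, ``(..., T, S)``
    final_state : the state after the last frame
    """

    tree: MotionTree
    config: InferenceConfig
    stream: ObservationStream
    times: np.ndarray
    lambda_sq: np.ndarray
    mu: np.ndarray
    final_state: InferenceState
    _ws: _Workspace = field(repr=False, default=None)

    @property
    def lambda_(self) -> np.ndarray:
        """Motion strengths ``lambda_t`` (non-negative root)."""
        return np.sqrt(np.maximum(self.lambda_sq, 0.0))

    def sigma_diag(self) -> np.ndarray:
        """Adiabatic posterior variances along the trajectory, ``(..., T, S)``."""
        ws = self._ws
        g = ws.g(self.stream.obs_var_at(0))
        return adiabatic_variance(
            self.lambda_sq[..., ws.comp], g, self.config.tau_s
        )

    def perceived_velocity(self) -> np.ndarray:
        """Perceived velocities along the trajectory, ``(..., T, K, D)``."""
        return perceived_velocity(self.mu, self.tree)

    def prediction_error(self) -> np.ndarray:
        """Precision-normalized prediction error at stored frames."""
        vpred = self.tree.compose(self.mu)
        idx = np.searchsorted(self.stream.times, self.times)
        v = self.stream.v[..., idx, :, :]
        if self.stream.obs_var.ndim == 2:
            inv = 1.0 / self.stream.obs_var[idx][:, None]
        else:
            inv = 1.0 / self.stream.obs_var[:, None]
        return (v - vpred) * inv

    def summary(self) -> str:
        lam_end = np.sqrt(np.maximum(self.final_state.lambda_sq, 0.0))
        lam_end = lam_end.reshape(-1, self.tree.n_components).mean(axis=0)
        lines = [
            "Online hierarchical motion inference",
            "=" * 44,
            f"frames: {self.stream.n_frames}   inputs: {self.tree.n_inputs}"
            f"   dims: {self.tree.n_dims}",
            f"tau_s = {self.config.tau_s:.3f} s   "
            f"tau_lambda = {self.config.tau_lambda:.3f} s",
            "-" * 44,
            f"{'component':<18}{'kind':<14}{'lambda(T)':>10}",
        ]
        for comp, le in zip(self.tree.components, lam_end):
            lines.append(f"{comp.label:<18}{comp.kind:<14}{le:>10.4f}")
        return "\n".join(lines)


def _replace_dt(config: InferenceConfig, dt: float) -> InferenceConfig:
    from dataclasses import replace

    return replace(config, dt=dt)
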