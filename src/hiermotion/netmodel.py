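"""Rate-network realization of the online hierarchical inference model.

Three populations of rate neurons (``tau_i dr_i/dt = -r_i + f_i(w_i^T r +
r^T Q^(i) r)``) implement the algorithm under a linear population code:

* an **input population** per visual input — MT-like neurons tuned to
  direction (von Mises) and speed (Gaussian in log speed) whose gain grows
  with contrast (inversely with the observation-noise variance), so that
  ``v / sigma_obs^2`` and ``1 / sigma_obs^2`` can be read out linearly;
* a **distributed population** representing the squared motion strengths
  ``lambda^2``, the source means ``mu`` and the (low-passed) prediction
  errors ``eps`` through random linear readouts ``a_x``;
* a **1-to-1 population** with one unit per motion component whose
  activation function is the adiabatic variance ``f_Sigma``, encoding the
  posterior uncertainty ``Sigma_m = 0.001 * r_m``.

The distributed dynamics are constructed from the readout matrix ``A``
(rows ``a_x``) and its numerically computed adjoint ``G`` (``A G = I``):
with ``r = r_null + G x`` and

    tau_r dr/dt = -(r - r_null) + G (x + tau_r F(x)),

the decoded state ``x = A r`` follows ``dx/dt = F(x)`` exactly — the
strength/source dynamics of the online model with the prediction error
low-passed at ``tau_eps`` — while components outside the readout span decay
to the baseline.  Because the decoded dynamics do not depend on the random
realization of ``A``, all decoded quantities are representation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .defaults import load_defaults
from .generative import GenerativeParams, ObservationStream, simulate_stream
from .inference import (
    InferenceConfig,
    _Workspace,
    adiabatic_variance,
)
from .trees import (
    ComponentSpec,
    KIND_FOVEA,
    KIND_TRANS,
    MotionTree,
)

__all__ = [
    "TuningGrid",
    "NetworkSpec",
    "mt_encode",
    "fit_input_decoder",
    "build_network",
    "simulate_network",
    "ring_demo_tree",
    "ring_demo_stream",
    "q_decoding_experiment",
]


@dataclass
class TuningGrid:
    """Velocity-tuning grid of an MT-like input population.

    Preferred directions cover the circle equidistantly; preferred speeds
    follow ``rho_min + d_rho * n^1.25`` (denser at slow speeds), with
    ``d_rho = (rho_max - rho_min) / (N_rho - 1)^1.25``.
    """

    n_dir: int = 16
    n_speed: int = 12
    rho_min: float = 0.1
    rho_max: float = 8.0
    kappa_dir: float = 1.0 / 0.35**2
    sigma_logspeed_sq: float = 0.35**2
    rate_scale: float = 0.1            # Hz, overall firing-rate scale

    def __post_init__(self) -> None:
        n = np.arange(self.n_speed)
        d_rho = (self.rho_max - self.rho_min) / (self.n_speed - 1) ** 1.25
        self.speed_centers = self.rho_min + d_rho * n**1.25
        self.dir_centers = 2.0 * np.pi * np.arange(self.n_dir) / self.n_dir
        if np.any(np.diff(self.speed_centers) <= 0):
            raise ValueError("speed centers must be strictly increasing")

    @property
    def size(self) -> int:
        return self.n_dir * self.n_speed


def mt_encode(
    v: np.ndarray,
    obs_var: float | np.ndarray,
    grid: TuningGrid,
    sigma_ref_sq: float = (0.05 / 3.0) ** 2,
) -> np.ndarray:
    """Population rates for velocities ``v`` (..., 2).

    ``rate = psi * (sigma_ref^2 / obs_var) * vonMises(direction)
    * GaussianInLogSpeed(speed)``; higher contrast (smaller ``obs_var``)
    scales all rates up, making the linear readout of ``v / obs_var`` and
    ``1 / obs_var`` gain-equivariant.  Returns shape ``(..., size)`` with
    neurons ordered direction-major.
    """
    v = np.asarray(v, dtype=float)
    rho = np.hypot(v[..., 0], v[..., 1])
    alpha = np.arctan2(v[..., 1], v[..., 0])
    log_rho = np.log(np.maximum(rho, 1e-4 * grid.rho_min))
    dir_tune = np.exp(
        grid.kappa_dir
        * (np.cos(alpha[..., None] - grid.dir_centers) - 1.0)
    )                                                   # (..., n_dir)
    sp_tune = np.exp(
        -((log_rho[..., None] - np.log(grid.speed_centers)) ** 2)
        / (2.0 * grid.sigma_logspeed_sq)
    )                                                   # (..., n_speed)
    bump = dir_tune[..., :, None] * sp_tune[..., None, :]
    gain = grid.rate_scale * sigma_ref_sq / np.asarray(obs_var, dtype=float)
    return np.asarray(gain)[..., None] * bump.reshape(
        v.shape[:-1] + (grid.size,)
    )


def fit_input_decoder(
    grid: TuningGrid,
    sigma_ref_sq: float = (0.05 / 3.0) ** 2,
    n_dir_train: int = 64,
    n_speed_train: int = 48,
) -> np.ndarray:
    """Least-squares linear readout of ``(v_x/s^2, v_y/s^2, 1/s^2)``.

    Fitted once on a dense polar grid at the reference noise level; the
    contrast gain of :func:`mt_encode` makes the same weights valid for any
    ``obs_var``.  Returns ``W`` with shape ``(3, grid.size)``.
    """
    dirs = np.linspace(0.0, 2.0 * np.pi, n_dir_train, endpoint=False)
    speeds = np.geomspace(grid.rho_min, grid.rho_max, n_speed_train)
    aa, rr = np.meshgrid(dirs, speeds, indexing="ij")
    v = np.stack([rr * np.cos(aa), rr * np.sin(aa)], axis=-1).reshape(-1, 2)
    rates = mt_encode(v, sigma_ref_sq, grid, sigma_ref_sq)
    targets = np.column_stack(
        [v / sigma_ref_sq, np.full(v.shape[0], 1.0 / sigma_ref_sq)]
    )
    W, *_ = np.linalg.lstsq(rates, targets, rcond=None)
    return W.T


@dataclass
class NetworkSpec:
    """A constructed rate network for a given motion tree."""

    tree: MotionTree
    config: InferenceConfig
    grid: TuningGrid
    W_in: np.ndarray            # (3, n_mt) input decoder per population
    A: np.ndarray               # (n_x, N) readout vectors (rows)
    G: np.ndarray               # (N, n_x) adjoint, A G = I
    r_null: np.ndarray          # (N,) baseline rates (null space of A)
    obs_var: np.ndarray         # (K,) observation-noise variances
    tau_r: float = 0.020        # s, distributed-population time constant
    tau_one: float = 0.010      # s, 1-to-1 population time constant
    tau_eps: float = 0.050      # s, prediction-error low-pass
    one_to_one_gain: float = 0.001   # Sigma_m = gain * r_m
    sigma_ref_sq: float = (0.05 / 3.0) ** 2
    seed: int | None = None

    @property
    def n_distributed(self) -> int:
        return self.A.shape[1]

    @property
    def orthonormality_residual(self) -> float:
        n_x = self.A.shape[0]
        return float(np.max(np.abs(self.A @ self.G - np.eye(n_x))))

    def slices(self) -> tuple[slice, slice, slice]:
        """State layout of ``x``: (lambda^2, mu, eps)."""
        M = self.tree.n_components
        S = self.tree.n_cols
        KD = self.tree.n_inputs * self.tree.n_dims
        return slice(0, M), slice(M, M + S), slice(M + S, M + S + KD)


def build_network(
    tree: MotionTree,
    config: InferenceConfig | None = None,
    obs_var: np.ndarray | None = None,
    n_distributed: int = 100,
    seed: int | np.random.Generator = 0,
    grid: TuningGrid | None = None,
    baseline: float = 50.0,
) -> NetworkSpec:
    """Draw random readouts, compute the adjoint, and fit the input decoder."""
    rng = np.random.default_rng(seed)
    p = load_defaults("network")
    if config is None:
        config = InferenceConfig(
            tau_s=p["tau_s"], tau_lambda=p["tau_lambda"], dt=p["dt"],
            lambda_init=p["lambda_init"], sigma_obs=p["sigma_obs"],
        )
    if obs_var is None:
        obs_var = np.full(tree.n_inputs, p["sigma_obs"] ** 2)
    grid = grid or TuningGrid()
    M, S = tree.n_components, tree.n_cols
    KD = tree.n_inputs * tree.n_dims
    n_x = M + S + KD
    if n_distributed < n_x:
        raise ValueError(
            f"distributed population ({n_distributed}) smaller than the "
            f"represented state ({n_x}); the adjoint solve is rank-deficient"
        )
    A = rng.standard_normal((n_x, n_distributed))
    G = A.T @ np.linalg.inv(A @ A.T)
    r_null = baseline * np.ones(n_distributed)
    r_null -= G @ (A @ r_null)          # project onto the null space of A
    return NetworkSpec(
        tree=tree, config=config, grid=grid,
        W_in=fit_input_decoder(grid),
        A=A, G=G, r_null=r_null, obs_var=np.asarray(obs_var, dtype=float),
        tau_eps=p["tau_eps"],
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class NetworkResult:
    """Rates and decoded state of a network simulation."""

    times: np.ndarray
    r_distributed: np.ndarray    # (T, N)
    r_one_to_one: np.ndarray     # (T, M)
    r_input: np.ndarray          # (T, K, n_mt)
    lambda_sq: np.ndarray        # (T, M) decoded
    mu: np.ndarray               # (T, S) decoded
    eps: np.ndarray              # (T, K*D) decoded (low-passed)


def _network_rhs(y, r1, spec, ws, dec_v, dec_prec):
    """Derivatives of distributed rates and 1-to-1 rates."""
    cfg = spec.config
    sl_l, sl_m, sl_e = spec.slices()
    x = spec.A @ (y)
    lam_sq, mu, eps = x[sl_l], x[sl_m], x[sl_e]
    sigma_col = (spec.one_to_one_gain * r1)[ws.comp]     # per-column Sigma
    # instantaneous precision-weighted error from decoded input rates;
    # it drives the source update directly (quadratic interaction), while
    # the *represented* eps is its tau_eps-low-passed version
    prec_flat = np.repeat(dec_prec, ws.D)
    eps_inst = dec_v - (mu @ ws.C_flat.T) * prec_flat
    dmu = -mu / cfg.tau_s + sigma_col * (eps_inst @ ws.C_flat)
    stat = ws.comp_mean(mu**2 + sigma_col)
    dlam = -lam_sq / cfg.tau_lambda + ws.alpha * stat + ws.beta
    deps = (eps_inst - eps) / spec.tau_eps
    dx = np.concatenate([dlam, dmu, deps])
    dy = (-(y - spec.r_null) + spec.G @ (x + spec.tau_r * dx)) / spec.tau_r
    # 1-to-1 units: activation f_Sigma applied to the decoded lambda^2
    g, _ = ws.noise(spec.obs_var)
    g_comp = g[_first_col_of_comp(ws)]
    target = adiabatic_variance(lam_sq, g_comp, cfg.tau_s) \
        / spec.one_to_one_gain
    dr1 = (target - r1) / spec.tau_one
    return dy, dr1


def _first_col_of_comp(ws: _Workspace) -> np.ndarray:
    first = np.zeros(ws.M, dtype=int)
    seen = set()
    for s, m in enumerate(ws.comp):
        if m not in seen:
            first[m] = s
            seen.add(m)
    return first


def simulate_network(
    spec: NetworkSpec,
    stream: ObservationStream,
    n_substeps: int = 6,
) -> NetworkResult:
    """Integrate the network (RK4 substeps per frame) over a stream."""
    tree, cfg = spec.tree, spec.config
    ws = _Workspace(tree, cfg)
    sl_l, sl_m, sl_e = spec.slices()
    M, S = ws.M, ws.S
    T = stream.n_frames
    if stream.batch_shape:
        raise ValueError("network simulation runs a single trial at a time")
    lam0 = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.lambda_init, float)) ** 2, (M,)
    )
    x0 = np.zeros(M + S + tree.n_inputs * tree.n_dims)
    x0[sl_l] = lam0
    y = spec.r_null + spec.G @ x0
    g, _ = ws.noise(spec.obs_var)
    r1 = adiabatic_variance(
        lam0, g[_first_col_of_comp(ws)], cfg.tau_s
    ) / spec.one_to_one_gain
    h = stream.dt / n_substeps
    out_rd = np.empty((T, spec.n_distributed))
    out_r1 = np.empty((T, M))
    out_rin = np.empty((T, tree.n_inputs, spec.grid.size))
    for i in range(T):
        v = stream.v[i]
        obs_var = stream.obs_var_at(i)
        r_in = mt_encode(v, obs_var, spec.grid, spec.sigma_ref_sq)
        dec = r_in @ spec.W_in.T                         # (K, 3)
        scale = spec.sigma_ref_sq / obs_var              # actual/ref gain
        dec_v = (dec[:, :2]).reshape(-1)
        dec_prec = dec[:, 2]
        out_rd[i], out_r1[i], out_rin[i] = y, r1, r_in
        for _ in range(n_substeps):
            k1y, k1r = _network_rhs(y, r1, spec, ws, dec_v, dec_prec)
            k2y, k2r = _network_rhs(y + 0.5 * h * k1y, r1 + 0.5 * h * k1r,
                                    spec, ws, dec_v, dec_prec)
            k3y, k3r = _network_rhs(y + 0.5 * h * k2y, r1 + 0.5 * h * k2r,
                                    spec, ws, dec_v, dec_prec)
            k4y, k4r = _network_rhs(y + h * k3y, r1 + h * k3r,
                                    spec, ws, dec_v, dec_prec)
            y = y + h / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
            r1 = r1 + h / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"network diverged at frame {i}")
    x_traj = out_rd @ spec.A.T
    return NetworkResult(
        times=stream.times, r_distributed=out_rd, r_one_to_one=out_r1,
        r_input=out_rin, lambda_sq=x_traj[:, sl_l], mu=x_traj[:, sl_m],
        eps=x_traj[:, sl_e],
    )


# --------------------------------------------------------------------------
# Reference protocols
# --------------------------------------------------------------------------

def ring_demo_tree(n_inputs: int = 6) -> MotionTree:
    """Six inputs on a unit ring: shared translation + shared polar +
    individual Cartesian components (M = 8 motion strengths)."""
    theta = np.radians(60.0 * np.arange(n_inputs))
    ones = np.ones(n_inputs)
    comps = [
        ComponentSpec("shared_trans", KIND_TRANS, ones),
        ComponentSpec("shared_polar", KIND_FOVEA, ones),
    ]
    for k in range(n_inputs):
        e = np.zeros(n_inputs)
        e[k] = 1.0
        comps.append(ComponentSpec(f"ind_{k}", KIND_TRANS, e))
    return MotionTree(
        comps, n_inputs=n_inputs, n_dims=2,
        input_radius=np.ones(n_inputs), input_angle=theta,
    )


def ring_demo_stream(
    duration: float = 3.0, seed: int | np.random.Generator = 0
) -> tuple[ObservationStream, MotionTree]:
    """Piecewise rotational/translational stimulus on the unit ring.

    CCW rotation of speed 2 for t <= 1 s, CW rotation for 1 < t <= 2 s,
    CW rotation plus rightward translation afterwards.
    """
    rng = np.random.default_rng(seed)
    p = load_defaults("network")
    tree = ring_demo_tree()
    theta = tree.input_angle
    t = np.arange(int(round(duration / p["dt"]))) * p["dt"]
    v = np.zeros((t.size, tree.n_inputs, 2))
    ccw = np.stack([-2.0 * np.sin(theta), 2.0 * np.cos(theta)], axis=-1)
    v[t <= 1.0] = ccw
    v[(t > 1.0)] = -ccw
    v[t > 2.0, :, 0] += 2.0
    sig2 = p["sigma_obs"] ** 2
    v += np.sqrt(sig2 / p["dt"]) * rng.standard_normal(v.shape)
    stream = ObservationStream(
        v=v, times=t, obs_var=np.full(tree.n_inputs, sig2), dt=p["dt"]
    )
    return stream, tree


def q_decoding_experiment(
    q_values: np.ndarray | None = None,
    n_runs: int = 10,
    duration: float = 10.0,
    seed: int | np.random.Generator = 0,
    n_inputs: int = 6,
    n_distributed: int = 100,
    total_sq: float = 4.0,
) -> dict:
    """Decode the fraction of shared motion from distributed-population rates.

    Stimuli are drawn from the generative model with
    ``lambda_shared^2 = total_sq * q`` and ``lambda_ind^2 = total_sq (1-q)``
    (constant total squared strength, so marginal input statistics are
    identical across ``q``).  A linear regression is trained on the
    per-frame rates of the two extreme fractions (second half of each run)
    and used to decode the intermediate ones.
    """
    from sklearn.linear_model import LinearRegression

    rng = np.random.default_rng(seed)
    if q_values is None:
        q_values = np.arange(1, 8) / 8.0
    p = load_defaults("network")
    ones = np.ones(n_inputs)
    comps = [ComponentSpec("shared", KIND_TRANS, ones)]
    for k in range(n_inputs):
        e = np.zeros(n_inputs)
        e[k] = 1.0
        comps.append(ComponentSpec(f"ind_{k}", KIND_TRANS, e))
    tree = MotionTree(comps, n_inputs=n_inputs, n_dims=2)
    spec = build_network(tree, n_distributed=n_distributed, seed=rng)
    rates, qs, runs = [], [], []
    for q in q_values:
        lam = np.sqrt(
            np.concatenate([[total_sq * q],
                            np.full(n_inputs, total_sq * (1.0 - q))])
        )
        for run in range(n_runs):
            params = GenerativeParams(
                lam=lam, tau_s=p["tau_s"], sigma_obs=p["sigma_obs"],
                dt=p["dt"],
            )
            stream = simulate_stream(tree, params, duration, rng)
            res = simulate_network(spec, stream)
            sel = res.times >= duration / 2.0
            rates.append(res.r_distributed[sel])
            qs.append(np.full(sel.sum(), q))
            runs.append(np.full(sel.sum(), run))
    rates = np.concatenate(rates)
    qs = np.concatenate(qs)
    runs = np.concatenate(runs)
    train = np.isin(qs, (q_values.min(), q_values.max()))
    reg = LinearRegression().fit(rates[train], qs[train])
    decoded = reg.predict(rates)
    mean_decoded = np.array(
        [decoded[qs == q].mean() for q in q_values]
    )
    return {
        "q_values": q_values,
        "decoded_mean": mean_decoded,
        "decoded": decoded,
        "q_per_sample": qs,
        "run_per_sample": runs,
        "regressor": reg,
        "spec": spec,
    }
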