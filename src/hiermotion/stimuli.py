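"""Deterministic stimulus protocols for classical psychophysics displays.

Each protocol pairs noise-free per-input velocity functions with a motion
tree and per-input noise levels.  The model receives *velocities* only;
positions never enter the inference.  Sampling a protocol adds one
independent observation-noise draw per frame (variance ``sigma_obs^2/dt``
for visual inputs); the vestibular channel, where present, is drawn i.i.d.
``N(0, sigma_vst^2)`` per frame while the inference weights it with
precision ``1/sigma_vst^2``.

Protocols
---------
* Johansson 3-dot display: shared horizontal oscillation with a nested
  vertical oscillation of the central dot.
* Duncker wheel: hub + rim dot of a rolling wheel.
* Motion direction repulsion (MDR): two dot groups at opening angle
  ``gamma`` plus a vestibular input, with optional contrast and speed
  manipulations of the second group.
* Surround MDR (annulus): two inner and two outer dot groups.
* Lorenceau illusion: two groups of ten dots oscillating with a 90-degree
  phase shift consistent with global clockwise rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .defaults import load_defaults
from .generative import ObservationStream
from .inference import InferenceConfig, OnlineMotionModel, OnlineMotionResults
from .trees import ComponentSpec, KIND_SELF, KIND_TRANS, MotionTree

__all__ = [
    "StimulusProtocol",
    "johansson_stimulus",
    "duncker_stimulus",
    "mdr_stimulus",
    "takemura_stimulus",
    "lorenceau_stimulus",
    "sample_stream",
    "run_protocol",
    "measure_repulsion_bias",
    "measure_rotation_percept",
]


@dataclass
class StimulusProtocol:
    """A deterministic stimulus plus everything needed to run the model."""

    name: str
    duration: float                        # s
    dt: float
    tree: MotionTree
    clean_fn: Callable[[np.ndarray], np.ndarray]   # times (T,) -> (T, K, D)
    obs_var: np.ndarray                    # (K,) inference noise variances
    frame_noise_var: np.ndarray            # (K,) per-frame draw variances
    config: InferenceConfig
    n_repetitions: int = 20
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.obs_var <= 0) or np.any(self.frame_noise_var < 0):
            raise ValueError("noise variances must be positive")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.dt))
        return np.arange(n) * self.dt


def sample_stream(
    protocol: StimulusProtocol,
    n_reps: int,
    seed: int | np.random.Generator,
) -> ObservationStream:
    """Draw ``n_reps`` noisy repetitions of the protocol (batched stream)."""
    rng = np.random.default_rng(seed)
    t = protocol.times
    clean = protocol.clean_fn(t)                       # (T, K, D)
    sd = np.sqrt(protocol.frame_noise_var)[:, None]    # (K, 1)
    shape = (n_reps,) + clean.shape
    v = clean[None] + sd * rng.standard_normal(shape)
    return ObservationStream(
        v=v, times=t, obs_var=protocol.obs_var, dt=protocol.dt
    )


def run_protocol(
    protocol: StimulusProtocol,
    n_reps: int | None = None,
    seed: int | np.random.Generator = 0,
) -> OnlineMotionResults:
    """Sample repetitions of the protocol and fit the online model."""
    if n_reps is None:
        n_reps = protocol.n_repetitions
    stream = sample_stream(protocol, n_reps, seed)
    return OnlineMotionModel(stream, protocol.tree, protocol.config).fit()


def _config(defaults: dict, **overrides) -> InferenceConfig:
    cfg = InferenceConfig(
        tau_s=defaults["tau_s"],
        tau_lambda=defaults["tau_lambda"],
        dt=defaults["dt"],
        lambda_init=defaults["lambda_init"],
        sigma_obs=defaults["sigma_obs"],
    )
    from dataclasses import replace

    return replace(cfg, **overrides) if overrides else cfg


# --------------------------------------------------------------------------
# Object-indexed displays
# --------------------------------------------------------------------------

def johansson_stimulus(duration: float = 20.0) -> StimulusProtocol:
    """Johansson's 3-dot display.

    All dots oscillate horizontally at 0.5 Hz with position amplitude
    ``2 sqrt(tau_s)``; the central dot adds a vertical oscillation with
    position amplitude ``cos(45 deg) * 2 sqrt(tau_s)``.  Humans perceive
    shared horizontal motion plus nested vertical motion of the central dot.
    """
    p = load_defaults("object_indexed")
    tau_s = p["tau_s"]
    amp = 2.0 * math.sqrt(tau_s)
    omega = 2.0 * math.pi * 0.5
    tree = MotionTree(
        [
            ComponentSpec("shared", KIND_TRANS, [1, 1, 1]),
            ComponentSpec("ind_outer_a", KIND_TRANS, [1, 0, 0]),
            ComponentSpec("ind_center", KIND_TRANS, [0, 1, 0]),
            ComponentSpec("ind_outer_b", KIND_TRANS, [0, 0, 1]),
        ],
        n_inputs=3, n_dims=2,
    )

    def clean(t: np.ndarray) -> np.ndarray:
        v = np.zeros((t.size, 3, 2))
        vx = amp * omega * np.cos(omega * t)
        v[:, :, 0] = vx[:, None]
        v[:, 1, 1] = math.cos(math.radians(45.0)) * vx
        return v

    sig2 = p["sigma_obs"] ** 2
    return StimulusProtocol(
        name="johansson", duration=duration, dt=p["dt"], tree=tree,
        clean_fn=clean,
        obs_var=np.full(3, sig2),
        frame_noise_var=np.full(3, sig2 / p["dt"]),
        config=_config(p),
        meta={"position_amplitude": amp, "omega": omega},
    )


def duncker_stimulus(duration: float = 12.0) -> StimulusProtocol:
    """Duncker wheel: hub plus one dot on the rim of a rolling wheel.

    Slip-free rolling at 1 Hz with radius 1: hub velocity ``(2 pi, 0)``;
    rim velocity ``(2 pi + R w cos(w t), -R w sin(w t))`` with
    ``R = 1, w = 2 pi``.  Runs with increased observation noise
    (``sigma_obs = 0.15``) and small initial strengths
    (``lambda(0) = 0.1``) to expose the gradual discovery of components.
    """
    p = load_defaults("object_indexed")
    sigma_obs = 0.15
    omega = 2.0 * math.pi
    R = 1.0
    tree = MotionTree(
        [
            ComponentSpec("shared", KIND_TRANS, [1, 1]),
            ComponentSpec("ind_hub", KIND_TRANS, [1, 0]),
            ComponentSpec("ind_rim", KIND_TRANS, [0, 1]),
        ],
        n_inputs=2, n_dims=2,
    )

    def clean(t: np.ndarray) -> np.ndarray:
        v = np.empty((t.size, 2, 2))
        v[:, 0, 0] = 2.0 * math.pi
        v[:, 0, 1] = 0.0
        v[:, 1, 0] = 2.0 * math.pi + R * omega * np.cos(omega * t)
        v[:, 1, 1] = -R * omega * np.sin(omega * t)
        return v

    return StimulusProtocol(
        name="duncker", duration=duration, dt=p["dt"], tree=tree,
        clean_fn=clean,
        obs_var=np.full(2, sigma_obs**2),
        frame_noise_var=np.full(2, sigma_obs**2 / p["dt"]),
        config=_config(p, sigma_obs=sigma_obs, lambda_init=0.1),
        meta={"omega": omega, "R": R},
    )


# --------------------------------------------------------------------------
# Location-indexed displays (with self-motion + vestibular input)
# --------------------------------------------------------------------------

def _self_tree(
    n_visual: int,
    extra: list[ComponentSpec],
    nu_self: float,
) -> MotionTree:
    """Tree with self-motion over ``n_visual`` inputs + trailing vestibular."""
    K = n_visual + 1
    sm = -np.ones(K)
    sm[-1] = +1.0
    comps = [ComponentSpec("self", KIND_SELF, sm, prior_nu=nu_self)] + extra
    return MotionTree(comps, n_inputs=K, n_dims=2, vestibular_index=K - 1)


def mdr_stimulus(
    gamma: float,
    contrast_factor: float = 1.0,
    speed_factor: float = 1.0,
    duration: float = 30.0,
) -> StimulusProtocol:
    """Motion direction repulsion: two dot groups at opening angle ``gamma``.

    Group 1 moves at ``v0 (cos(gamma/2), sin(gamma/2))`` with
    ``v0 = 2 sqrt(tau_s)``; group 2 mirrors it below the horizontal, its
    speed multiplied by ``speed_factor`` and its observation-noise variance
    divided by ``contrast_factor`` (higher contrast = less noise).  A
    zero-mean noisy vestibular input disambiguates self-motion.

    ``gamma`` in degrees, in [0, 180].
    """
    if not 0.0 <= gamma <= 180.0:
        raise ValueError("gamma must be in [0, 180] degrees")
    if contrast_factor <= 0:
        raise ValueError("contrast_factor must be > 0")
    p = load_defaults("location_indexed")
    v0 = 2.0 * math.sqrt(p["tau_s"])
    half = math.radians(gamma / 2.0)
    extra = [
        ComponentSpec("shared", KIND_TRANS, [1, 1, 0]),
        ComponentSpec("ind_g1", KIND_TRANS, [1, 0, 0]),
        ComponentSpec("ind_g2", KIND_TRANS, [0, 1, 0]),
    ]
    tree = _self_tree(2, extra, nu_self=p["nu_self"])
    v1 = v0 * np.array([math.cos(half), math.sin(half)])
    v2 = v0 * speed_factor * np.array([math.cos(half), -math.sin(half)])

    def clean(t: np.ndarray) -> np.ndarray:
        v = np.zeros((t.size, 3, 2))
        v[:, 0, :] = v1
        v[:, 1, :] = v2
        return v

    sig2 = p["sigma_obs"] ** 2
    obs_var = np.array([sig2, sig2 / contrast_factor, p["sigma_vst"] ** 2])
    frame_var = np.array(
        [sig2 / p["dt"], sig2 / contrast_factor / p["dt"],
         p["sigma_vst"] ** 2]
    )
    return StimulusProtocol(
        name="mdr", duration=duration, dt=p["dt"], tree=tree,
        clean_fn=clean, obs_var=obs_var, frame_noise_var=frame_var,
        config=_config(p),
        meta={
            "gamma": gamma, "v0": v0, "contrast_factor": contrast_factor,
            "speed_factor": speed_factor, "group_inputs": (0, 1),
        },
    )


_TAKEMURA_CONDITIONS = {
    # (inner diagonal?, outer mode)
    "bidir_h": (False, "bidir"),
    "coherent_down_h": (False, "down"),
    "down_diag": (True, "down"),
    "bidir_diag": (True, "bidir"),
    "up_diag": (True, "up"),
}


def takemura_stimulus(
    condition: str,
    duration: float = 5.0,
) -> StimulusProtocol:
    """Surround MDR: two inner RDKs plus two outer (annulus) RDKs.

    Inner stimuli move at ``v_x = +/- v0`` (plus ``v_y = v0`` in the
    diagonal conditions); outer stimuli move vertically (``v_y = +/- v0``,
    both up, or both down).  The outer observation-noise SD is divided by 6
    (larger area, higher dot density).  Tree: self -> shared ->
    {inner group, outer group} -> 4 individual components.
    """
    try:
        diag, outer_mode = _TAKEMURA_CONDITIONS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; "
            f"one of {sorted(_TAKEMURA_CONDITIONS)}"
        ) from None
    p = load_defaults("location_indexed")
    v0 = 2.0 * math.sqrt(p["tau_s"])
    extra = [
        ComponentSpec("shared", KIND_TRANS, [1, 1, 1, 1, 0]),
        ComponentSpec("grp_inner", KIND_TRANS, [1, 1, 0, 0, 0]),
        ComponentSpec("grp_outer", KIND_TRANS, [0, 0, 1, 1, 0]),
        ComponentSpec("ind_in1", KIND_TRANS, [1, 0, 0, 0, 0]),
        ComponentSpec("ind_in2", KIND_TRANS, [0, 1, 0, 0, 0]),
        ComponentSpec("ind_out1", KIND_TRANS, [0, 0, 1, 0, 0]),
        ComponentSpec("ind_out2", KIND_TRANS, [0, 0, 0, 1, 0]),
    ]
    tree = _self_tree(4, extra, nu_self=p["nu_self"])
    vy_in = v0 if diag else 0.0
    inner = np.array([[+v0, vy_in], [-v0, vy_in]])
    outer = {
        "bidir": np.array([[0.0, +v0], [0.0, -v0]]),
        "down": np.array([[0.0, -v0], [0.0, -v0]]),
        "up": np.array([[0.0, +v0], [0.0, +v0]]),
    }[outer_mode]

    def clean(t: np.ndarray) -> np.ndarray:
        v = np.zeros((t.size, 5, 2))
        v[:, 0:2, :] = inner
        v[:, 2:4, :] = outer
        return v

    sig2 = p["sigma_obs"] ** 2
    sig2_out = (p["sigma_obs"] / 6.0) ** 2
    obs_var = np.array(
        [sig2, sig2, sig2_out, sig2_out, p["sigma_vst"] ** 2]
    )
    frame_var = obs_var / p["dt"]
    frame_var[-1] = p["sigma_vst"] ** 2
    return StimulusProtocol(
        name=f"takemura_{condition}", duration=duration, dt=p["dt"],
        tree=tree, clean_fn=clean, obs_var=obs_var,
        frame_noise_var=frame_var, config=_config(p),
        n_repetitions=200,
        meta={"condition": condition, "v0": v0, "inner_inputs": (0, 1)},
    )


def lorenceau_stimulus(
    noisy: bool,
    duration: float = 6.0,
    n_per_group: int = 10,
) -> StimulusProtocol:
    """Lorenceau's noise-dependent motion-integration illusion.

    Two groups of dots oscillate (horizontal group: ``v_x = R w cos(w t)``;
    vertical group: ``v_y = -R w sin(w t)``; ``R = 1/2``,
    ``w = 2 pi * 0.83 /s``), maintaining a 90-degree phase shift consistent
    with global clockwise rotation.  ``noisy=True`` multiplies the visual
    observation noise by 25 (the vestibular channel is unchanged), which
    flips the perceived rotation from counter-clockwise (transparent
    motion) to clockwise (coherent rotation).
    """
    p = load_defaults("location_indexed")
    R = 0.5
    omega = 2.0 * math.pi * 0.83
    n_dots = 2 * n_per_group
    sigma_vis = p["sigma_obs"] * (25.0 if noisy else 1.0)
    extra = [ComponentSpec("shared", KIND_TRANS,
                           [1] * n_dots + [0])]
    g_h = np.zeros(n_dots + 1)
    g_h[:n_per_group] = 1
    g_v = np.zeros(n_dots + 1)
    g_v[n_per_group:n_dots] = 1
    extra.append(ComponentSpec("grp_h", KIND_TRANS, g_h))
    extra.append(ComponentSpec("grp_v", KIND_TRANS, g_v))
    for k in range(n_dots):
        e = np.zeros(n_dots + 1)
        e[k] = 1
        extra.append(ComponentSpec(f"ind_{k}", KIND_TRANS, e))
    tree = _self_tree(n_dots, extra, nu_self=p["nu_self"])

    def clean(t: np.ndarray) -> np.ndarray:
        v = np.zeros((t.size, n_dots + 1, 2))
        v[:, :n_per_group, 0] = (R * omega * np.cos(omega * t))[:, None]
        v[:, n_per_group:n_dots, 1] = (-R * omega * np.sin(omega * t))[:, None]
        return v

    obs_var = np.full(n_dots + 1, sigma_vis**2)
    obs_var[-1] = p["sigma_vst"] ** 2
    frame_var = obs_var / p["dt"]
    frame_var[-1] = p["sigma_vst"] ** 2
    return StimulusProtocol(
        name="lorenceau_noisy" if noisy else "lorenceau",
        duration=duration, dt=p["dt"], tree=tree, clean_fn=clean,
        obs_var=obs_var, frame_noise_var=frame_var, config=_config(p),
        n_repetitions=10,
        meta={
            "noisy": noisy, "omega": omega, "R": R,
            "group_h": tuple(range(n_per_group)),
            "group_v": tuple(range(n_per_group, n_dots)),
            "window": 5.0 if noisy else 2.0,
        },
    )


# --------------------------------------------------------------------------
# Percept measurements
# --------------------------------------------------------------------------

def measure_repulsion_bias(
    results: OnlineMotionResults,
    protocol: StimulusProtocol,
    reference: str = "full_angle",
    averaging_window: float = 10.0,
) -> float:
    """Repulsion bias (degrees) of an MDR run.

    Perceived velocities are averaged over the last ``averaging_window``
    seconds of each trial and across repetitions (vector average before
    angle extraction).  ``reference="full_angle"`` measures the perceived
    opening angle between the two groups against the true angle;
    ``reference="first_group_vs_horizontal"`` measures only the first
    group's perceived direction against its true direction ``gamma / 2``.
    """
    gamma = protocol.meta["gamma"]
    k1, k2 = protocol.meta["group_inputs"]
    t = results.times
    t_end = t[-1]
    if t_end - t[0] < averaging_window:
        raise ValueError("trial shorter than the averaging window")
    win = t >= t_end - averaging_window
    vp = results.perceived_velocity()[..., win, :, :]   # (..., Tw, K, D)
    mean_v = vp.mean(axis=tuple(range(vp.ndim - 2)))    # (K, D)
    ang1 = math.degrees(math.atan2(mean_v[k1, 1], mean_v[k1, 0]))
    if reference == "first_group_vs_horizontal":
        return ang1 - gamma / 2.0
    if reference == "full_angle":
        ang2 = math.degrees(math.atan2(mean_v[k2, 1], mean_v[k2, 0]))
        return (ang1 - ang2) - gamma
    raise ValueError(f"unknown reference {reference!r}")


def _box_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Box filter along the last axis."""
    kernel = np.ones(width) / width
    return np.apply_along_axis(
        lambda a: np.convolve(a, kernel, mode="same"), -1, x
    )


def measure_rotation_percept(
    results: OnlineMotionResults,
    protocol: StimulusProtocol,
    smooth: float = 0.2,
) -> np.ndarray:
    """Signed rotation indicator of the perceived-velocity orbit per trial.

    For each repetition, the perceived velocities of each dot group are
    averaged within the group, smoothed with a ``smooth``-seconds box
    filter, and the time-averaged cross product ``v x dv/dt`` over the
    protocol's evaluation window is computed; the sign (+1 CCW / -1 CW) of
    the mean over both groups is returned, shape ``(n_reps,)``.
    """
    window = protocol.meta["window"]
    gh = list(protocol.meta["group_h"])
    gv = list(protocol.meta["group_v"])
    t = results.times
    sel = t <= window
    vp = results.perceived_velocity()                    # (R, T, K, D)
    if vp.ndim == 3:
        vp = vp[None]
    curves = np.stack(
        [vp[:, :, gh, :].mean(axis=2), vp[:, :, gv, :].mean(axis=2)], axis=1
    )                                                    # (R, 2, T, D)
    width = max(int(round(smooth / protocol.dt)), 1)
    vx = _box_smooth(curves[..., 0], width)[..., sel]
    vy = _box_smooth(curves[..., 1], width)[..., sel]
    dt = protocol.dt
    dvx = np.gradient(vx, dt, axis=-1)
    dvy = np.gradient(vy, dt, axis=-1)
    cross = (vx * dvy - vy * dvx).mean(axis=-1)          # (R, 2)
    return np.sign(cross.mean(axis=-1))
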