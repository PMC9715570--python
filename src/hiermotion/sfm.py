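"""Structure-from-motion: rotating-cylinder displays and bistable percepts.

A transparent cylinder covered with dots, viewed frontally, projects to
pairs of spatially overlapping leftward/rightward velocities.  Each cylinder
is modeled as a ring in the x-z plane observed at fixed receptive-field
(RF) x-positions; a surface point at angle ``phi`` (with ``x = R cos(phi)``)
contributes ``v_x = -R sin(phi) * s_rot`` and ``v_y = 0``, linear in the
angular-velocity source ``s_rot`` (counter-clockwise positive, seen from
above).

The depth ambiguity (front vs back surface) is a correspondence problem:
which observed velocity belongs to which surface point.  It is resolved by
a local assignment process: at every frame and RF independently, the
previous assignment is kept with probability ``p_keep``; otherwise all
permutations of the RF's overlapping observations are scored against the
model's predicted velocities ``C mu`` and the Euclidean-distance minimizer
is chosen.  All RFs are decided before the state is integrated, so the
process is order-independent across RFs.

The inferred rotation ``mu_rot`` switches stochastically between signs;
inter-switch durations follow a Gamma distribution, as in human bistable
perception.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .defaults import load_defaults
from .generative import ObservationStream
from .inference import (
    InferenceConfig,
    OnlineMotionResults,
    _rk4_frame,
    _Workspace,
    adiabatic_variance,
    InferenceState,
)
from .stimuli import StimulusProtocol
from .trees import (
    ComponentSpec,
    KIND_ROT_VERTICAL,
    KIND_SELF,
    KIND_TRANS,
    MotionTree,
)

__all__ = [
    "CylinderScene",
    "cylinder_stimulus",
    "assignment_step",
    "run_sfm",
    "switch_statistics",
    "SwitchStatistics",
]

RF_X = np.array([1.2, 0.8, 0.4, 0.0, -0.4, -0.8, -1.2])


@dataclass
class CylinderScene:
    """Geometry and correspondence structure of a cylinder display.

    ``point_cyl``/``point_phi``/``point_radius`` describe each visual input's
    surface point; ``rf_groups`` lists, per RF location, the visual input
    indices whose observations spatially overlap (2 for one cylinder, 4
    where two nested cylinders overlap).
    """

    radii: np.ndarray                 # per cylinder
    omegas: np.ndarray                # per cylinder, rad/s (signed, CCW > 0)
    rf_x: np.ndarray
    point_cyl: np.ndarray             # (n_points,) cylinder index
    point_phi: np.ndarray             # (n_points,) surface angle
    point_radius: np.ndarray          # (n_points,)
    rf_groups: list[np.ndarray] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.point_phi.size


def cylinder_stimulus(
    speeds_deg: tuple[float, ...] = (90.0,),
    nested: bool = False,
    duration: float = 100.0,
) -> tuple[StimulusProtocol, CylinderScene]:
    """Build the cylinder SfM stimulus and its motion tree.

    ``speeds_deg`` gives each cylinder's rotation speed in deg/s (signed;
    the classic conditions are 90 and 135 deg/s).  Single cylinder:
    radius 1.5, seven RFs at x in {1.2, 0.8, ..., -1.2}; nested adds an
    inner cylinder of radius 1.0 covering five RFs.  Visual observation
    noise is the location-indexed default multiplied by 20 (single) or 30
    (nested).  The tree holds self-motion, rotational component(s)
    (shared/outer/inner for nested displays), and one translational
    individual component per visual input.
    """
    if nested and len(speeds_deg) != 2:
        raise ValueError("nested display needs two speeds (outer, inner)")
    if not nested and len(speeds_deg) != 1:
        raise ValueError("single display needs one speed")
    p = load_defaults("location_indexed")
    radii = np.array([1.5, 1.0][: len(speeds_deg)])
    omegas = np.radians(np.asarray(speeds_deg, dtype=float))

    point_cyl, point_phi, point_r = [], [], []
    rf_groups: list[list[int]] = [[] for _ in RF_X]
    for ci, R in enumerate(radii):
        for ri, x in enumerate(RF_X):
            if abs(x) > R:
                continue
            phi0 = float(np.arccos(x / R))
            for phi in (phi0, -phi0):      # front/back surface points
                rf_groups[ri].append(len(point_phi))
                point_cyl.append(ci)
                point_phi.append(phi)
                point_r.append(R)
    scene = CylinderScene(
        radii=radii, omegas=omegas, rf_x=RF_X.copy(),
        point_cyl=np.array(point_cyl), point_phi=np.array(point_phi),
        point_radius=np.array(point_r),
        rf_groups=[np.array(g) for g in rf_groups],
    )

    n_pts = scene.n_points
    K = n_pts + 1                       # + vestibular
    sm = -np.ones(K)
    sm[-1] = +1.0
    comps = [ComponentSpec("self", KIND_SELF, sm, prior_nu=p["nu_self"])]
    vis = np.zeros(K)
    vis[:n_pts] = 1.0
    if nested:
        comps.append(ComponentSpec("rot_shared", KIND_ROT_VERTICAL, vis))
        for ci, name in enumerate(("rot_outer", "rot_inner")):
            mask = np.zeros(K)
            mask[:n_pts][scene.point_cyl == ci] = 1.0
            comps.append(ComponentSpec(name, KIND_ROT_VERTICAL, mask))
    else:
        comps.append(ComponentSpec("rot", KIND_ROT_VERTICAL, vis))
    for i in range(n_pts):
        e = np.zeros(K)
        e[i] = 1.0
        comps.append(ComponentSpec(f"ind_{i}", KIND_TRANS, e))
    tree = MotionTree(
        comps, n_inputs=K, n_dims=2,
        input_radius=np.append(scene.point_radius, 0.0),
        input_angle=np.append(scene.point_phi, 0.0),
        vestibular_index=K - 1,
    )

    vx_true = -scene.point_radius * np.sin(scene.point_phi) \
        * omegas[scene.point_cyl]

    def clean(t: np.ndarray) -> np.ndarray:
        v = np.zeros((t.size, K, 2))
        v[:, :n_pts, 0] = vx_true
        return v

    noise_mult = 30.0 if nested else 20.0
    sigma_vis = p["sigma_obs"] * noise_mult
    obs_var = np.full(K, sigma_vis**2)
    obs_var[-1] = p["sigma_vst"] ** 2
    frame_var = obs_var / p["dt"]
    frame_var[-1] = p["sigma_vst"] ** 2
    cfg = InferenceConfig(
        tau_s=p["tau_s"], tau_lambda=p["tau_lambda"], dt=p["dt"],
        lambda_init=p["lambda_init"], sigma_obs=sigma_vis,
    )
    protocol = StimulusProtocol(
        name="sfm_nested" if nested else "sfm", duration=duration,
        dt=p["dt"], tree=tree, clean_fn=clean, obs_var=obs_var,
        frame_noise_var=frame_var, config=cfg, n_repetitions=1,
        meta={"nested": nested, "speeds_deg": tuple(speeds_deg),
              "noise_mult": noise_mult},
    )
    return protocol, scene


_PERMS: dict[int, np.ndarray] = {
    n: np.array(list(itertools.permutations(range(n)))) for n in (1, 2, 4)
}


def candidate_permutations(group_size: int) -> np.ndarray:
    """All permutations of a group of overlapping observations."""
    if group_size not in _PERMS:
        _PERMS[group_size] = np.array(
            list(itertools.permutations(range(group_size)))
        )
    return _PERMS[group_size]


def assignment_step(
    scene: CylinderScene,
    v_pred: np.ndarray,
    v_frame: np.ndarray,
    current: list[int],
    p_keep: float,
    rng: np.random.Generator,
) -> list[int]:
    """Re-evaluate the per-RF assignment of overlapping observations.

    ``v_pred`` are the model's expected velocities ``C mu`` (K, D);
    ``v_frame`` the observed velocities (K, D); ``current`` holds, per RF,
    the index of the active permutation.  Each RF independently keeps its
    permutation with probability ``p_keep``, otherwise all permutations of
    its overlapping observations are enumerated and the Euclidean-distance
    minimizer is selected.  All decisions use the same ``v_pred`` snapshot,
    so the result is independent of the RF iteration order.
    """
    new = list(current)
    keep = rng.random(len(scene.rf_groups)) < p_keep
    for ri, grp in enumerate(scene.rf_groups):
        if grp.size == 0 or keep[ri]:
            continue
        perms = candidate_permutations(grp.size)         # (n_p, n)
        diff = v_pred[grp][None, :, :] - v_frame[grp[perms]]
        cost = np.einsum("pnd,pnd->p", diff, diff)
        new[ri] = int(np.argmin(cost))
    return new


def apply_assignment(
    scene: CylinderScene, v_frame: np.ndarray, perm_idx: list[int]
) -> np.ndarray:
    """Permute each RF's overlapping observations per the active assignment."""
    v = v_frame.copy()
    for ri, grp in enumerate(scene.rf_groups):
        if grp.size:
            perms = candidate_permutations(grp.size)
            v[grp] = v_frame[grp[perms[perm_idx[ri]]]]
    return v


@dataclass
class SfmResult:
    """Trajectories from a structure-from-motion run."""

    times: np.ndarray
    mu_rot: np.ndarray          # (T, n_rot) rotational source means
    rot_labels: list[str]
    lambda_sq: np.ndarray       # (T, M)
    tree: MotionTree
    assignments: np.ndarray     # (T, n_rf) active permutation index


def run_sfm(
    protocol: StimulusProtocol,
    scene: CylinderScene,
    T: float | None = None,
    seed: int | np.random.Generator = 0,
    p_keep: float = 0.7,
    store_stride: int = 1,
) -> SfmResult:
    """Run online inference with the interleaved assignment process."""
    rng = np.random.default_rng(seed)
    from .stimuli import sample_stream

    if T is not None:
        from dataclasses import replace as _rep

        protocol = _rep(protocol, duration=T)
    stream = sample_stream(protocol, 1, rng)
    v_all = stream.v[0]                                   # (T, K, D)
    tree, cfg = protocol.tree, protocol.config
    ws = _Workspace(tree, cfg)
    M, S = ws.M, ws.S
    lam_sq = np.full(M, float(np.atleast_1d(cfg.lambda_init)[0]) ** 2)
    mu = np.zeros(S)
    rot_cols = np.where(
        [tree.components[m].kind == KIND_ROT_VERTICAL
         for m in tree.comp_of_col]
    )[0]
    rot_labels = [tree.components[tree.comp_of_col[c]].label
                  for c in rot_cols]
    n_frames = v_all.shape[0]
    idx = np.arange(0, n_frames, store_stride)
    mu_rot = np.empty((idx.size, rot_cols.size))
    lam_traj = np.empty((idx.size, M))
    n_rf = len(scene.rf_groups)
    assign_traj = np.empty((idx.size, n_rf), dtype=np.int16)
    perm_idx = [0] * n_rf
    obs_var = stream.obs_var_at(0)
    j = 0
    for i in range(n_frames):
        v_pred = tree.compose(mu)
        perm_idx = assignment_step(
            scene, v_pred, v_all[i], perm_idx, p_keep, rng
        )
        if j < idx.size and i == idx[j]:
            mu_rot[j] = mu[rot_cols]
            lam_traj[j] = lam_sq
            assign_traj[j] = perm_idx
            j += 1
        v = apply_assignment(scene, v_all[i], perm_idx)
        lam_sq, mu = _rk4_frame(lam_sq, mu, v, obs_var, ws, cfg.n_substeps)
    return SfmResult(
        times=stream.times[idx], mu_rot=mu_rot, rot_labels=rot_labels,
        lambda_sq=lam_traj, tree=tree, assignments=assign_traj,
    )


@dataclass
class SwitchStatistics:
    """Perceptual-switch statistics of a rotational-source trace."""

    threshold: float
    switch_times: np.ndarray
    durations: np.ndarray
    gamma_shape: float
    gamma_scale: float
    ks_pvalue: float

    @property
    def n_switches(self) -> int:
        return self.switch_times.size


def switch_statistics(
    mu_rot: np.ndarray,
    times: np.ndarray,
    min_switches: int = 10,
) -> SwitchStatistics:
    """Detect perceptual switches and fit a Gamma law to percept durations.

    The perceptual threshold is the histogram mode of ``|mu_rot|``
    (Freedman-Diaconis binning); a switch to the positive (negative)
    percept occurs when the trace crosses ``+threshold`` (``-threshold``),
    giving hysteresis around zero.  Durations between switches are fitted
    by maximum-likelihood Gamma (location fixed at 0) and checked with a
    Kolmogorov-Smirnov test.
    """
    x = np.asarray(mu_rot, dtype=float).ravel()
    counts, edges = np.histogram(np.abs(x), bins="fd")
    imax = int(np.argmax(counts))
    threshold = 0.5 * (edges[imax] + edges[imax + 1])
    state = np.where(x >= threshold, 1, np.where(x <= -threshold, -1, 0))
    nz = np.flatnonzero(state)
    if nz.size == 0:
        raise ValueError("trace never crosses the perceptual threshold")
    seq = state[nz]
    change = np.flatnonzero(np.diff(seq) != 0) + 1
    switch_idx = nz[change]
    switch_times = times[switch_idx]
    durations = np.diff(switch_times)
    if durations.size < min_switches:
        raise ValueError(
            f"only {durations.size} percept durations; need at least "
            f"{min_switches} for a Gamma fit"
        )
    try:
        shape, _loc, scale = stats.gamma.fit(durations, floc=0.0)
    except (ValueError, RuntimeError):
        # ML fit degenerates for near-constant durations; fall back to
        # method of moments with a capped shape
        mean, var = durations.mean(), durations.var()
        var = max(var, 1e-12 * mean**2)
        shape = min(mean**2 / var, 1e6)
        scale = mean / shape
    ks = stats.kstest(durations, "gamma", args=(shape, 0.0, scale))
    return SwitchStatistics(
        threshold=float(threshold), switch_times=switch_times,
        durations=durations, gamma_shape=float(shape),
        gamma_scale=float(scale), ks_pvalue=float(ks.pvalue),
    )


def percept_speed_cv(
    mu_rot: np.ndarray,
    times: np.ndarray,
    stats_: SwitchStatistics,
    guard: float = 0.5,
) -> float:
    """Coefficient of variation of ``|mu_rot|`` inside percepts.

    Samples within ``guard`` seconds of a switch are excluded; a small CV
    indicates a roughly constant perceived angular speed between switches.
    """
    x = np.abs(np.asarray(mu_rot, dtype=float).ravel())
    mask = np.ones_like(x, dtype=bool)
    for t_sw in stats_.switch_times:
        mask &= np.abs(times - t_sw) > guard
    mask &= x > 0.25 * stats_.threshold
    vals = x[mask]
    return float(vals.std() / vals.mean())
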