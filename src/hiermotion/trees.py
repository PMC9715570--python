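"""Motion trees and component matrices.

A motion tree describes how ``K`` observable velocities are composed from
``M`` latent motion sources: each observable is the sum of all its ancestral
sources in the tree.  The composition is linear and is therefore fully
captured by a component matrix ``C`` whose columns correspond to motion
components and whose rows correspond to observable inputs.

Translational components (including self-motion) act independently and
identically on every spatial dimension, with entries in {-1, 0, +1}.
Polar components exploit fixed input locations (location-indexed scenes):

* vertical-axis rotation: an angular-velocity source ``s_rot`` produces
  ``v_x = -R_k sin(phi_k) * s_rot`` and ``v_y = 0`` at an input with polar
  coordinates ``(R_k, phi_k)`` (the z-component is unobserved in a frontal
  view);
* fovea-centered radial/rotational motion: a pair of sources ``(s_r, s_phi)``
  produces ``v_x = s_r cos(theta_k) - s_phi R_k sin(theta_k)`` and
  ``v_y = s_r sin(theta_k) + s_phi R_k cos(theta_k)``.

Internally every component is expanded into one or more *source columns*
(translational: one per spatial dimension; fovea polar: two; vertical-axis
rotation: one) and stored in a dense tensor ``C_tensor[k, d, s]`` so that the
noise-free velocities are ``v[k, d] = sum_s C_tensor[k, d, s] * mu[s]``.
A component's motion strength ``lambda_m`` is shared across its columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KIND_SELF = "self_motion"
KIND_TRANS = "translational"
KIND_ROT_VERTICAL = "polar_rotation_vertical_axis"
KIND_FOVEA = "polar_fovea"

_KNOWN_KINDS = (KIND_SELF, KIND_TRANS, KIND_ROT_VERTICAL, KIND_FOVEA)


@dataclass
class ComponentSpec:
    """One motion component (one column group of ``C``).

    Parameters
    ----------
    label
        Human-readable name ("shared", "ind_1", ...).
    kind
        One of ``self_motion``, ``translational``,
        ``polar_rotation_vertical_axis``, ``polar_fovea``.
    sign_map
        Length-``K`` coefficients.  For translational/self components these
        are the +1/-1/0 entries of the component matrix.  For polar kinds a
        0/1 mask of which inputs the component drives; the actual (real)
        coefficients are derived from the tree's input geometry.
    prior_nu, prior_kappa_sq
        Hyper-parameters of the scaled-inverse-chi-squared prior on
        ``lambda^2``: ``nu`` pseudo-observations of value ``kappa^2``.
        The Jeffreys prior ``nu = kappa^2 = 0`` is the sparsity-promoting
        default; a uniform prior over ``lambda`` is obtained with
        ``nu = -2/D``.
    """

    label: str
    kind: str
    sign_map: np.ndarray
    prior_nu: float = 0.0
    prior_kappa_sq: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KNOWN_KINDS:
            raise ValueError(f"unknown component kind: {self.kind!r}")
        self.sign_map = np.asarray(self.sign_map, dtype=float)
        if not np.all(np.isfinite(self.sign_map)):
            raise ValueError("sign_map must be finite")
        if self.kind in (KIND_SELF, KIND_TRANS):
            if not np.all(np.isin(self.sign_map, (-1.0, 0.0, 1.0))):
                raise ValueError(
                    "translational coefficients must be -1, 0 or +1"
                )


@dataclass
class MotionTree:
    """A reservoir of motion components over ``K`` inputs in ``D`` dimensions.

    ``input_radius`` / ``input_angle`` give per-input polar coordinates
    ``(R_k, phi_k)`` (vertical-axis rotation) or ``(R_k, theta_k)``
    (fovea-centered polar motion); they are required only when the tree
    contains polar components.  ``vestibular_index`` marks the input carrying
    the vestibular self-motion signal, if any.
    """

    components: list[ComponentSpec]
    n_inputs: int
    n_dims: int = 2
    input_radius: np.ndarray | None = None
    input_angle: np.ndarray | None = None
    vestibular_index: int | None = None

    def __post_init__(self) -> None:
        for comp in self.components:
            if comp.sign_map.shape != (self.n_inputs,):
                raise ValueError(
                    f"component {comp.label!r}: sign_map length "
                    f"{comp.sign_map.size} != K={self.n_inputs}"
                )
        if self.input_radius is not None:
            self.input_radius = np.asarray(self.input_radius, dtype=float)
        if self.input_angle is not None:
            self.input_angle = np.asarray(self.input_angle, dtype=float)
        self._build()

    # -- derived structure -------------------------------------------------
    def _build(self) -> None:
        K, D = self.n_inputs, self.n_dims
        cols: list[np.ndarray] = []      # each (K, D)
        comp_of_col: list[int] = []
        for m, comp in enumerate(self.components):
            for col in polar_columns(self, comp) if comp.kind in (
                KIND_ROT_VERTICAL, KIND_FOVEA
            ) else _translational_columns(comp, D):
                cols.append(col)
                comp_of_col.append(m)
        if not cols:
            raise ValueError("tree has no components")
        self.C_tensor = np.stack(cols, axis=-1)            # (K, D, S)
        self.comp_of_col = np.asarray(comp_of_col)          # (S,)
        self.col_norm_sq = np.einsum("kds->s", self.C_tensor**2)
        if np.any(self.col_norm_sq <= 0):
            dead = [self.components[m].label
                    for m in self.comp_of_col[self.col_norm_sq <= 0]]
            raise ValueError(f"dead component column(s): {dead}")
        driven = np.einsum("kds->k", self.C_tensor**2)
        if np.any(driven <= 0):
            raise ValueError("every observable input must be driven by "
                             ">=1 component")
        self.self_mask = np.array(
            [self.components[m].kind == KIND_SELF for m in self.comp_of_col]
        )

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_cols(self) -> int:
        return self.C_tensor.shape[2]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    @property
    def prior_nu(self) -> np.ndarray:
        return np.array([c.prior_nu for c in self.components])

    @property
    def prior_kappa_sq(self) -> np.ndarray:
        return np.array([c.prior_kappa_sq for c in self.components])

    def compose(self, mu: np.ndarray) -> np.ndarray:
        """Noise-free velocities ``v[..., k, d]`` from sources ``mu[..., s]``."""
        return np.einsum("kds,...s->...kd", self.C_tensor, mu)

    def expand_lambda(self, lam: np.ndarray) -> np.ndarray:
        """Broadcast per-component values ``lam[..., m]`` to source columns."""
        return np.asarray(lam)[..., self.comp_of_col]


def _translational_columns(comp: ComponentSpec, D: int) -> list[np.ndarray]:
    K = comp.sign_map.size
    out = []
    for d in range(D):
        col = np.zeros((K, D))
        col[:, d] = comp.sign_map
        out.append(col)
    return out


def polar_columns(tree: MotionTree, comp: ComponentSpec) -> list[np.ndarray]:
    """Geometry-derived column(s) of ``C`` for a polar component.

    Returns a list of ``(K, D)`` arrays, one per source column.
    """
    if tree.input_radius is None or tree.input_angle is None:
        raise ValueError(
            f"polar component {comp.label!r} requires input geometry"
        )
    if tree.n_dims != 2:
        raise ValueError("polar components require D = 2")
    K = tree.n_inputs
    R, ang = tree.input_radius, tree.input_angle
    mask = (comp.sign_map != 0).astype(float)
    if comp.kind == KIND_ROT_VERTICAL:
        col = np.zeros((K, 2))
        col[:, 0] = -R * np.sin(ang) * mask    # v_x = -R sin(phi) s_rot
        return [col]                            # v_y = 0, z unobserved
    if comp.kind == KIND_FOVEA:
        col_r = np.zeros((K, 2))
        col_r[:, 0] = np.cos(ang) * mask
        col_r[:, 1] = np.sin(ang) * mask
        col_phi = np.zeros((K, 2))
        col_phi[:, 0] = -R * np.sin(ang) * mask
        col_phi[:, 1] = R * np.cos(ang) * mask
        return [col_r, col_phi]
    raise ValueError(f"not a polar component kind: {comp.kind!r}")


def build_component_matrix(tree: MotionTree) -> np.ndarray:
    """Return the per-dimension component matrix.

    For trees with only translational components this is the classic
    ``K x M`` matrix of +1/-1/0 entries (identical for every spatial
    dimension).  For trees containing polar components the joint action on
    (x, y) cannot be summarized per dimension; use ``tree.C_tensor``
    (shape ``K x D x S``) instead, and this function raises.
    """
    if any(c.kind in (KIND_ROT_VERTICAL, KIND_FOVEA) for c in tree.components):
        raise ValueError(
            "tree has polar components; use tree.C_tensor for the joint map"
        )
    return np.stack([c.sign_map for c in tree.components], axis=1)


# -- convenience constructors ----------------------------------------------

def shared_individual_tree(
    n_dots: int,
    n_dims: int = 2,
    shared: bool = True,
    self_motion: bool = False,
    vestibular_index: int | None = None,
    nu_self: float | None = None,
) -> MotionTree:
    """Flat tree: optional self-motion, one shared, one individual per dot."""
    n_inputs = n_dots + (1 if vestibular_index is not None else 0)
    comps = []
    if self_motion:
        sm = -np.ones(n_inputs)
        if vestibular_index is not None:
            sm[vestibular_index] = +1.0
        if nu_self is None:
            nu_self = -2.0 / n_dims
        comps.append(ComponentSpec("self", KIND_SELF, sm, prior_nu=nu_self))
    visual = np.ones(n_inputs)
    if vestibular_index is not None:
        visual[vestibular_index] = 0.0
    if shared:
        comps.append(ComponentSpec("shared", KIND_TRANS, visual.copy()))
    for k in range(n_inputs):
        if k == vestibular_index:
            continue
        e = np.zeros(n_inputs)
        e[k] = 1.0
        comps.append(ComponentSpec(f"ind_{k}", KIND_TRANS, e))
    return MotionTree(comps, n_inputs=n_inputs, n_dims=n_dims,
                      vestibular_index=vestibular_index)
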