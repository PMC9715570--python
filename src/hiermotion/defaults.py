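"""Default simulation parameters.

Three parameter sets are distinguished by how observed velocities are bound
to the world: *object-indexed* (velocities belong to objects, e.g. dots on a
screen), *location-indexed* (velocities sit at fixed spatial locations /
receptive fields, with a vestibular channel and a self-motion component),
and *network* (the rate-network realization, which runs at a higher frame
rate and low-passes the prediction error).
"""

from __future__ import annotations

from typing import Any

OBJECT_INDEXED: dict[str, Any] = {
    "tau_s": 0.300,        # s, source time constant
    "tau_lambda": 1.000,   # s, strength time constant
    "dt": 1.0 / 60.0,      # s, inverse frame rate
    "sigma_obs": 0.05,     # observation noise scale
    "lambda_init": 0.5,    # initial motion strength
    "nu": 0.0,             # pseudo-observation count (Jeffreys prior)
    "kappa_sq": 0.0,       # pseudo-observation value
}

LOCATION_INDEXED: dict[str, Any] = {
    **OBJECT_INDEXED,
    "tau_s": 0.100,
    "tau_lambda": 0.333,
    "sigma_obs": 0.05 / 3.0,   # = 0.017 (rounded in print)
    "nu_self": -1.0,           # uniform prior on self-motion (D = 2)
    "v_vst": 0.0,              # vestibular mean
    "sigma_vst": 0.05,         # vestibular noise scale
}

NETWORK: dict[str, Any] = {
    **LOCATION_INDEXED,
    "dt": 1.0 / 120.0,
    "tau_eps": 0.050,          # s, prediction-error low-pass
}

_MODES = {
    "object_indexed": OBJECT_INDEXED,
    "location_indexed": LOCATION_INDEXED,
    "network": NETWORK,
}


def load_defaults(mode: str) -> dict[str, Any]:
    """Return a copy of the default parameter set for ``mode``."""
    try:
        return dict(_MODES[mode])
    except KeyError:
        raise ValueError(
            f"unknown mode {mode!r}; expected one of {sorted(_MODES)}"
        ) from None
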