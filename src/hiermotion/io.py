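"""Serialization: trees as YAML, streams and trajectories as tidy CSV.

A result bundle written by :func:`run_experiment` contains the resolved
configuration, the tidy trajectory tables, and a manifest with content
hashes, so every output is regenerable from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .generative import ObservationStream
from .inference import OnlineMotionResults
from .trees import ComponentSpec, MotionTree


def tree_to_dict(tree: MotionTree) -> dict:
    d = {
        "n_inputs": tree.n_inputs,
        "n_dims": tree.n_dims,
        "vestibular_index": tree.vestibular_index,
        "components": [
            {
                "label": c.label,
                "kind": c.kind,
                "sign_map": np.asarray(c.sign_map).tolist(),
                "prior_nu": c.prior_nu,
                "prior_kappa_sq": c.prior_kappa_sq,
            }
            for c in tree.components
        ],
    }
    if tree.input_radius is not None:
        d["input_radius"] = tree.input_radius.tolist()
        d["input_angle"] = tree.input_angle.tolist()
    return d


def tree_from_dict(d: dict) -> MotionTree:
    comps = [
        ComponentSpec(
            label=c["label"], kind=c["kind"],
            sign_map=np.asarray(c["sign_map"], dtype=float),
            prior_nu=float(c.get("prior_nu", 0.0)),
            prior_kappa_sq=float(c.get("prior_kappa_sq", 0.0)),
        )
        for c in d["components"]
    ]
    return MotionTree(
        comps, n_inputs=int(d["n_inputs"]), n_dims=int(d["n_dims"]),
        input_radius=(np.asarray(d["input_radius"], dtype=float)
                      if "input_radius" in d else None),
        input_angle=(np.asarray(d["input_angle"], dtype=float)
                     if "input_angle" in d else None),
        vestibular_index=d.get("vestibular_index"),
    )


def save_tree(tree: MotionTree, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(tree_to_dict(tree)))


def load_tree(path: str | Path) -> MotionTree:
    return tree_from_dict(yaml.safe_load(Path(path).read_text()))


def stream_to_frame(stream: ObservationStream) -> pd.DataFrame:
    """Tidy table (t, input, dim, v, obs_var); single-trial streams only."""
    if stream.batch_shape:
        raise ValueError("tidy export supports unbatched streams")
    T, K, D = stream.v.shape
    t_idx, k_idx, d_idx = np.meshgrid(
        np.arange(T), np.arange(K), np.arange(D), indexing="ij"
    )
    ov = np.broadcast_to(stream.obs_var, (T, K)) \
        if stream.obs_var.ndim == 2 else np.tile(stream.obs_var, (T, 1))
    return pd.DataFrame({
        "t": stream.times[t_idx.ravel()],
        "input": k_idx.ravel(),
        "dim": d_idx.ravel(),
        "v": stream.v.ravel(),
        "obs_var": ov[t_idx.ravel(), k_idx.ravel()],
    })


def save_stream(stream: ObservationStream, path: str | Path) -> None:
    """Write a stream as tidy CSV, plus an ``.npz`` binary cache."""
    path = Path(path)
    stream_to_frame(stream).to_csv(path, index=False)
    np.savez_compressed(
        path.with_suffix(".npz"), v=stream.v, times=stream.times,
        obs_var=stream.obs_var, dt=stream.dt,
    )


def load_stream(path: str | Path) -> ObservationStream:
    path = Path(path)
    npz = path.with_suffix(".npz")
    if npz.exists():
        d = np.load(npz)
        return ObservationStream(v=d["v"], times=d["times"],
                                 obs_var=d["obs_var"], dt=float(d["dt"]))
    df = pd.read_csv(path)
    times = np.sort(df["t"].unique())
    K = int(df["input"].max()) + 1
    D = int(df["dim"].max()) + 1
    v = (df.sort_values(["t", "input", "dim"])["v"]
         .to_numpy().reshape(times.size, K, D))
    obs_var = (df[df["t"] == times[0]]
               .sort_values(["input", "dim"])
               .groupby("input")["obs_var"].first().to_numpy())
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0 / 60.0
    return ObservationStream(v=v, times=times, obs_var=obs_var, dt=dt)


def results_to_frame(res: OnlineMotionResults) -> pd.DataFrame:
    """Tidy long table of state trajectories (first batch element if batched)."""
    lam = res.lambda_sq
    mu = res.mu
    if lam.ndim > 2:
        lam = lam.reshape((-1,) + lam.shape[-2:])[0]
        mu = mu.reshape((-1,) + mu.shape[-2:])[0]
    rows = []
    labels = res.tree.labels
    for m, lab in enumerate(labels):
        rows.append(pd.DataFrame({
            "t": res.times, "variable": "lambda_sq", "component": lab,
            "dim": -1, "value": lam[:, m],
        }))
    col_labels = [labels[m] for m in res.tree.comp_of_col]
    for s, lab in enumerate(col_labels):
        rows.append(pd.DataFrame({
            "t": res.times, "variable": "mu", "component": lab,
            "dim": s, "value": mu[:, s],
        }))
    return pd.concat(rows, ignore_index=True)


def content_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Write resolved config + content hashes of every file in ``out_dir``."""
    out_dir = Path(out_dir)
    files = sorted(
        p for p in out_dir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config,
        "files": {str(p.relative_to(out_dir)): content_hash(p)
                  for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=str))
    return path
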