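"""Readers, writers, configuration, and run manifests.

All on-disk formats are plain text: delimited tables for areas, edges,
labels and summaries; YAML for configuration; a directory of columnar
tables plus a JSON metadata file for MCMC draw archives.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import AreaGraph, build_area_graph
from .mcmc import ChainConfig, PosteriorSamples
from .model import Dataset, ModelConfig
from .simulate import SimulationConfig
from .stick import StickConfig

__version__ = "0.1.0"


# ---------------------------------------------------------------- tables

def load_area_table(path) -> pd.DataFrame:
    """Area table: columns area_id, y, x1..xp, lon, lat (header required)."""
    df = pd.read_csv(path)
    required = {"area_id", "y", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    if not xcols:
        raise ValueError("area table has no covariate columns x1..xp")
    return df


def covariate_columns(df: pd.DataFrame) -> list:
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    return sorted(xcols, key=lambda c: int(c[1:]))


def load_edge_list(path) -> list:
    """Two-column delimited text of area-id pairs."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def load_dataset(area_path, edges_path, log_transform: bool = False) -> Dataset:
    df = load_area_table(area_path)
    graph = build_area_graph(df, load_edge_list(edges_path))
    xcols = covariate_columns(df)
    y = df["y"].to_numpy(float)
    X = df[xcols].to_numpy(float)
    if log_transform:
        if np.any(y <= 0) or np.any(X <= 0):
            raise ValueError("log transform requires strictly positive y and covariates")
        y, X = np.log(y), np.log(X)
    return Dataset(y=y, X=X, graph=graph)


def write_dataset(data: Dataset, out_dir, truth: dict | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = data.p
    df = pd.DataFrame({"area_id": data.graph.area_ids, "y": data.y})
    for j in range(p):
        df[f"x{j + 1}"] = data.X[:, j]
    df["lon"] = data.coords[:, 0]
    df["lat"] = data.coords[:, 1]
    areas_path = out_dir / "areas.csv"
    df.to_csv(areas_path, index=False)
    ids = data.graph.area_ids
    edges = pd.DataFrame(sorted(data.graph.edges), columns=["i", "j"])
    edges_df = pd.DataFrame({"from": [ids[i] for i in edges["i"]],
                             "to": [ids[j] for j in edges["j"]]})
    edges_path = out_dir / "edges.csv"
    edges_df.to_csv(edges_path, index=False)
    paths = {"areas": str(areas_path), "edges": str(edges_path)}
    if truth is not None:
        tdf = pd.DataFrame({"area_id": ids, "label": truth["labels"]})
        for j in range(truth["beta"].shape[1]):
            tdf[f"beta{j + 1}"] = truth["beta"][:, j]
        truth_path = out_dir / "truth_labels.csv"
        tdf.to_csv(truth_path, index=False)
        paths["truth"] = str(truth_path)
    return paths


def load_labels(path) -> np.ndarray:
    df = pd.read_csv(path)
    col = "label" if "label" in df.columns else df.columns[-1]
    return df[col].to_numpy(int)


# ---------------------------------------------------------------- GeoJSON

def load_geojson_areas(path):
    """Polygon input: derive centroids and queen contiguity with shapely.

    Returns ``(ids, centroids, edges)`` where two polygons are contiguous
    when their boundaries intersect (shared vertex or edge).
    """
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    geoms = [shape(f["geometry"]) for f in feats]
    ids = [f.get("properties", {}).get("area_id", f"f{i:04d}")
           for i, f in enumerate(feats)]
    centroids = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
    edges = set()
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].intersects(geoms[j]):
                edges.add((ids[i], ids[j]))
    return ids, centroids, sorted(edges)


# ---------------------------------------------------------------- config

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping")
    return cfg


def _require(section: dict, key: str, check, message: str):
    if key in section and not check(section[key]):
        raise ValueError(message)


def simulation_config_from(cfg: dict) -> SimulationConfig:
    sec = dict(cfg.get("simulation", {}))
    _require(sec, "phi", lambda v: v is not None and v > 0,
             "simulation.phi must be positive")
    kwargs = {}
    for src, dst in [("n", "n"), ("p", "p"), ("phi", "gp_range"),
                     ("noise_sd", "noise_sd"), ("layout_seed", "layout_seed")]:
        if src in sec:
            kwargs[dst] = sec[src]
    if "partition" in sec:
        kwargs["partition"] = tuple(sec["partition"])
    if "cluster_coeffs" in sec:
        kwargs["cluster_coeffs"] = np.asarray(sec["cluster_coeffs"], float)
    kwargs["seed"] = int(cfg.get("seed", 0))
    return SimulationConfig(**kwargs)


def stick_config_from(cfg: dict) -> StickConfig:
    sec = dict(cfg.get("kernel", {}))
    kwargs = {}
    for src, dst in [("kind", "kernel_kind"), ("lambda", "lam"),
                     ("bandwidth_prior", "bandwidth_prior"),
                     ("truncation_K", "truncation_K"), ("knots", "knots"),
                     ("beta_a", "beta_a"), ("beta_b", "beta_b")]:
        if src in sec:
            kwargs[dst] = sec[src]
    return StickConfig(**kwargs)


def model_config_from(cfg: dict, p: int) -> ModelConfig:
    sec = dict(cfg.get("model", {}))
    kwargs = {"p": p, "stick": stick_config_from(cfg)}
    for key in ["a_v", "b_v", "alpha1", "alpha2", "D", "likelihood_mode",
                "intercept", "distance_metric", "weight_threshold", "c"]:
        if key in sec:
            kwargs[key] = sec[key]
    if "m" in sec:
        kwargs["m"] = np.asarray(sec["m"], float)
    if "D_scale" in sec:
        kwargs["D_scale"] = np.asarray(sec["D_scale"], float)
    return ModelConfig(**kwargs)


def chain_config_from(cfg: dict) -> ChainConfig:
    sec = dict(cfg.get("chain", {}))
    kwargs = {k: sec[k] for k in ["n_iter", "burn_in", "thin", "adapt"] if k in sec}
    kwargs["seed"] = int(cfg.get("seed", 0))
    return ChainConfig(**kwargs)


# ---------------------------------------------------------------- archive

def save_samples(samples: PosteriorSamples, out_dir, extra_meta: dict | None = None):
    """Write a draw archive: one delimited table per parameter block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    M = samples.n_draws
    np.savetxt(out_dir / "z.csv", samples.z, fmt="%d", delimiter=",")
    for name in ["beta", "mu", "Sigma", "knots", "eps"]:
        arr = getattr(samples, name)
        np.savetxt(out_dir / f"{name}.csv", arr.reshape(M, -1),
                   fmt="%.10g", delimiter=",")
    for name in ["sigma2", "b", "V", "loglik"]:
        arr = getattr(samples, name)
        np.savetxt(out_dir / f"{name}.csv", np.atleast_2d(arr.T).T.reshape(M, -1),
                   fmt="%.10g", delimiter=",")
    meta = {
        "n_draws": M, "n_areas": samples.n_areas,
        "K": samples.beta.shape[1], "p": samples.beta.shape[2],
        "n_knots": samples.knots.shape[1],
        "seed": samples.seed, "likelihood_mode": samples.likelihood_mode,
        "acceptance": samples.acceptance,
    }
    meta.update(extra_meta or {})
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_samples(in_dir) -> PosteriorSamples:
    in_dir = Path(in_dir)
    try:
        meta = json.loads((in_dir / "meta.json").read_text())
        M, n = meta["n_draws"], meta["n_areas"]
        K, p, n_knots = meta["K"], meta["p"], meta["n_knots"]
        load = lambda name: np.loadtxt(in_dir / f"{name}.csv", delimiter=",", ndmin=2)
        return PosteriorSamples(
            z=load("z").astype(int),
            beta=load("beta").reshape(M, K, p),
            mu=load("mu").reshape(M, K, p),
            Sigma=load("Sigma").reshape(M, K, p, p),
            sigma2=load("sigma2").reshape(M, n),
            b=load("b").ravel(),
            V=load("V").reshape(M, K),
            knots=load("knots").reshape(M, n_knots, 2),
            eps=load("eps").reshape(M, n_knots, 2),
            loglik=load("loglik").reshape(M, n),
            acceptance=meta.get("acceptance", {}),
            seed=meta.get("seed"),
            likelihood_mode=meta.get("likelihood_mode", "composite"),
        )
    except (OSError, KeyError, ValueError) as err:
        raise ValueError(f"corrupt or incomplete draw archive at {in_dir}") from err


# ---------------------------------------------------------------- manifest

def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, *, config: dict, seed: int,
                   inputs: dict | None = None, outputs: dict | None = None,
                   acceptance: dict | None = None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sdpgwr", "version": __version__,
        "numpy": np.__version__,
        "seed": seed, "config": config,
        "input_digests": {k: file_digest(v) for k, v in (inputs or {}).items()},
        "outputs": outputs or {},
        "acceptance_rates": acceptance or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
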