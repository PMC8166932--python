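"""Plain-text import/export: geometry CSV, OBJ meshes, curve tables.

Geometry CSV dialect (one row per platelet)::

    id,w,t,l,dim_w,dim_t,dim_l,r00,r01,r02,r10,r11,r12,r20,r21,r22

with centroid coordinates (w, t, l) and full dimensions in nm and the
orientation matrix row-major.  Domain metadata travels in ``#``-comment
header lines so a file round-trips to an identical configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .configuration import Configuration
from .geometry import FibrilDomain
from .percolation import PercolationCurve
from .sweep import SweepConfig, SweepResult

__all__ = [
    "write_geometry_csv",
    "read_geometry_csv",
    "write_obj",
    "curve_to_frame",
    "write_curves_csv",
    "result_to_json",
    "load_sweep_config",
]

GEOMETRY_COLUMNS = (
    ["id", "w", "t", "l", "dim_w", "dim_t", "dim_l"]
    + [f"r{i}{j}" for i in range(3) for j in range(3)]
)


def write_geometry_csv(cfg: Configuration, path) -> None:
    path = Path(path)
    rows = []
    for i in range(cfg.n_platelets):
        rows.append(
            [i, *cfg.centroids[i], *(2.0 * cfg.half_dims[i]),
             *cfg.orientations[i].ravel()]
        )
    frame = pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)
    d = cfg.domain
    with path.open("w") as fh:
        fh.write(
            f"# diameter={d.diameter!r} length={d.length!r} "
            f"tolerance_factor={d.tolerance_factor!r} "
            f"achieved_vf={cfg.achieved_vf!r}\n"
        )
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_geometry_csv(path) -> Configuration:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, val = tok.split("=")
            meta[key] = float(val)
    frame = pd.read_csv(path, comment="#")
    n = len(frame)
    centroids = frame[["w", "t", "l"]].to_numpy()
    half_dims = 0.5 * frame[["dim_w", "dim_t", "dim_l"]].to_numpy()
    orients = frame[[f"r{i}{j}" for i in range(3) for j in range(3)]]
    orients = orients.to_numpy().reshape(n, 3, 3)
    domain = FibrilDomain(
        meta.get("diameter", 50.0),
        meta.get("length", 1000.0),
        meta.get("tolerance_factor", 1.05),
    )
    return Configuration(
        domain, centroids, half_dims, orients,
        achieved_vf=meta.get("achieved_vf", 0.0),
    )


_BOX_FACES = [
    (4, 6, 7, 5), (0, 1, 3, 2), (2, 3, 7, 6),
    (0, 4, 5, 1), (1, 5, 7, 3), (0, 2, 6, 4),
]


def write_obj(cfg: Configuration, path) -> None:
    """Triangle mesh of all platelet boxes (Wavefront OBJ)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# mcfperc platelet boxes\n")
        for i in range(cfg.n_platelets):
            verts = cfg.vertices(i)
            for v in verts:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            base = 8 * i + 1
            for a, b, c, d in _BOX_FACES:
                fh.write(f"f {base+a} {base+b} {base+c}\n")
                fh.write(f"f {base+a} {base+c} {base+d}\n")


def curve_to_frame(curve: PercolationCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vf": curve.vf_grid,
            "n_p": curve.n_p,
            "N": curve.N,
            "P": curve.P,
            "se": curve.se,
            "mode": curve.mode,
            "direction": curve.direction,
        }
    )


def write_curves_csv(result: SweepResult, path) -> None:
    frames = [curve_to_frame(c) for c in result.curves.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def result_to_json(result: SweepResult, path=None) -> dict:
    doc = {"config": result.config.manifest(), "fits": {}}
    doc["achieved_vf"] = [float(v) for v in result.achieved_vf]
    doc["n_platelets"] = [int(v) for v in result.n_platelets]
    for (mode, direction), curve in result.curves.items():
        fit = curve.fit
        doc["fits"][f"{mode}/{direction}"] = {
            "vf_c": fit.vf_c,
            "delta": fit.delta,
            "status": fit.status,
            "vf_c_empirical": fit.vf_c_empirical,
            "P": [float(p) for p in curve.P],
        }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def load_sweep_config(path) -> SweepConfig:
    """Build a SweepConfig from a YAML configuration file.

    Recognized keys: fibril.diameter_nm, fibril.length_nm,
    platelets.*_range_nm (consumed by DimensionRanges at call sites),
    vf.grid, mc.{n_realizations,equil_cycles,thinning,tau0_nm,theta0_deg},
    connectivity.{delta_nm,include_overlapping_in_shell}, seeds.master.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fibril = raw.get("fibril", {})
    vf = raw.get("vf", {})
    mc = raw.get("mc", {})
    conn = raw.get("connectivity", {})
    seeds = raw.get("seeds", {})
    kwargs = {}
    if "diameter_nm" in fibril:
        kwargs["diameter"] = float(fibril["diameter_nm"])
    if "length_nm" in fibril:
        kwargs["length"] = float(fibril["length_nm"])
    if "grid" in vf:
        kwargs["vf_grid"] = tuple(float(v) for v in vf["grid"])
    for src, dst in (
        ("n_realizations", "n_realizations"),
        ("equil_cycles", "equil_cycles"),
        ("thinning", "thinning"),
    ):
        if src in mc:
            kwargs[dst] = int(mc[src])
    if "tau0_nm" in mc:
        kwargs["tau0"] = float(mc["tau0_nm"])
    if "theta0_deg" in mc:
        kwargs["theta0"] = float(mc["theta0_deg"])
    if "delta_nm" in conn:
        kwargs["delta"] = float(conn["delta_nm"])
    if "include_overlapping_in_shell" in conn:
        kwargs["include_overlapping_in_shell"] = bool(
            conn["include_overlapping_in_shell"]
        )
    if "master" in seeds:
        kwargs["seed"] = int(seeds["master"])
    return SweepConfig(**kwargs)
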