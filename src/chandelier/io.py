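"""Readers and writers for the pipeline's file interfaces.

All tables are plain CSV; skeletons are standard 7-column SWC (nm); edge
lists and fitted summaries are JSON. AIS domains round-trip through a long
CSV (one row per node).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ais import AISDomain
from .skeleton import SkeletonGraph, read_swc, write_swc

__all__ = [
    "write_ais_domains",
    "read_ais_domains",
    "write_axons_swc",
    "read_axons_swc",
    "write_network",
    "read_network",
]


def write_ais_domains(ais_domains, path) -> None:
    rows = []
    for a in ais_domains:
        for i in range(len(a)):
            rows.append(
                {
                    "cell_id": a.cell_id,
                    "node": i,
                    "x": a.positions[i, 0],
                    "y": a.positions[i, 1],
                    "z": a.positions[i, 2],
                    "radius": a.radii[i],
                    "arclength": a.arclength[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ais_domains(path) -> list[AISDomain]:
    df = pd.read_csv(path)
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("node")
        pos = grp[["x", "y", "z"]].to_numpy(float)
        out.append(
            AISDomain(
                cell_id=cell_id,
                positions=pos,
                radii=grp["radius"].to_numpy(float),
                arclength=grp["arclength"].to_numpy(float),
                top=pos[0],
                bottom=pos[-1],
            )
        )
    return out


def write_axons_swc(axons: dict, outdir) -> list[Path]:
    """One SWC file per axon point cloud (chained nodes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for aid, pts in axons.items():
        pts = np.atleast_2d(pts)
        p = outdir / f"axon_{aid}.swc"
        with open(p, "w") as fh:
            fh.write("# id type x y z radius parent (nm)\n")
            for i, (x, y, z) in enumerate(pts):
                parent = i if i > 0 else -1  # SWC ids are 1-based
                fh.write(f"{i + 1} 2 {x:.3f} {y:.3f} {z:.3f} 100.000 {parent}\n")
        paths.append(p)
    return paths


def read_axons_swc(indir) -> dict:
    """Read axon_*.swc files back into id -> (n, 3) nm point clouds."""
    axons = {}
    for p in sorted(Path(indir).glob("axon_*.swc")):
        aid = int(p.stem.split("_")[1])
        skel = read_swc(p)
        axons[aid] = skel.positions
    if not axons:
        raise FileNotFoundError(f"no axon_*.swc files under {indir}")
    return axons


def write_network(network: dict, path) -> None:
    payload = {
        "potential": [[a, c] for a, c in network["potential"]],
        "actual": [[a, c] for a, c in network["actual"]],
    }
    if "volume_bounds" in network:
        payload["volume_bounds"] = [list(b) for b in network["volume_bounds"]]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_network(path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    out = {
        "potential": [tuple(e) for e in data["potential"]],
        "actual": [tuple(e) for e in data["actual"]],
    }
    if "volume_bounds" in data:
        out["volume_bounds"] = tuple(tuple(b) for b in data["volume_bounds"])
    return out
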