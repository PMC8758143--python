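"""Potential connectivity and the multiplicative input decomposition.

A potential connection is an axon/AIS pair whose point clouds approach
within a distance threshold (default 7.5 um; results in the source study are
stable for 5-10 um). Per-cell synaptic input then factors as

    N_syn = mu_con * N_con,      N_con = N_pot * f_con

separating the local abundance of axons (N_pot) from the propensity of
nearby axons to actually connect (f_con) and the size of each connection
(mu_con).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ais import NM_PER_UM, AISDomain

__all__ = [
    "PotentialMatrix",
    "potential_connections",
    "boundary_exclusion",
    "decompose",
]


@dataclass
class PotentialMatrix:
    """Binary potential-edge structure between axons and cells."""

    axon_ids: list
    cell_ids: list
    matrix: np.ndarray  # (n_axons, n_cells) bool
    threshold: float  # um

    def edges(self) -> set[tuple]:
        ii, jj = np.nonzero(self.matrix)
        return {(self.axon_ids[i], self.cell_ids[j]) for i, j in zip(ii, jj)}

    def n_pot(self) -> pd.Series:
        """Potential in-degree per cell."""
        return pd.Series(self.matrix.sum(axis=0), index=self.cell_ids, name="n_pot")


def potential_connections(
    axon_points: dict, ais_domains: list[AISDomain], threshold: float = 7.5
) -> PotentialMatrix:
    """Potential edges by minimum point-cloud distance.

    An edge (axon, cell) is present iff the minimum Euclidean distance
    between any axon point and any node of the cell's AIS is <= ``threshold``
    (um). Axon points are nm. Accelerated with a k-d tree per AIS; the
    definition (and the test oracle) is the all-pairs brute-force scan.
    """
    if not axon_points:
        raise ValueError("empty axon set")
    if not ais_domains:
        raise ValueError("empty AIS set")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    r_nm = threshold * NM_PER_UM
    axon_ids = list(axon_points)
    cell_ids = [a.cell_id for a in ais_domains]
    mat = np.zeros((len(axon_ids), len(cell_ids)), dtype=bool)
    trees = [cKDTree(a.positions) for a in ais_domains]
    for i, aid in enumerate(axon_ids):
        pts = np.atleast_2d(np.asarray(axon_points[aid], float))
        for j, tree in enumerate(trees):
            d, _ = tree.query(pts, k=1, distance_upper_bound=r_nm * 1.001)
            if np.any(d <= r_nm):
                mat[i, j] = True
    return PotentialMatrix(axon_ids, cell_ids, mat, threshold)


def boundary_exclusion(
    ais_domains: list[AISDomain],
    volume_bounds,
    threshold: float = 7.5,
    sample_spacing: float = 0.25,
    max_outside_fraction: float = 0.10,
) -> list:
    """Cells whose threshold tube stays (mostly) inside the volume.

    For each AIS, a regular grid of points at ``sample_spacing`` (um) is
    laid over the axis-aligned box around the AIS expanded by ``threshold``;
    points within ``threshold`` of any AIS node form the sample of the
    tube. If more than ``max_outside_fraction`` of those samples fall
    outside ``volume_bounds`` (3 axis-aligned (lo, hi) intervals, um), the
    cell is excluded. Returns the kept cell ids.
    """
    if sample_spacing >= threshold:
        raise ValueError("sample spacing must be smaller than the threshold")
    bounds = np.asarray(volume_bounds, float)
    if bounds.shape != (3, 2) or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("volume_bounds must be three (lo, hi) intervals")
    r_nm = threshold * NM_PER_UM
    step_nm = sample_spacing * NM_PER_UM
    kept = []
    for ais in ais_domains:
        tree = cKDTree(ais.positions)
        lo = ais.positions.min(axis=0) - r_nm
        hi = ais.positions.max(axis=0) + r_nm
        axes = [np.arange(lo[k], hi[k] + step_nm / 2, step_nm) for k in range(3)]
        outside = 0
        total = 0
        # sweep x-slabs to bound memory on long AISes
        yz = np.array(np.meshgrid(axes[1], axes[2], indexing="ij")).reshape(2, -1).T
        for x in axes[0]:
            pts = np.column_stack([np.full(len(yz), x), yz])
            d, _ = tree.query(pts, k=1, distance_upper_bound=r_nm * 1.001)
            in_tube = d <= r_nm
            if not in_tube.any():
                continue
            p = pts[in_tube] / NM_PER_UM
            total += len(p)
            out = np.any((p < bounds[:, 0]) | (p > bounds[:, 1]), axis=1)
            outside += int(out.sum())
        if total and outside / total <= max_outside_fraction:
            kept.append(ais.cell_id)
    return kept


def decompose(
    connections: pd.DataFrame, potential: PotentialMatrix
) -> pd.DataFrame:
    """Per-cell decomposition N_syn = mu_con * N_con, N_con = N_pot * f_con.

    Parameters
    ----------
    connections : DataFrame with columns ``axon_id``, ``cell_id``,
        ``n_synapses`` — one row per (axon, cell) connection.
    potential : the potential matrix supplying N_pot per cell.

    Returns
    -------
    DataFrame indexed by cell id with columns n_syn, n_con, mu_con, n_pot,
    f_con and boolean flags mu_con_undefined (N_con = 0) and
    f_con_undefined (N_pot = 0). Actual connections absent from the
    potential matrix raise an inconsistency error.
    """
    req = {"axon_id", "cell_id", "n_synapses"}
    if not req.issubset(connections.columns):
        raise ValueError(f"connections must have columns {sorted(req)}")
    if connections.duplicated(["axon_id", "cell_id"]).any():
        raise ValueError("duplicate (axon, cell) connection rows")
    pot_edges = potential.edges()
    actual = set(
        zip(connections["axon_id"].tolist(), connections["cell_id"].tolist())
    )
    missing = actual - pot_edges
    if missing:
        raise ValueError(
            f"{len(missing)} actual connection(s) absent from the potential "
            f"matrix, e.g. {sorted(missing)[:3]}"
        )
    n_pot = potential.n_pot()
    grouped = connections.groupby("cell_id")["n_synapses"]
    n_syn = grouped.sum().reindex(n_pot.index, fill_value=0)
    n_con = grouped.size().reindex(n_pot.index, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_con = n_syn / n_con
        f_con = n_con / n_pot
    out = pd.DataFrame(
        {
            "n_syn": n_syn.astype(int),
            "n_con": n_con.astype(int),
            "mu_con": mu_con,
            "n_pot": n_pot.astype(int),
            "f_con": f_con.where(n_pot > 0, 0.0),
            "mu_con_undefined": n_con == 0,
            "f_con_undefined": n_pot == 0,
        }
    )
    out.index.name = "cell_id"
    return out
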