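"""Connection-size distribution and cisternal-organelle proximity.

Connection sizes (synapses per axon/AIS connection, support {1, 2, ...})
are fit with a support-1 geometric distribution whose MLE is p = 1/mean.
Cisternal organelles (COs) are located by density-based clustering of
annotation points in (depth, orientation) coordinates, and chandelier
synapse/CO proximity is tested against a depth-matched spatial shuffle.

Distances on the AIS surface use cylinder coordinates: with r the AIS mean
radius (um),

    d = sqrt(d_depth^2 + (r * d_theta_wrapped)^2)

which approximates the mesh-surface geodesic on a near-cylindrical AIS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

__all__ = [
    "GeometricFit",
    "COCluster",
    "fit_connection_size",
    "shifted_poisson_fit",
    "cylinder_distance",
    "cluster_co_points",
    "co_proximity_test",
    "census_summary",
    "ais_input_summary",
]


@dataclass
class GeometricFit:
    """Support-1 geometric fit to connection sizes."""

    p: float
    implied_mean: float  # 1/p
    n: int
    log_likelihood: float
    gof_statistic: float  # chi-square with expected-count pooling
    gof_pvalue: float
    gof_dof: int


@dataclass
class COCluster:
    """A cisternal-organelle location on one AIS."""

    ais_id: object
    depth: float  # um
    orientation: float  # radians
    n_points: int


def fit_connection_size(sizes) -> GeometricFit:
    """MLE geometric fit: p = 1/mean for counts on support {1, 2, ...}.

    Goodness of fit is a chi-square on the observed size histogram with
    tail bins pooled so every expected count is >= 5.
    """
    sizes = np.asarray(sizes, int)
    if sizes.size == 0:
        raise ValueError("empty size sample")
    if np.any(sizes < 1):
        raise ValueError("connection sizes must be >= 1")
    mean = sizes.mean()
    p = 1.0 / mean
    n = sizes.size
    ll = float(np.sum(np.log(p) + (sizes - 1) * np.log1p(-p))) if p < 1 else 0.0
    # chi-square GOF with pooling at expected < 5
    kmax = sizes.max()
    ks = np.arange(1, kmax + 1)
    probs = p * (1 - p) ** (ks - 1)
    probs = np.append(probs, 1 - probs.sum())  # tail > kmax
    obs = np.append(np.bincount(sizes, minlength=kmax + 1)[1:], 0)
    exp = n * probs
    # pool from the right until every expected count >= 5
    o_pool, e_pool = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            o_pool.append(acc_o)
            e_pool.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and e_pool:
        o_pool[-1] += acc_o
        e_pool[-1] += acc_e
    if len(e_pool) >= 2:
        e_arr = np.array(e_pool) * (np.sum(o_pool) / np.sum(e_pool))
        dof = len(e_pool) - 2  # one estimated parameter
        chi2 = float(np.sum((np.array(o_pool) - e_arr) ** 2 / e_arr))
        pval = float(stats.chi2.sf(chi2, max(dof, 1)))
    else:
        chi2, pval, dof = 0.0, 1.0, 0
    return GeometricFit(
        p=float(p),
        implied_mean=float(mean),
        n=int(n),
        log_likelihood=ll,
        gof_statistic=chi2,
        gof_pvalue=pval,
        gof_dof=dof,
    )


def shifted_poisson_fit(sizes) -> dict:
    """Alternative fit: 1 + Poisson(lam), MLE lam = mean - 1."""
    sizes = np.asarray(sizes, int)
    if np.any(sizes < 1):
        raise ValueError("connection sizes must be >= 1")
    lam = float(sizes.mean() - 1)
    ll = float(np.sum(stats.poisson.logpmf(sizes - 1, lam))) if lam > 0 else 0.0
    return {"lam": lam, "implied_mean": lam + 1, "log_likelihood": ll}


def cylinder_distance(coords_a, coords_b, radius: float) -> np.ndarray:
    """Pairwise surface distance between (depth, orientation) coordinates.

    ``coords_*`` are (n, 2) arrays of (depth um, orientation rad); angular
    differences are wrapped to [-pi, pi] and scaled by ``radius`` (um).
    """
    a = np.atleast_2d(np.asarray(coords_a, float))
    b = np.atleast_2d(np.asarray(coords_b, float))
    dd = a[:, None, 0] - b[None, :, 0]
    dth = a[:, None, 1] - b[None, :, 1]
    dth = np.angle(np.exp(1j * dth))  # wrap
    return np.sqrt(dd**2 + (radius * dth) ** 2)


def cluster_co_points(
    points: pd.DataFrame,
    eps: float = 1.0,
    min_pts: int = 3,
    radius_by_ais: dict | None = None,
    default_radius: float = 0.5,
) -> list[COCluster]:
    """DBSCAN clustering of CO annotation points per AIS.

    ``points`` needs columns ``ais_id``, ``depth``, ``orientation``.
    Distances use the cylindrical metric with the AIS's mean radius (um).
    Noise points are discarded; clusters below ``min_pts`` members never
    form by construction of DBSCAN.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    out = []
    for ais_id, grp in points.groupby("ais_id"):
        r = (radius_by_ais or {}).get(ais_id, default_radius)
        coords = grp[["depth", "orientation"]].to_numpy(float)
        d = cylinder_distance(coords, coords, r)
        labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(
            d
        ).labels_
        for lab in sorted(set(labels) - {-1}):
            members = coords[labels == lab]
            mean_depth = float(members[:, 0].mean())
            mean_theta = float(np.angle(np.mean(np.exp(1j * members[:, 1]))))
            out.append(COCluster(ais_id, mean_depth, mean_theta, int(len(members))))
    return out


def co_proximity_test(
    synapse_coords: pd.DataFrame,
    co_clusters: list[COCluster],
    candidates: dict,
    n_shuffles: int = 1000,
    depth_tolerance: float = 0.2,
    seed: int = 0,
    radius_by_ais: dict | None = None,
    default_radius: float = 0.5,
    max_retries: int = 10,
    mode: str = "between",
) -> dict:
    """Are ChC synapses closer to COs than a spatial shuffle predicts?

    Statistic: mean over synapses of the cylindrical distance to the
    nearest same-AIS CO cluster. The null reassigns each synapse, per
    shuffle, to a location on a random AIS drawn from ``candidates``
    (ais_id -> (m, 2) array of (depth, orientation) positions): among
    candidates within ``depth_tolerance`` um of the synapse's depth the one
    nearest in orientation is taken. If the drawn AIS has no depth-matched
    candidate another AIS is drawn (up to ``max_retries``), else the
    synapse is dropped from that shuffle (counted in the report). With
    ``mode="within"`` the shuffle stays on the synapse's own AIS.

    p = fraction of null means <= observed.
    """
    if not co_clusters:
        raise ValueError("need at least one CO cluster")
    if len(synapse_coords) == 0:
        raise ValueError("need at least one synapse")
    clusters_by_ais: dict = {}
    for c in co_clusters:
        clusters_by_ais.setdefault(c.ais_id, []).append(c)
    ais_with_cos = sorted(clusters_by_ais, key=str)

    def radius_of(ais_id):
        return (radius_by_ais or {}).get(ais_id, default_radius)

    def dist_to_cos(ais_id, depth, theta):
        cos = clusters_by_ais.get(ais_id)
        if not cos:
            return np.nan
        pts = np.array([[c.depth, c.orientation] for c in cos])
        return float(
            cylinder_distance([[depth, theta]], pts, radius_of(ais_id)).min()
        )

    syn = synapse_coords[synapse_coords["ais_id"].isin(clusters_by_ais)]
    obs_d = [
        dist_to_cos(r.ais_id, r.depth, r.orientation)
        for r in syn.itertuples()
    ]
    observed = float(np.nanmean(obs_d))

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    dropped_total = 0
    syn_rows = list(syn.itertuples())
    for s in range(n_shuffles):
        ds = []
        for row in syn_rows:
            placed = False
            for _ in range(max_retries):
                if mode == "within":
                    target = row.ais_id
                else:
                    target = ais_with_cos[rng.integers(len(ais_with_cos))]
                cand = np.asarray(candidates.get(target, np.empty((0, 2))), float)
                if cand.size == 0:
                    continue
                match = np.abs(cand[:, 0] - row.depth) <= depth_tolerance
                if not match.any():
                    continue
                sub = cand[match]
                dth = np.abs(np.angle(np.exp(1j * (sub[:, 1] - row.orientation))))
                pick = sub[np.argmin(dth)]
                ds.append(dist_to_cos(target, pick[0], pick[1]))
                placed = True
                break
            if not placed:
                dropped_total += 1
        null[s] = np.nanmean(ds) if ds else np.nan
    ok = null[np.isfinite(null)]
    p = float((np.sum(ok <= observed) + 1) / (len(ok) + 1))
    return {
        "observed": observed,
        "null": null,
        "p": p,
        "n_synapses": len(syn_rows),
        "n_dropped": dropped_total,
    }


def census_summary(
    synapse_table: pd.DataFrame, n_cells: int | None = None
) -> dict:
    """Census arithmetic over an AIS synapse table.

    ``synapse_table`` has one row per synapse with columns ``cell_id``,
    ``axon_id`` and ``source_class`` ("chc" or "non_chc"). Returns mean
    synapses per AIS, the non-ChC share, the fraction of cells with ChC
    input, and the fraction of cells with at least one >=2-synapse ChC
    connection.
    """
    if n_cells is None:
        n_cells = synapse_table["cell_id"].nunique()
    total = len(synapse_table)
    non_chc = int((synapse_table["source_class"] == "non_chc").sum())
    chc = synapse_table[synapse_table["source_class"] == "chc"]
    cells_with_chc = chc["cell_id"].nunique()
    conn_sizes = chc.groupby(["axon_id", "cell_id"]).size()
    cells_with_cartridge = (
        conn_sizes[conn_sizes >= 2].reset_index()["cell_id"].nunique()
    )
    return {
        "n_synapses": total,
        "n_cells": n_cells,
        "mean_synapses_per_ais": total / n_cells,
        "non_chc_share": non_chc / total if total else float("nan"),
        "fraction_cells_with_chc_input": cells_with_chc / n_cells,
        "fraction_cells_with_multisynapse_connection": cells_with_cartridge
        / n_cells,
    }


def ais_input_summary(chc_synapses: pd.DataFrame, n_cells: int | None = None) -> dict:
    """Per-AIS means of ChC input from a synapse table.

    Returns the mean number of ChC synapses per AIS and the mean number of
    distinct presynaptic ChC axons per AIS, averaged over ``n_cells`` cells
    (cells absent from the table count as zero).
    """
    if n_cells is None:
        n_cells = chc_synapses["cell_id"].nunique()
    syn_per_cell = chc_synapses.groupby("cell_id").size()
    axons_per_cell = chc_synapses.groupby("cell_id")["axon_id"].nunique()
    return {
        "mean_chc_synapses_per_ais": float(syn_per_cell.sum() / n_cells),
        "mean_chc_axons_per_ais": float(axons_per_cell.sum() / n_cells),
        "n_cells": int(n_cells),
    }
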