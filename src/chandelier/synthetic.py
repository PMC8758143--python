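"""Synthetic populations with the statistical structure of the EM census.

The generator emulates the features the downstream analyses assume:

* a depth gradient in chandelier axon abundance (Poisson N_pot with
  log-rate linear in depth),
* three latent per-cell components (depth, perisomatic inhibition,
  perisomatic size) that drive six observed structural features through a
  loadings matrix plus feature noise,
* a logistic connection probability f_con raised by the size and
  inhibition components,
* geometric synapses-per-connection on support {1, 2, ...},
* optional co-targeting bias alpha for motif power studies,
* axon point clouds placed so the distance-threshold potential-connection
  operation recovers the generated potential graph exactly (contacts are
  2 um from the target AIS; somata sit on a 40 um lateral grid, so any
  threshold in [2, ~19] um reproduces the generated edges),
* correlated calcium traces driven by a latent Ornstein-Uhlenbeck arousal
  process with pupil/locomotion covariates.

Latent components are independent unit-variance Laplace variables: they are
uncorrelated and standardized as the component analysis assumes, and their
non-Gaussianity is what makes the ICA mixing identifiable. All randomness
flows from a single seed through named ``SeedSequence`` child streams.

The ``"paper"`` preset (``presets/paper.json``) carries parameters
calibrated once so that the full pipeline at n_cells=113 reproduces the
reference census and regression structure (mean ~3.3 connections and ~7.4
chandelier synapses per AIS, geometric p = 0.44, standardized coefficients
near (-0.47, +0.33, +0.34), R^2 near 0.45).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .activity import TraceBundle
from .ais import NM_PER_UM, AISDomain
from .motifs import BipartiteNetwork, _completes_bifan, _edge_maps

__all__ = [
    "PopulationParams",
    "ActivityParams",
    "load_preset",
    "generate_structural_population",
    "generate_biased_network",
    "generate_activity",
]

FEATURES = [
    "depth",
    "ais_radius",
    "nonchc_ais_syn_count",
    "soma_syn_density",
    "soma_area",
    "soma_syn_count",
]

_DEFAULT_LOADINGS = [
    # depth, inhibition, size
    [1.00, 0.00, 0.00],  # depth
    [0.00, 0.00, 0.80],  # ais_radius
    [0.00, 0.70, 0.00],  # nonchc_ais_syn_count
    [0.00, 0.80, -0.30],  # soma_syn_density
    [0.00, 0.00, 0.90],  # soma_area
    [0.00, 0.80, 0.40],  # soma_syn_count
]

_FEATURE_LOC = {
    "depth": (100.0, 30.0),
    "ais_radius": (0.55, 0.08),
    "nonchc_ais_syn_count": (5.2, 2.0),
    "soma_syn_density": (0.55, 0.10),
    "soma_area": (600.0, 80.0),
    "soma_syn_count": (75.0, 12.0),
}


@dataclass
class PopulationParams:
    """Generative parameters for a structural population."""

    n_cells: int = 113
    volume_bounds: tuple | None = None  # 3 x (lo, hi) um; auto-sized if None
    depth_density_slope: float = -0.011  # log N_pot rate change per um depth
    npot_log_intercept: float = 2.0  # log expected N_pot at the reference depth
    component_loadings: list = field(
        default_factory=lambda: [row[:] for row in _DEFAULT_LOADINGS]
    )
    noise_sd: list = field(
        default_factory=lambda: [0.15, 0.60, 0.60, 0.60, 0.60, 0.60]
    )
    fcon_intercept: float = -0.2
    fcon_size_coef: float = 0.5
    fcon_inhib_coef: float = 0.5
    geometric_p: float = 0.44
    bifan_bias: float = 1.0
    seed: int = 0
    # geometry knobs
    n_axons: int | None = None  # default ~0.81 per cell (124 axons / 153 cells)
    ais_length: float = 45.0  # um
    grid_spacing: float = 40.0  # um between somata laterally
    contact_distance: float = 2.0  # um from axon contact point to the AIS
    synapse_depth_mean: float = 23.0  # um; ~97% of synapses land above 37 um
    synapse_depth_sd: float = 7.5

    def validate(self) -> None:
        vals = [
            self.depth_density_slope, self.npot_log_intercept,
            self.fcon_intercept, self.fcon_size_coef, self.fcon_inhib_coef,
            self.geometric_p, self.bifan_bias,
        ]
        arr = np.concatenate(
            [np.asarray(vals, float).ravel(),
             np.asarray(self.component_loadings, float).ravel(),
             np.asarray(self.noise_sd, float).ravel()]
        )
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite generator parameter")
        if not (0 < self.geometric_p <= 1):
            raise ValueError("geometric_p must be in (0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.bifan_bias < 0:
            raise ValueError("bifan_bias must be >= 0")


@dataclass
class ActivityParams:
    """Generative parameters for calcium-trace bundles."""

    n_cells: int = 5
    duration: float = 600.0  # s
    rate: float = 12.0  # Hz
    arousal_timescale: float = 8.0  # s
    shared_gain: float = 1.0
    private_noise_sd: float = 1.0
    indicator_tau: float = 0.7  # s (GCaMP6f-like decay)
    seed: int = 0

    def validate(self) -> None:
        if self.duration * self.rate < 2:
            raise ValueError("duration x rate must give at least 2 samples")
        if self.arousal_timescale <= 0 or self.indicator_tau <= 0:
            raise ValueError("timescales must be positive")
        if self.private_noise_sd < 0 or self.rate <= 0:
            raise ValueError("invalid noise or rate")


def load_preset(name: str = "paper") -> PopulationParams:
    """Load a named generator preset (calibrated parameters)."""
    ref = resources.files("chandelier") / "presets" / f"{name}.json"
    with ref.open() as fh:
        data = json.load(fh)
    return PopulationParams(**data)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _laplace_latents(rng, n):
    """Independent unit-variance Laplace latent components, (n, 3)."""
    return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, 3))


def generate_structural_population(params: PopulationParams):
    """Generate (cell table, axon point clouds, synapse table, network).

    Returns
    -------
    cells : DataFrame with the six observed features, soma position (um),
        hidden truth columns (latent_*, n_pot_true, f_con_true) and
        realized chc_syn_count / n_con.
    ais_domains : list of AISDomain (vertical AISes below each soma).
    axons : dict axon_id -> (m, 3) point cloud in nm.
    synapses : DataFrame, one row per synapse (ChC and non-ChC).
    network : dict with "potential" and "actual" edge lists.
    """
    params.validate()
    n = params.n_cells
    root = np.random.SeedSequence(params.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["latents", "noise", "npot", "edges", "sizes", "geometry",
             "nonchc"],
            root.spawn(7),
        )
    }

    Z = _laplace_latents(streams["latents"], n)  # columns: depth, inhib, size
    L = np.asarray(params.component_loadings, float)
    noise = streams["noise"].normal(0.0, 1.0, size=(n, 6)) * np.asarray(
        params.noise_sd, float
    )
    raw = Z @ L.T + noise
    cells = pd.DataFrame({"cell_id": np.arange(n)})
    for j, name in enumerate(FEATURES):
        mu, sc = _FEATURE_LOC[name]
        vals = mu + sc * raw[:, j]
        if name.endswith("count"):
            vals = np.maximum(np.round(vals), 0)
        cells[name] = vals

    # soma placement: lateral 40-um grid, depth from the depth latent
    side = int(np.ceil(np.sqrt(n)))
    gx, gz = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    gx = gx.ravel()[:n] * params.grid_spacing
    gz = gz.ravel()[:n] * params.grid_spacing
    depth = cells["depth"].to_numpy()
    cells["soma_x"] = gx
    cells["soma_y"] = depth
    cells["soma_z"] = gz

    if params.volume_bounds is None:
        bounds = (
            (float(gx.min() - 20), float(gx.max() + 20)),
            (float(depth.min() - 20), float(depth.max() + params.ais_length + 20)),
            (float(gz.min() - 20), float(gz.max() + 20)),
        )
    else:
        bounds = tuple(tuple(b) for b in params.volume_bounds)

    # vertical AIS below each soma, 1-um node spacing
    ais_domains = []
    n_nodes = int(params.ais_length) + 1
    for i in range(n):
        s = np.arange(n_nodes, dtype=float)
        pos = np.column_stack(
            [np.full(n_nodes, gx[i]), depth[i] + s, np.full(n_nodes, gz[i])]
        ) * NM_PER_UM
        radius_nm = max(cells.loc[i, "ais_radius"], 0.1) * NM_PER_UM
        ais_domains.append(
            AISDomain(
                cell_id=i,
                positions=pos,
                radii=np.full(n_nodes, radius_nm),
                arclength=s,
                top=pos[0],
                bottom=pos[-1],
            )
        )

    # potential graph: N_pot ~ Poisson(exp(a0 + slope * (depth - ref)))
    n_axons = params.n_axons or max(2, int(round(0.81 * n)))
    ref_depth = _FEATURE_LOC["depth"][0]
    log_rate = params.npot_log_intercept + params.depth_density_slope * (
        depth - ref_depth
    )
    n_pot = np.minimum(streams["npot"].poisson(np.exp(log_rate)), n_axons)
    potential = []
    for i in range(n):
        partners = streams["npot"].choice(n_axons, size=n_pot[i], replace=False)
        potential.extend((int(a), i) for a in partners)

    # connection probability per cell
    f_con = _sigmoid(
        params.fcon_intercept
        + params.fcon_size_coef * Z[:, 2]
        + params.fcon_inhib_coef * Z[:, 1]
    )
    if np.all(f_con >= 1 - 1e-12) or np.all(f_con <= 1e-12):
        warnings.warn("logistic coefficients give a degenerate network")

    if params.bifan_bias == 1.0:
        actual = [
            (a, c) for a, c in potential
            if streams["edges"].random() < f_con[c]
        ]
    else:
        net = BipartiteNetwork(
            axon_ids=list(range(n_axons)),
            cell_ids=list(range(n)),
            potential=set(potential),
            actual=set(),
        )
        degrees = {
            c: int(streams["edges"].binomial(n_pot[c], f_con[c]))
            for c in range(n)
        }
        actual = sorted(
            generate_biased_network(
                net, params.bifan_bias, degrees,
                seed=int(root.spawn(1)[0].generate_state(1)[0] % 2**31),
            )
        )

    # synapses per connection ~ geometric(p), placed on the target AIS
    geo = streams["sizes"]
    gm = streams["geometry"]
    syn_rows = []
    syn_id = 0
    a_lo, a_hi = 0.0, params.ais_length
    mu_d, sd_d = params.synapse_depth_mean, params.synapse_depth_sd
    for a, c in actual:
        size = int(geo.geometric(params.geometric_p))
        for _ in range(size):
            d = stats.truncnorm.rvs(
                (a_lo - mu_d) / sd_d, (a_hi - mu_d) / sd_d, loc=mu_d,
                scale=sd_d, random_state=gm,
            )
            theta = gm.uniform(-np.pi, np.pi)
            r_nm = max(cells.loc[c, "ais_radius"], 0.1) * NM_PER_UM
            x = gx[c] * NM_PER_UM + r_nm * np.cos(theta)
            z = gz[c] * NM_PER_UM + r_nm * np.sin(theta)
            y = (depth[c] + d) * NM_PER_UM
            syn_rows.append(
                {
                    "synapse_id": syn_id,
                    "axon_id": a,
                    "cell_id": c,
                    "x": x,
                    "y": y,
                    "z": z,
                    "depth": d,
                    "source_class": "chc",
                }
            )
            syn_id += 1

    # non-ChC AIS synapses: singleton connections, concentrated proximally
    nonchc_rng = streams["nonchc"]
    nonchc_axon = 10_000  # ids disjoint from the ChC pool
    for c in range(n):
        k = int(cells.loc[c, "nonchc_ais_syn_count"])
        for _ in range(k):
            d = float(np.clip(nonchc_rng.exponential(10.0), 0, params.ais_length))
            theta = nonchc_rng.uniform(-np.pi, np.pi)
            r_nm = max(cells.loc[c, "ais_radius"], 0.1) * NM_PER_UM
            syn_rows.append(
                {
                    "synapse_id": syn_id,
                    "axon_id": nonchc_axon,
                    "cell_id": c,
                    "x": gx[c] * NM_PER_UM + r_nm * np.cos(theta),
                    "y": (depth[c] + d) * NM_PER_UM,
                    "z": gz[c] * NM_PER_UM + r_nm * np.sin(theta),
                    "depth": d,
                    "source_class": "non_chc",
                }
            )
            syn_id += 1
            nonchc_axon += 1
    synapses = pd.DataFrame(
        syn_rows,
        columns=["synapse_id", "axon_id", "cell_id", "x", "y", "z", "depth",
                 "source_class"],
    )

    # axon point clouds: one contact point per potential edge, offset
    # contact_distance from a node of the target AIS
    axons: dict = {a: [] for a in range(n_axons)}
    off = params.contact_distance * NM_PER_UM
    for a, c in potential:
        d = stats.truncnorm.rvs(
            (a_lo - mu_d) / sd_d, (a_hi - mu_d) / sd_d, loc=mu_d, scale=sd_d,
            random_state=gm,
        )
        phi = gm.uniform(-np.pi, np.pi)
        axons[a].append(
            [
                gx[c] * NM_PER_UM + off * np.cos(phi),
                (depth[c] + d) * NM_PER_UM,
                gz[c] * NM_PER_UM + off * np.sin(phi),
            ]
        )
    axons = {
        a: np.asarray(pts, float).reshape(-1, 3) for a, pts in axons.items()
        if pts
    }

    chc = synapses[synapses["source_class"] == "chc"]
    syn_per_cell = chc.groupby("cell_id").size()
    con_per_cell = chc.groupby("cell_id")["axon_id"].nunique()
    cells["chc_syn_count"] = (
        syn_per_cell.reindex(range(n), fill_value=0).to_numpy()
    )
    cells["n_con"] = con_per_cell.reindex(range(n), fill_value=0).to_numpy()
    cells["n_pot_true"] = n_pot
    cells["f_con_true"] = f_con
    cells["latent_depth"] = Z[:, 0]
    cells["latent_inhib"] = Z[:, 1]
    cells["latent_size"] = Z[:, 2]

    network = {
        "potential": sorted(potential),
        "actual": sorted(set(actual)),
        "volume_bounds": bounds,
    }
    return cells, ais_domains, axons, synapses, network


def generate_biased_network(
    potential_net: BipartiteNetwork, alpha: float, target_degrees: dict,
    seed: int = 0,
) -> set:
    """Draw an actual edge set with co-targeting bias within a potential graph.

    Each cell receives exactly ``target_degrees[cell]`` actual edges (capped
    at its potential degree). Edges are chosen sequentially in random order;
    at each step a candidate axon whose edge would complete a bifan against
    the edges chosen so far carries weight ``alpha``, all others weight 1
    (alpha = 1 is uniform; alpha = 0 avoids bifans whenever possible).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not potential_net.potential:
        raise ValueError("empty potential graph")
    rng = np.random.default_rng(seed)
    pot_axons = {
        c: potential_net.potential_axons_of(c) for c in potential_net.cell_ids
    }
    slots = []
    for c, d in target_degrees.items():
        slots.extend([c] * min(int(d), len(pot_axons.get(c, []))))
    rng.shuffle(slots)
    actual_cells: dict = {}
    actual_axons: dict = {}
    for c in slots:
        connected = actual_axons.setdefault(c, set())
        candidates = [a for a in pot_axons[c] if a not in connected]
        if not candidates:
            continue
        w = np.array(
            [
                alpha if _completes_bifan(actual_cells, actual_axons, a, c)
                else 1.0
                for a in candidates
            ]
        )
        tot = w.sum()
        if tot == 0:
            pick = candidates[rng.integers(len(candidates))]
        else:
            pick = candidates[rng.choice(len(candidates), p=w / tot)]
        connected.add(pick)
        actual_cells.setdefault(pick, set()).add(c)
    return {(a, c) for a, cs in actual_cells.items() for c in cs}


def generate_activity(params: ActivityParams):
    """Correlated calcium traces driven by a latent arousal process.

    The arousal is a unit-variance Ornstein-Uhlenbeck process. Pupil is a
    smoothed copy of arousal plus noise; locomotion is thresholded arousal
    bursts. Each cell trace is shared_gain * s + private_noise_sd * n_i,
    where s and n_i are the arousal and a private white noise, both
    convolved with an exponential indicator kernel and standardized to unit
    variance — so the expected pairwise cell-cell correlation is
    g^2 / (g^2 + sigma^2).
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    r_arousal, r_noise, r_beh = (
        np.random.default_rng(c) for c in root.spawn(3)
    )
    n = int(round(params.duration * params.rate))
    dt = 1.0 / params.rate
    rho = np.exp(-dt / params.arousal_timescale)
    innov = r_arousal.normal(0, np.sqrt(1 - rho**2), n)
    arousal = np.empty(n)
    arousal[0] = r_arousal.normal()
    for t in range(1, n):
        arousal[t] = rho * arousal[t - 1] + innov[t]

    kernel = np.exp(-np.arange(0, 5 * params.indicator_tau, dt)
                    / params.indicator_tau)
    kernel /= kernel.sum()

    def filt_std(x):
        y = signal.lfilter(kernel, [1.0], x)
        sd = y.std()
        return y / sd if sd > 0 else y

    s = filt_std(arousal)
    traces = np.empty((params.n_cells, n))
    for i in range(params.n_cells):
        ni = filt_std(r_noise.normal(0, 1, n))
        traces[i] = params.shared_gain * s + params.private_noise_sd * ni

    pupil = ndimage.gaussian_filter1d(arousal, sigma=max(1.0, 0.5 / dt))
    pupil = pupil + 0.1 * r_beh.normal(0, 1, n)
    locomotion = np.maximum(arousal - 1.0, 0.0)
    locomotion = locomotion + 0.05 * np.abs(r_beh.normal(0, 1, n))

    return TraceBundle(
        traces=traces, rate=params.rate, pupil=pupil, locomotion=locomotion,
        mask=np.ones(n, bool),
    )


def params_to_json(params) -> str:
    """Serialize a params dataclass losslessly to JSON."""
    return json.dumps(asdict(params), indent=2, sort_keys=True)
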