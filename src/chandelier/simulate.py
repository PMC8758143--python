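"""Inhibition-scenario simulation on a surrogate neuron.

Three activation scenarios for AIS-targeting inhibition differ only in how
spike trains are shared across synapses: *synchronous* (all synapses share
one Poisson realization), *biologically inspired* (synapses grouped into
clusters matching measured connection sizes, one realization per cluster),
and *asynchronous* (one realization per synapse). Inhibitory rate is held
at 100 Hz per train; excitation is 25 connections x 2 synapses with Poisson
rates swept 0-500 Hz, or Gaussian-profile barrages (peak 500 Hz excitation,
200 Hz inhibition) with a controlled centroid offset.

The driven cell is a two-compartment conductance-based leaky
integrate-and-fire neuron (soma + AIS) with conductance synapses, an AIS
spike threshold and a refractory period. It is a surrogate standing in for
morphologically detailed models; quantitative firing rates are not
comparable, but the qualitative orderings between scenarios and inhibition
sites are the object of study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScenarioConfig",
    "BarrageConfig",
    "NeuronParams",
    "SurrogateNeuron",
    "SpikeTrainSet",
    "SimResult",
    "make_scenario_trains",
    "sample_cluster_sizes",
    "sample_gaussian_barrage",
    "differential_effect_ratio",
    "run_fi_experiment",
    "run_offset_experiment",
]

SCENARIOS = ("synchronous", "biologically_inspired", "asynchronous")


@dataclass
class SpikeTrainSet:
    """Per-synapse spike-time lists (seconds) plus cluster identities."""

    trains: list  # list of np.ndarray, one per synapse
    cluster_of: np.ndarray  # synapse -> cluster index

    def __len__(self) -> int:
        return len(self.trains)


@dataclass
class ScenarioConfig:
    scenario: str
    n_inh_synapses: int
    cluster_sizes: list | None = None
    inh_rate: float = 100.0
    duration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario == "synchronous":
            self.cluster_sizes = [self.n_inh_synapses]
        elif self.scenario == "asynchronous":
            self.cluster_sizes = [1] * self.n_inh_synapses
        elif self.cluster_sizes is None:
            raise ValueError("biologically_inspired requires cluster_sizes")
        if sum(self.cluster_sizes) != self.n_inh_synapses:
            raise ValueError("cluster_sizes must sum to n_inh_synapses")


@dataclass
class BarrageConfig:
    exc_peak_rate: float = 500.0
    inh_peak_rate: float = 200.0
    width: float = 0.05  # s, Gaussian rate-profile SD
    offset: float = 0.0  # s, excitation centroid minus inhibition centroid
    repetitions: int = 10
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.exc_peak_rate < 0 or self.inh_peak_rate < 0:
            raise ValueError("peak rates must be >= 0")
        if abs(self.offset) > self.duration / 2:
            raise ValueError("|offset| must be <= duration/2")


@dataclass
class NeuronParams:
    """Two-compartment conductance LIF parameters.

    Capacitances in pF, conductances in nS, voltages in mV, times in ms.
    The AIS compartment is small and tightly coupled to the soma; spikes
    initiate when the AIS voltage crosses threshold.
    """

    c_soma: float = 180.0
    c_ais: float = 12.0
    g_leak_soma: float = 12.0
    g_leak_ais: float = 1.5
    e_leak: float = -70.0
    g_couple: float = 25.0
    v_thresh: float = -52.0
    v_reset: float = -65.0
    refractory: float = 3.0
    # synapses
    g_exc: float = 0.9
    tau_exc: float = 2.0
    e_exc: float = 0.0
    g_inh: float = 2.5
    tau_inh: float = 8.0
    e_inh: float = -78.0
    dt: float = 0.1


class SurrogateNeuron:
    """Conductance-based soma+AIS integrate-and-fire model.

    Contract: ``run(exc_trains, inh_trains, inh_site, duration)`` returns
    output spike times (s). Excitation enters the soma (lumped dendrite);
    inhibition enters either the AIS or the soma. Any conforming simulator
    can replace this class in the experiment drivers.
    """

    def __init__(self, params: NeuronParams | None = None):
        self.params = params or NeuronParams()

    def run(self, exc_trains, inh_trains, inh_site: str, duration: float):
        counts = self.run_batch([exc_trains], [inh_trains], inh_site, duration)
        return counts[0]

    def run_batch(self, exc_sets, inh_sets, inh_site: str, duration: float):
        """Simulate B independent realizations; returns spike-time lists.

        ``exc_sets``/``inh_sets`` are length-B lists of train lists. All
        realizations share parameters and the inhibition site.
        """
        if inh_site not in ("AIS", "soma"):
            raise ValueError("inh_site must be 'AIS' or 'soma'")
        p = self.params
        dt = p.dt
        n_steps = int(round(duration * 1000.0 / dt))
        B = len(exc_sets)

        def binned(train_sets):
            out = np.zeros((B, n_steps), dtype=np.int32)
            for b, trains in enumerate(train_sets):
                for t in trains:
                    idx = np.floor(np.asarray(t) * 1000.0 / dt).astype(int)
                    idx = idx[(idx >= 0) & (idx < n_steps)]
                    np.add.at(out[b], idx, 1)
            return out

        exc_in = binned(exc_sets)
        inh_in = binned(inh_sets)
        decay_e = np.exp(-dt / p.tau_exc)
        decay_i = np.exp(-dt / p.tau_inh)
        v_s = np.full(B, p.e_leak)
        v_a = np.full(B, p.e_leak)
        g_e = np.zeros(B)
        g_i = np.zeros(B)
        refr = np.zeros(B)
        spikes = [[] for _ in range(B)]
        for k in range(n_steps):
            g_e = g_e * decay_e + p.g_exc * exc_in[:, k]
            g_i = g_i * decay_i + p.g_inh * inh_in[:, k]
            gi_soma = g_i if inh_site == "soma" else 0.0
            gi_ais = g_i if inh_site == "AIS" else 0.0
            i_couple = p.g_couple * (v_a - v_s)
            dv_s = (
                p.g_leak_soma * (p.e_leak - v_s)
                + g_e * (p.e_exc - v_s)
                + gi_soma * (p.e_inh - v_s)
                + i_couple
            ) / p.c_soma
            dv_a = (
                p.g_leak_ais * (p.e_leak - v_a)
                + gi_ais * (p.e_inh - v_a)
                - i_couple
            ) / p.c_ais
            v_s = v_s + dt * dv_s
            v_a = v_a + dt * dv_a
            active = refr <= 0
            refr = np.maximum(refr - dt, 0.0)
            fired = active & (v_a >= p.v_thresh)
            if fired.any():
                t_now = k * dt / 1000.0
                for b in np.flatnonzero(fired):
                    spikes[b].append(t_now)
                v_a[fired] = p.v_reset
                v_s[fired] -= 3.0  # small somatic AHP on each spike
                refr[fired] = p.refractory
            clamped = refr > 0
            v_a[clamped] = np.minimum(v_a[clamped], p.v_reset)
        if np.any(~np.isfinite(v_s)) or np.any(~np.isfinite(v_a)):
            raise RuntimeError("surrogate neuron produced non-finite voltage")
        return [np.asarray(s) for s in spikes]


@dataclass
class SimResult:
    """Condition grid of spike counts plus derived comparisons."""

    table: pd.DataFrame
    comparisons: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)


def make_scenario_trains(config: ScenarioConfig) -> SpikeTrainSet:
    """Homogeneous Poisson trains shared within clusters.

    One train per cluster at ``inh_rate`` over ``duration``; every synapse
    in a cluster carries its cluster's train verbatim.
    """
    rng = np.random.default_rng(config.seed)
    trains_by_cluster = []
    for _ in config.cluster_sizes:
        n = rng.poisson(config.inh_rate * config.duration)
        trains_by_cluster.append(np.sort(rng.uniform(0, config.duration, n)))
    trains = []
    cluster_of = []
    for ci, size in enumerate(config.cluster_sizes):
        for _ in range(size):
            trains.append(trains_by_cluster[ci])
            cluster_of.append(ci)
    return SpikeTrainSet(trains=trains, cluster_of=np.asarray(cluster_of))


def sample_cluster_sizes(empirical_sizes, n_total: int, seed: int = 0) -> list:
    """Cluster sizes drawn from the measured connection-size distribution.

    Draws with replacement until the running total reaches ``n_total``,
    truncating the final draw.
    """
    empirical_sizes = np.asarray(empirical_sizes, int)
    if empirical_sizes.size == 0:
        raise ValueError("empirical size table is empty")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    total = 0
    while total < n_total:
        s = int(empirical_sizes[rng.integers(empirical_sizes.size)])
        s = min(s, n_total - total)
        out.append(s)
        total += s
    return out


def sample_gaussian_barrage(
    peak_rate: float,
    center: float,
    width: float,
    duration: float,
    n_trains: int,
    seed: int = 0,
) -> list:
    """Inhomogeneous Poisson trains via thinning of a Gaussian rate.

    r(t) = peak * exp(-(t - center)^2 / (2 width^2)) over [0, duration].
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if peak_rate < 0:
        raise ValueError("peak rate must be >= 0")
    if peak_rate * duration > 1e7:
        raise ValueError("peak rate x duration too large")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_trains):
        if peak_rate == 0:
            trains.append(np.empty(0))
            continue
        n = rng.poisson(peak_rate * duration)
        t = rng.uniform(0, duration, n)
        keep = rng.uniform(0, 1, n) < np.exp(-((t - center) ** 2) / (2 * width**2))
        trains.append(np.sort(t[keep]))
    return trains


def differential_effect_ratio(count_soma: float, count_ais: float) -> float:
    """(N_soma - N_AIS) / (N_soma + N_AIS).

    Positive values mean AIS inhibition suppressed output more than somatic
    inhibition; bounded in [-1, 1]. Undefined (NaN) when both counts are 0.
    """
    if count_soma < 0 or count_ais < 0:
        raise ValueError("spike counts must be >= 0")
    tot = count_soma + count_ais
    if tot == 0:
        return float("nan")
    return (count_soma - count_ais) / tot


def _poisson_trains(rng, rate, duration, n):
    out = []
    for _ in range(n):
        m = rng.poisson(rate * duration)
        out.append(np.sort(rng.uniform(0, duration, m)))
    return out


def _exc_trains(rng, rate, duration, n_connections=25, syn_per_connection=2,
                shared=True):
    """25 excitatory connections, two synapses each, shared per connection."""
    if shared:
        conn = _poisson_trains(rng, rate, duration, n_connections)
        return [t for t in conn for _ in range(syn_per_connection)]
    return _poisson_trains(rng, rate, duration, n_connections * syn_per_connection)


def _check_contract(neuron, duration=0.5):
    rng = np.random.default_rng(12345)
    exc = _exc_trains(rng, 400.0, duration)
    out = neuron.run(exc, [], "AIS", duration)
    if len(out) == 0:
        raise RuntimeError(
            "neuron model violates contract: no spikes under strong excitation "
            "and zero inhibition"
        )


def run_fi_experiment(
    neuron,
    n_syn_values=(9, 15),
    exc_rates=(0.0, 100.0, 200.0, 300.0, 400.0, 500.0),
    reps: int = 8,
    duration: float = 1.0,
    inh_rate: float = 100.0,
    empirical_sizes=(1, 1, 2, 2, 3, 4, 5),
    seed: int = 0,
    scenarios=SCENARIOS,
) -> SimResult:
    """f-I curves under the three inhibition scenarios.

    Per condition the neuron receives 25 excitatory Poisson connections
    (two synapses each) plus the scenario's inhibitory trains at the AIS.
    Scenario pairs are compared per (n_syn, rate) with one-sided Wilcoxon
    signed-rank tests across repetitions, Benjamini-Hochberg corrected at
    5% FDR.
    """
    _check_contract(neuron)
    ss = np.random.SeedSequence(seed)
    rows = []
    for n_syn in n_syn_values:
        for scen in scenarios:
            for rate in exc_rates:
                batch_exc, batch_inh = [], []
                for rep in range(reps):
                    child = np.random.SeedSequence(
                        entropy=ss.entropy,
                        spawn_key=(int(n_syn), SCENARIOS.index(scen),
                                   int(rate), rep),
                    )
                    rng = np.random.default_rng(child)
                    exc = _exc_trains(rng, rate, duration)
                    if n_syn == 0:
                        batch_exc.append(exc)
                        batch_inh.append([])
                        continue
                    if scen == "biologically_inspired":
                        cs = sample_cluster_sizes(
                            empirical_sizes, n_syn,
                            seed=int(child.generate_state(1)[0] % 2**31),
                        )
                    else:
                        cs = None
                    cfg = ScenarioConfig(
                        scenario=scen, n_inh_synapses=n_syn, cluster_sizes=cs,
                        inh_rate=inh_rate, duration=duration,
                        seed=int(child.generate_state(2)[1] % 2**31),
                    )
                    inh = make_scenario_trains(cfg).trains
                    batch_exc.append(exc)
                    batch_inh.append(inh)
                counts = neuron.run_batch(batch_exc, batch_inh, "AIS", duration)
                for rep, spk in enumerate(counts):
                    rows.append(
                        {
                            "scenario": scen,
                            "n_syn": n_syn,
                            "exc_rate": rate,
                            "rep": rep,
                            "spike_count": len(spk),
                        }
                    )
    table = pd.DataFrame(rows)
    comparisons = _pairwise_scenario_tests(table, scenarios)
    return SimResult(table=table, comparisons=comparisons,
                     config={"seed": seed, "reps": reps, "duration": duration})


def _pairwise_scenario_tests(table: pd.DataFrame, scenarios) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank per condition, BH-corrected at 5% FDR.

    Direction tested: the first scenario of the pair yields *more* output
    spikes than the second (less effective suppression).
    """
    rows = []
    pairs = [
        (a, b) for i, a in enumerate(scenarios) for b in scenarios[i + 1:]
    ]
    for (a, b) in pairs:
        for (n_syn, rate), grp in table.groupby(["n_syn", "exc_rate"]):
            xa = grp[grp["scenario"] == a].sort_values("rep")["spike_count"]
            xb = grp[grp["scenario"] == b].sort_values("rep")["spike_count"]
            if len(xa) == 0 or len(xa) != len(xb):
                continue
            diff = xa.to_numpy() - xb.to_numpy()
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = wilcoxon(diff, alternative="greater")
            rows.append(
                {
                    "scenario_a": a,
                    "scenario_b": b,
                    "n_syn": n_syn,
                    "exc_rate": rate,
                    "statistic": stat,
                    "pvalue": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant_fdr05"] = multipletests(
            out["pvalue"], alpha=0.05, method="fdr_bh"
        )[0]
    return out


def run_offset_experiment(
    neuron,
    offsets=None,
    n_syn_values=(9,),
    reps: int = 10,
    duration: float = 1.0,
    barrage: BarrageConfig | None = None,
    seed: int = 0,
) -> SimResult:
    """AIS vs somatic inhibition under offset Gaussian barrages.

    For each excitation/inhibition centroid offset and synapse count,
    identical barrages are delivered with the inhibition placed at the AIS
    or at the soma (all else identical); spike counts, the differential
    effect ratio, and FDR-controlled one-sided Wilcoxon site comparisons
    are reported.
    """
    _check_contract(neuron)
    if offsets is None:
        offsets = np.arange(-0.1, 0.1001, 0.005)
    base = barrage or BarrageConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for n_syn in n_syn_values:
        for offset in offsets:
            inh_center = duration / 2.0
            exc_center = inh_center + offset
            batch_exc, batch_inh = [], []
            for rep in range(reps):
                child = np.random.SeedSequence(
                    entropy=ss.entropy,
                    spawn_key=(int(n_syn), int(round(offset * 1000)) + 1000, rep),
                )
                s1, s2 = child.spawn(2)
                exc_conn = sample_gaussian_barrage(
                    base.exc_peak_rate, exc_center, base.width, duration, 25,
                    seed=int(s1.generate_state(1)[0] % 2**31),
                )
                exc = [t for t in exc_conn for _ in range(2)]
                inh = sample_gaussian_barrage(
                    base.inh_peak_rate, inh_center, base.width, duration, n_syn,
                    seed=int(s2.generate_state(1)[0] % 2**31),
                )
                batch_exc.append(exc)
                batch_inh.append(inh)
            for site in ("AIS", "soma"):
                counts = neuron.run_batch(batch_exc, batch_inh, site, duration)
                for rep, spk in enumerate(counts):
                    rows.append(
                        {
                            "offset": float(offset),
                            "n_syn": n_syn,
                            "site": site,
                            "rep": rep,
                            "spike_count": len(spk),
                        }
                    )
    table = pd.DataFrame(rows)
    # DER and site comparisons per condition
    comp_rows = []
    for (n_syn, offset), grp in table.groupby(["n_syn", "offset"]):
        ais = grp[grp["site"] == "AIS"].sort_values("rep")["spike_count"].to_numpy()
        soma = grp[grp["site"] == "soma"].sort_values("rep")["spike_count"].to_numpy()
        der = differential_effect_ratio(float(soma.sum()), float(ais.sum()))
        diff = soma - ais
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(diff, alternative="greater")
        comp_rows.append(
            {
                "n_syn": n_syn,
                "offset": offset,
                "der": der,
                "mean_count_ais": ais.mean(),
                "mean_count_soma": soma.mean(),
                "statistic": stat,
                "pvalue": p,
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons["significant_fdr05"] = multipletests(
            comparisons["pvalue"], alpha=0.05, method="fdr_bh"
        )[0]
    return SimResult(table=table, comparisons=comparisons,
                     config={"seed": seed, "barrage": asdict(base)})
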