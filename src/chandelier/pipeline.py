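"""End-to-end orchestration with fixed-seed reproducibility.

Stages run in dependency order (generate -> ais -> connectivity ->
stats / motifs / synapse-stats; simulate and activity are independent).
Every output file is recorded in a manifest with its SHA-256 checksum; the
log carries the package version, seed, and per-stage timing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .activity import behavior_correlations, pairwise_correlations
from .connectivity import decompose, potential_connections
from .motifs import BipartiteNetwork, motif_null_test
from .simulate import SurrogateNeuron, run_fi_experiment, run_offset_experiment
from .structural import (
    FEATURE_COLUMNS,
    correlation_screen,
    fit_components,
    regress_on_components,
)
from .synapses import fit_connection_size
from .synthetic import (
    ActivityParams,
    PopulationParams,
    generate_activity,
    generate_structural_population,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "validate_inputs", "PipelineError"]

logger = logging.getLogger("chandelier")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "chandelier_out",
    "stages": [
        "generate", "ais", "connectivity", "stats", "motifs",
        "synapse-stats", "simulate", "activity",
    ],
    "population": {},  # PopulationParams overrides
    "activity": {},  # ActivityParams overrides
    "threshold": 7.5,
    "ica_restarts": 25,
    "motif_shuffles": 200,
    "simulate_scale": "demo",  # demo keeps run-all fast; "full" = study sizes
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(stage: str, *paths):
    for p in paths:
        if not Path(p).exists():
            raise PipelineError(stage, f"missing input {p}")


def run_pipeline(config: dict | None = None) -> dict:
    """Run the configured stages; returns a manifest of outputs.

    The manifest maps relative output paths to SHA-256 checksums and is
    also written to ``manifest.json`` in the output directory.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    produced: list[Path] = []
    timings = {}

    def stage_enabled(name):
        return name in cfg["stages"]

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:  # halt with a typed error naming the stage
            raise PipelineError(name, str(exc)) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, timings[name])

    if stage_enabled("generate"):
        def _generate():
            params = PopulationParams(**{**cfg["population"], "seed": seed})
            cells, ais_domains, axons, synapses, network = (
                generate_structural_population(params)
            )
            cells.to_csv(out / "cells.csv", index=False)
            synapses.to_csv(out / "synapses.csv", index=False)
            io.write_ais_domains(ais_domains, out / "ais_domains.csv")
            produced.extend(io.write_axons_swc(axons, out / "axons"))
            io.write_network(network, out / "network.json")
            aparams = ActivityParams(**{**cfg["activity"], "seed": seed})
            bundle = generate_activity(aparams)
            traces = pd.DataFrame(
                bundle.traces.T,
                columns=[f"cell_{i}" for i in range(bundle.traces.shape[0])],
            )
            traces["pupil"] = bundle.pupil
            traces["locomotion"] = bundle.locomotion
            traces.to_csv(out / "traces.csv", index=False)
            with open(out / "params.json", "w") as fh:
                json.dump(
                    {
                        "population": params.__dict__,
                        "activity": aparams.__dict__,
                        # outdir omitted: implied by location, and keeping
                        # the echo path-free makes reruns checksum-identical
                        "config": {k: v for k, v in cfg.items()
                                   if k not in ("population", "activity",
                                                "outdir")},
                    },
                    fh, indent=2, default=str,
                )
            produced.extend(
                out / n
                for n in ["cells.csv", "synapses.csv", "ais_domains.csv",
                          "network.json", "traces.csv", "params.json"]
            )
        run_stage("generate", _generate)

    if stage_enabled("ais"):
        def _ais():
            _require("ais", out / "ais_domains.csv", out / "synapses.csv")
            from .ais import synapse_coordinates, truncate_ais

            domains = io.read_ais_domains(out / "ais_domains.csv")
            synapses = pd.read_csv(out / "synapses.csv")
            rows = []
            for d in domains:
                sub = synapses[synapses["cell_id"] == d.cell_id]
                if not len(sub):
                    continue
                coords = synapse_coordinates(
                    truncate_ais(d, cutoff=max(d.arclength.max(), 37.0)),
                    sub[["x", "y", "z"]].to_numpy(float),
                    synapse_ids=sub["synapse_id"].tolist(),
                )
                for c in coords:
                    rows.append(
                        {
                            "synapse_id": c.synapse_id,
                            "ais_id": d.cell_id,
                            "depth": c.depth,
                            "orientation": c.orientation,
                            "degenerate": c.degenerate,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "synapse_coords.csv", index=False)
            produced.append(out / "synapse_coords.csv")
        run_stage("ais", _ais)

    if stage_enabled("connectivity"):
        def _connectivity():
            _require("connectivity", out / "axons", out / "ais_domains.csv",
                     out / "synapses.csv")
            domains = io.read_ais_domains(out / "ais_domains.csv")
            axons = io.read_axons_swc(out / "axons")
            synapses = pd.read_csv(out / "synapses.csv")
            pot = potential_connections(axons, domains, cfg["threshold"])
            chc = synapses[synapses["source_class"] == "chc"]
            conns = (
                chc.groupby(["axon_id", "cell_id"]).size()
                .rename("n_synapses").reset_index()
            )
            summary = decompose(conns, pot)
            summary.to_csv(out / "connection_summary.csv")
            pd.DataFrame(sorted(pot.edges()), columns=["axon_id", "cell_id"]
                         ).to_csv(out / "potential_edges.csv", index=False)
            produced.extend(
                [out / "connection_summary.csv", out / "potential_edges.csv"]
            )
        run_stage("connectivity", _connectivity)

    if stage_enabled("stats"):
        def _stats():
            _require("stats", out / "cells.csv", out / "connection_summary.csv")
            cells = pd.read_csv(out / "cells.csv")
            feats = cells[FEATURE_COLUMNS]
            r, padj = correlation_screen(feats)
            model = fit_components(feats, restarts=cfg["ica_restarts"],
                                   seed=seed)
            fit = regress_on_components(cells["chc_syn_count"], model.scores)
            pd.DataFrame(
                model.mixing, index=FEATURE_COLUMNS,
                columns=model.labels,
            ).to_csv(out / "components.csv")
            with open(out / "regression.json", "w") as fh:
                json.dump(
                    {
                        "coef": fit.coef.tolist(),
                        "conf_int": fit.conf_int.tolist(),
                        "pvalues": fit.pvalues.tolist(),
                        "pvalues_adjusted": fit.pvalues_adjusted.tolist(),
                        "r_squared": fit.r_squared,
                        "correlation_matrix": r.to_dict(),
                        "correlation_p_adjusted": padj.to_dict(),
                    },
                    fh, indent=2,
                )
            produced.extend([out / "components.csv", out / "regression.json"])
        run_stage("stats", _stats)

    if stage_enabled("motifs"):
        def _motifs():
            _require("motifs", out / "network.json")
            net = io.read_network(out / "network.json")
            axon_ids = sorted({a for a, _ in net["potential"]})
            cell_ids = sorted({c for _, c in net["potential"]})
            network = BipartiteNetwork(
                axon_ids, cell_ids, set(net["potential"]), set(net["actual"])
            )
            res = motif_null_test(
                network, alpha=1.0, n_shuffles=cfg["motif_shuffles"], seed=seed
            )
            pd.DataFrame({"null_bifan_fraction": res.null}).to_csv(
                out / "null_distributions.csv", index=False
            )
            with open(out / "motif_test.json", "w") as fh:
                json.dump(
                    {"observed": res.observed, "p_gt": res.p_gt,
                     "p_lt": res.p_lt, "p_two_sided": res.p_two_sided},
                    fh, indent=2,
                )
            produced.extend(
                [out / "null_distributions.csv", out / "motif_test.json"]
            )
        run_stage("motifs", _motifs)

    if stage_enabled("synapse-stats"):
        def _synstats():
            _require("synapse-stats", out / "synapses.csv")
            synapses = pd.read_csv(out / "synapses.csv")
            chc = synapses[synapses["source_class"] == "chc"]
            sizes = chc.groupby(["axon_id", "cell_id"]).size().to_numpy()
            fit = fit_connection_size(sizes)
            with open(out / "geometric_fit.json", "w") as fh:
                json.dump(
                    {"p": fit.p, "implied_mean": fit.implied_mean, "n": fit.n,
                     "gof_pvalue": fit.gof_pvalue}, fh, indent=2,
                )
            produced.append(out / "geometric_fit.json")
        run_stage("synapse-stats", _synstats)

    if stage_enabled("simulate"):
        def _simulate():
            neuron = SurrogateNeuron()
            demo = cfg["simulate_scale"] == "demo"
            fi = run_fi_experiment(
                neuron,
                n_syn_values=(9,) if demo else (9, 15),
                exc_rates=(0.0, 250.0, 500.0) if demo
                else (0.0, 100.0, 200.0, 300.0, 400.0, 500.0),
                reps=4 if demo else 8,
                seed=seed,
            )
            fi.table.to_csv(out / "fi_table.csv", index=False)
            offs = run_offset_experiment(
                neuron,
                offsets=(-0.1, 0.0, 0.1) if demo
                else tuple(np.arange(-0.1, 0.1001, 0.005)),
                reps=4 if demo else 10,
                seed=seed,
            )
            offs.table.to_csv(out / "offset_table.csv", index=False)
            offs.comparisons.to_csv(out / "offset_der.csv", index=False)
            produced.extend(
                [out / "fi_table.csv", out / "offset_table.csv",
                 out / "offset_der.csv"]
            )
        run_stage("simulate", _simulate)

    if stage_enabled("activity"):
        def _activity():
            _require("activity", out / "traces.csv")
            df = pd.read_csv(out / "traces.csv")
            cell_cols = [c for c in df.columns if c.startswith("cell_")]
            traces = df[cell_cols].to_numpy(float).T
            pw = pairwise_correlations(traces)
            beh = behavior_correlations(
                traces,
                {"pupil": df["pupil"].to_numpy(),
                 "locomotion": df["locomotion"].to_numpy()},
            )
            pw.to_csv(out / "correlations.csv", index=False)
            beh.to_csv(out / "behavior_correlations.csv", index=False)
            produced.extend(
                [out / "correlations.csv", out / "behavior_correlations.csv"]
            )
        run_stage("activity", _activity)

    manifest = {
        "version": __version__,
        "seed": seed,
        "timings": timings,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(produced))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def validate_inputs(paths: dict) -> list[dict]:
    """Schema checks for the file interfaces; returns a list of issues.

    ``paths`` maps kind ("cells", "synapses", "swc", "network",
    "ais_domains", "traces") to a file path. Report-only: never raises for
    content problems.
    """
    issues = []

    def add(path, message):
        issues.append({"path": str(path), "issue": message})

    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            add(p, "file does not exist")
            continue
        try:
            if kind == "cells":
                df = pd.read_csv(p)
                for col in ["cell_id", *FEATURE_COLUMNS]:
                    if col not in df.columns:
                        add(p, f"missing column {col!r}")
            elif kind == "synapses":
                df = pd.read_csv(p)
                for col in ["synapse_id", "axon_id", "cell_id", "x", "y", "z"]:
                    if col not in df.columns:
                        add(p, f"missing column {col!r}")
                if "cells" in paths and Path(paths["cells"]).exists():
                    known = set(pd.read_csv(paths["cells"])["cell_id"])
                    unknown = set(df["cell_id"]) - known
                    for cid in sorted(unknown):
                        add(p, f"synapse references unknown cell id {cid}")
            elif kind == "swc":
                rows = []
                for line in p.read_text().splitlines():
                    line = line.strip()
                    if line and not line.startswith("#"):
                        rows.append(line.split())
                ids = {int(r[0]) for r in rows}
                for r in rows:
                    parent = int(r[6])
                    if parent != -1 and parent not in ids:
                        add(p, f"orphan node {r[0]} (parent {parent} missing)")
            elif kind == "network":
                net = io.read_network(p)
                if not set(net["actual"]) <= set(net["potential"]):
                    add(p, "actual edges not a subset of potential edges")
            elif kind == "ais_domains":
                df = pd.read_csv(p)
                for col in ["cell_id", "x", "y", "z", "radius", "arclength"]:
                    if col not in df.columns:
                        add(p, f"missing column {col!r}")
            elif kind == "traces":
                df = pd.read_csv(p)
                if not any(c.startswith("cell_") for c in df.columns):
                    add(p, "no cell_* trace columns")
        except Exception as exc:
            add(p, f"unreadable: {exc}")
    return issues
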