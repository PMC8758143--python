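# chandelier

Analysis pipeline for chandelier-cell (ChC) input onto the axon initial
segments (AIS) of layer 2/3 pyramidal neurons (PyCs), as measured in dense
electron-microscopy reconstructions: synapse census and connection-size
statistics, geometry-aware connectivity decomposition, structural-components
regression, co-targeting motif null models, inhibition-scenario simulation
on a surrogate neuron, and in vivo activity-correlation statistics — plus a
synthetic-data generator so every stage is testable without any download.

## Who this is for

Connectomics and circuits researchers who want to reuse (or stress-test) the
statistical machinery behind AIS-innervation analyses: how variable is
axo-axonic input across a PyC population, which structural properties of the
target cell predict it, and whether ChC axons co-target cells beyond what
their geometry already imposes.

## The models at the core

**Input decomposition.** Per-cell ChC synapse count factors as

    N_syn = mu_con * N_con        N_con = N_pot * f_con

where `mu_con` is mean synapses per connection, `N_pot` counts *potential*
connections (axon/AIS pairs approaching within a distance threshold, default
7.5 µm), and `f_con` is the fraction of potential partners actually
connected. Connection sizes follow a support-1 geometric law,
`P(k) = p (1-p)^(k-1)`, with MLE `p = 1/mean` (reference value p = 0.44,
mean 2.3 synapses per connection).

**Structural components.** Six perisomatic features (depth, AIS radius,
non-ChC AIS synapse count, soma synapse density, soma area, soma synapse
count) are z-scored and decomposed with a 3-component ICA (restart-robust
FastICA, components signed so the largest loading is positive);
standardized OLS of `N_syn` on the uncorrelated component scores gives
interpretable coefficients whose squares sum to R².

**Motif null.** On the bipartite ChC→PyC graph, the bifan connectivity
fraction (probability that the fourth edge of a potential bifan is actual)
is compared against degree-preserving shuffles confined to the potential
graph; a bias weight α on bifan-completing candidates generates
(anti-)clustered networks for power analysis.

**Inhibition scenarios.** Synchronous / biologically-inspired /
asynchronous activation of AIS synapses (100 Hz Poisson trains shared per
cluster) and Gaussian-profile excitation/inhibition barrages (peaks 500/200
Hz) drive a two-compartment conductance-based integrate-and-fire neuron;
the differential effect ratio `(N_soma - N_AIS) / (N_soma + N_AIS)`
quantifies where inhibition bites hardest.

## Worked example

```python
import numpy as np
from chandelier.synthetic import load_preset, generate_structural_population
from chandelier.structural import FEATURE_COLUMNS, fit_components, regress_on_components
from chandelier.synapses import fit_connection_size, ais_input_summary

params = load_preset("paper")        # calibrated study conditions, n=113
params.seed = 7
cells, ais_domains, axons, synapses, network = generate_structural_population(params)

chc = synapses[synapses.source_class == "chc"]
print(ais_input_summary(chc, n_cells=params.n_cells))
sizes = chc.groupby(["axon_id", "cell_id"]).size().to_numpy()
fit = fit_connection_size(sizes)
print(f"geometric p = {fit.p:.3f}, mean synapses/connection = {fit.implied_mean:.2f}")

model = fit_components(cells[FEATURE_COLUMNS], k=3, restarts=25, seed=0)
reg = regress_on_components(cells["chc_syn_count"], model.scores)
for lab, c in zip(model.labels, np.round(reg.coef, 3)):
    print(lab, c)
print(f"R^2 = {reg.r_squared:.3f}")
```

prints (component order/sign is the usual ICA indeterminacy; labels name
the dominant feature):

```
{'mean_chc_synapses_per_ais': 8.575221238938052, 'mean_chc_axons_per_ais': 3.495575221238938, 'n_cells': 113}
geometric p = 0.408, mean synapses/connection = 2.45
component_0:soma_syn_density 0.248
component_1:ais_radius 0.437
component_2:depth -0.524
R^2 = 0.528
```

Read: at this seed each AIS receives ~8.6 ChC synapses from ~3.5 axons;
connection sizes are geometric with p ≈ 0.41 (≈2.4 synapses per
connection); deeper cells receive fewer ChC synapses while larger and more
perisomatically inhibited cells receive more, the three components together
explaining ~53% of the variance in synapse count. Averaged over seeds these
quantities sit at the preset's calibration points (p = 0.44, R² ≈ 45%,
coefficients ≈ (-0.47, +0.33, +0.34)).

A command-line interface mirrors the stages:

```bash
chandelier run-all --seed 7 --outdir out/
chandelier connectivity --threshold 7.5 --outdir out/
chandelier validate --cells out/cells.csv --synapses out/synapses.csv
```

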