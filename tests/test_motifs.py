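"""Bifan fraction, degree-preserving shuffles, null tests, and power."""

import itertools

import numpy as np
import pytest

from chandelier.motifs import (
    BipartiteNetwork,
    ShuffleConfig,
    bifan_connectivity_fraction,
    motif_null_test,
    power_analysis,
    shuffle_network,
)


def brute_force_bifan_fraction(net: BipartiteNetwork) -> float:
    """O(n^4) oracle: enumerate all (a, a', c, c') quadruples."""
    num_edges, den_edges = set(), set()
    for a, a2 in itertools.permutations(net.axon_ids, 2):
        for c, c2 in itertools.permutations(net.cell_ids, 2):
            if (
                (a, c) in net.potential
                and (a, c2) in net.actual
                and (a2, c) in net.actual
                and (a2, c2) in net.actual
            ):
                den_edges.add((a, c))
                if (a, c) in net.actual:
                    num_edges.add((a, c))
    if not den_edges:
        return float("nan")
    return len(num_edges) / len(den_edges)


def random_network(rng, n_axons=20, n_cells=20, p_pot=0.3, p_act=0.5):
    potential = {
        (a, c)
        for a in range(n_axons)
        for c in range(n_cells)
        if rng.random() < p_pot
    }
    actual = {e for e in potential if rng.random() < p_act}
    return BipartiteNetwork(
        list(range(n_axons)), list(range(n_cells)), potential, actual
    )


class TestBifanFraction:
    def test_two_by_two_missing_edge(self):
        potential = {(0, 0), (0, 1), (1, 0), (1, 1)}
        actual = {(0, 0), (0, 1), (1, 0)}
        net = BipartiteNetwork([0, 1], [0, 1], potential, actual)
        assert bifan_connectivity_fraction(net) == 0.0
        net2 = BipartiteNetwork([0, 1], [0, 1], potential, set(potential))
        assert bifan_connectivity_fraction(net2) == 1.0

    def test_no_bifans_is_undefined(self):
        net = BipartiteNetwork([0], [0], {(0, 0)}, {(0, 0)})
        assert np.isnan(bifan_connectivity_fraction(net))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            net = random_network(rng)
            got = bifan_connectivity_fraction(net)
            want = brute_force_bifan_fraction(net)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, 12, 12)
        perm_a = dict(zip(net.axon_ids, rng.permutation(net.axon_ids)))
        perm_c = dict(zip(net.cell_ids, rng.permutation(net.cell_ids)))
        relabeled = BipartiteNetwork(
            net.axon_ids,
            net.cell_ids,
            {(perm_a[a], perm_c[c]) for a, c in net.potential},
            {(perm_a[a], perm_c[c]) for a, c in net.actual},
        )
        assert bifan_connectivity_fraction(relabeled) == pytest.approx(
            bifan_connectivity_fraction(net)
        )


class TestShuffle:
    def test_single_potential_partner_pins_the_edge(self):
        net = BipartiteNetwork([0], [0, 1], {(0, 0), (0, 1)}, {(0, 0)})
        out = shuffle_network(net, ShuffleConfig(alpha=7.0, seed=0))
        assert out == {(0, 0)}

    def test_target_degrees_preserved_and_within_potential(self):
        rng = np.random.default_rng(29)
        for trial in range(5):
            net = random_network(rng, 15, 15)
            out = shuffle_network(net, ShuffleConfig(seed=trial))
            assert out <= net.potential
            before = net.target_degrees()
            after = {c: 0 for c in net.cell_ids}
            for _, c in out:
                after[c] += 1
            assert before == after

    def test_positive_degree_without_potential_rejected(self):
        with pytest.raises(ValueError):
            BipartiteNetwork([0], [0], set(), {(0, 0)})

    def test_uniform_shuffle_matches_enumeration_on_small_network(self):
        """alpha=1 occupancy matches uniform degree-feasible configurations.

        3 axons x 2 cells, cell 0 potential {0,1,2} degree 1, cell 1
        potential {0,1} degree 1: 6 equally likely configurations, so each
        cell-0 edge occurs w.p. 1/3 and each cell-1 edge w.p. 1/2.
        """
        potential = {(0, 0), (1, 0), (2, 0), (0, 1), (1, 1)}
        actual = {(0, 0), (1, 1)}
        net = BipartiteNetwork([0, 1, 2], [0, 1], potential, actual)
        counts = {e: 0 for e in potential}
        n_shuffles = 6000
        ss = np.random.SeedSequence(31)
        for child in ss.spawn(n_shuffles):
            out = shuffle_network(
                net,
                ShuffleConfig(seed=int(child.generate_state(1)[0] % 2**31)),
            )
            for e in out:
                counts[e] += 1
        for c, expected in ((0, 1 / 3), (1, 1 / 2)):
            for a in range(3):
                if (a, c) not in potential:
                    continue
                freq = counts[(a, c)] / n_shuffles
                sigma = np.sqrt(expected * (1 - expected) / n_shuffles)
                assert abs(freq - expected) < 4 * sigma


class TestNullTest:
    def test_identical_seed_identical_null(self):
        rng = np.random.default_rng(37)
        net = random_network(rng, 10, 10)
        a = motif_null_test(net, n_shuffles=120, seed=5)
        b = motif_null_test(net, n_shuffles=120, seed=5)
        assert np.array_equal(a.null, b.null)
        assert a.p_gt == b.p_gt

    def test_p_bounds_consistency(self):
        rng = np.random.default_rng(41)
        net = random_network(rng, 12, 12)
        res = motif_null_test(net, n_shuffles=150, seed=2)
        assert 0 <= res.p_gt <= 1 and 0 <= res.p_lt <= 1
        assert res.p_gt + res.p_lt >= 1.0 - 1e-12

    def test_mean_null_matches_density_expectation_small_instance(self):
        """On an enumerable instance the alpha=1 null mean bifan fraction
        tracks the unbiased configuration average."""
        potential = {(a, c) for a in range(3) for c in range(3)}
        actual = {(0, 0), (1, 0), (0, 1), (1, 1), (2, 2)}
        net = BipartiteNetwork(list(range(3)), list(range(3)), potential,
                               actual)
        # oracle: average fraction over all degree-feasible configurations
        degs = net.target_degrees()
        per_cell_choices = [
            list(itertools.combinations(range(3), degs[c])) for c in range(3)
        ]
        fracs = []
        for combo in itertools.product(*per_cell_choices):
            conf = {
                (a, c) for c, axons in enumerate(combo) for a in axons
            }
            f = bifan_connectivity_fraction(
                BipartiteNetwork(net.axon_ids, net.cell_ids, potential, conf)
            )
            if np.isfinite(f):
                fracs.append(f)
        oracle_mean = np.mean(fracs)
        res = motif_null_test(net, n_shuffles=400, seed=3)
        null_mean = np.nanmean(res.null)
        assert abs(null_mean - oracle_mean) < 0.08


class TestBiasAndPower:
    def test_alpha5_yields_more_bifans_than_alpha1(self):
        """Monte-Carlo: biased shuffles raise the mean bifan fraction."""
        rng = np.random.default_rng(43)
        net = random_network(rng, 25, 25, p_pot=0.3, p_act=0.4)
        means = {}
        for alpha in (1.0, 5.0):
            vals = []
            ss = np.random.SeedSequence(int(alpha * 100))
            for child in ss.spawn(60):
                out = shuffle_network(
                    net,
                    ShuffleConfig(
                        alpha=alpha,
                        seed=int(child.generate_state(1)[0] % 2**31),
                    ),
                )
                vals.append(
                    bifan_connectivity_fraction(
                        BipartiteNetwork(net.axon_ids, net.cell_ids,
                                         net.potential, out)
                    )
                )
            means[alpha] = np.nanmean(vals)
        assert means[5.0] > means[1.0]

    def test_power_monotone_and_calibrated(self):
        """Rejection ~5% at alpha=1; power grows with |log alpha|."""
        rng = np.random.default_rng(47)
        net = random_network(rng, 20, 24, p_pot=0.35, p_act=0.45)
        table = power_analysis(
            net, alpha_grid=(0.1, 1.0, 8.0), n_shuffles=100,
            n_replicates=16, seed=11,
        )
        by_alpha = dict(zip(table["alpha"], table["rejection_rate"]))
        assert by_alpha[1.0] <= 0.25  # calibration (binomial noise, 16 reps)
        assert by_alpha[0.1] >= by_alpha[1.0]
        assert by_alpha[8.0] >= by_alpha[1.0]
        assert max(by_alpha[0.1], by_alpha[8.0]) >= 0.5
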