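import numpy as np
import pytest

import pollendiv as pv
from pollendiv.errors import InfeasibleSamplingError, InputError, SimulationAbortError
from pollendiv.sse_core import SSEParameters
from pollendiv.simulate import (
    SimConfig,
    apply_incomplete_sampling,
    generate_synthetic_pollen_dataset,
    prune_to_tips,
    samples_to_frame,
    simulate_bisse_tree,
    simulate_mk_traits,
    state_specific_rho,
)
from pollendiv.trees import validate_ultrametric


def yule_config(seed, stop, lam=0.1):
    return SimConfig(
        params=SSEParameters.bisse(lam, lam, 0.0, 0.0, 0.0, 0.0),
        stop=stop,
        seed=seed,
        min_surviving_tips=2,
    )


class TestTreeSimulation:
    def test_no_transitions_all_tips_root_state(self):
        cfg = SimConfig(
            params=SSEParameters.bisse(0.2, 0.2, 0.0, 0.0, 0.0, 0.0),
            stop=("n_tips", 30),
            seed=1,
            root_state=0,
        )
        rep = simulate_bisse_tree(cfg)
        assert set(rep.tip_states.values()) == {0}

    def test_reproducible_given_seed(self):
        cfg = SimConfig(
            params=SSEParameters.bisse(0.1, 0.2, 0.02, 0.02, 0.03, 0.03),
            stop=("n_tips", 25),
            seed=9,
        )
        r1 = simulate_bisse_tree(cfg)
        r2 = simulate_bisse_tree(cfg)
        assert r1.tree.newick() == r2.tree.newick()
        assert r1.tip_states == r2.tip_states

    def test_n_tips_stop_reaches_target(self):
        rep = simulate_bisse_tree(yule_config(3, ("n_tips", 40)))
        assert rep.tree.n_tips == 40

    def test_trees_are_ultrametric(self):
        for seed in (1, 2, 3):
            rep = simulate_bisse_tree(yule_config(seed, ("n_tips", 20)))
            assert validate_ultrametric(rep.tree, rel_tol=1e-9).passed

    def test_yule_crown_expectation(self):
        # crown process, lam = 0.1, t = 10: E[tips] = 2 e; sample mean over
        # 200 replicates must sit within 3 standard errors
        counts = [
            simulate_bisse_tree(yule_config(1000 + i, ("time", 10.0))).tree.n_tips
            for i in range(200)
        ]
        m = np.e  # e^{lam t} per crown lineage
        expected = 2 * m
        var = 2 * m * (m - 1)  # geometric offspring count per lineage
        se = np.sqrt(var / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_symmetric_rates_give_balanced_frequencies(self):
        freqs = []
        for seed in range(30):
            cfg = SimConfig(
                params=SSEParameters.bisse(0.15, 0.15, 0.0, 0.0, 0.05, 0.05),
                stop=("n_tips", 60),
                seed=400 + seed,
            )
            rep = simulate_bisse_tree(cfg)
            freqs.append(np.mean(list(rep.tip_states.values())))
        assert abs(np.mean(freqs) - 0.5) < 0.1

    def test_hopeless_regime_aborts(self):
        cfg = SimConfig(
            params=SSEParameters.bisse(0.01, 0.01, 5.0, 5.0, 0.0, 0.0),
            stop=("n_tips", 50),
            seed=2,
            max_attempts=20,
        )
        with pytest.raises(SimulationAbortError):
            simulate_bisse_tree(cfg)


class TestMkTraitSimulation:
    def test_zero_rates_keep_root_state(self, sim_replicate_50):
        states = simulate_mk_traits(sim_replicate_50.tree, 0.0, 0.0, root_state=0)
        assert set(states.values()) == {0}

    def test_expected_change_count_is_poisson(self, sim_replicate_50):
        # small q: E[# flips] ~ q * total tree length
        tree = sim_replicate_50.tree
        q = 0.005
        expected = 2 * q * tree.total_branch_length  # flips in both directions
        # count flips via parent/child state mismatches over many replicates
        n_rep = 100
        total = 0
        for seed in range(n_rep):
            states = simulate_mk_traits(tree, q, q, root_state=0, seed=seed)
            total += sum(states.values())  # tips that end flipped (odd # flips)
        # for small expected flip counts, P(tip odd) ~ q * depth
        depth = tree.height
        p_tip_flipped = q * 2 * depth / 2  # symmetric two-state small-rate
        exp_tips = tree.n_tips * p_tip_flipped
        se = np.sqrt(n_rep * tree.n_tips * p_tip_flipped) / n_rep
        assert abs(total / n_rep - exp_tips) < 4 * se + 0.5

    def test_stationary_frequency_on_long_tree(self):
        cfg = yule_config(5, ("n_tips", 200), lam=0.3)
        tree = simulate_bisse_tree(cfg).tree
        ones = []
        for seed in range(40):
            states = simulate_mk_traits(tree, q01=0.9, q10=0.3, seed=seed)
            ones.append(np.mean(list(states.values())))
        assert np.mean(ones) == pytest.approx(0.75, abs=0.08)


class TestIncompleteSampling:
    def test_equal_fraction_recovers_global_rho(self):
        # f equal to the sampled accessible share: both rho ~ 89/397
        n0, n1 = 40, 49
        fr = state_specific_rho(n0, n1, 397, f=n0 / 89)
        assert fr.rho[0] == pytest.approx(89 / 397)
        assert fr.rho[1] == pytest.approx(89 / 397)

    def test_arithmetic_example(self):
        fr = state_specific_rho(40, 49, 397, f=0.5)
        assert fr.rho[0] == pytest.approx(40 / (40 + 154))
        assert fr.rho[1] == pytest.approx(49 / (49 + 154))

    def test_f_zero_means_all_unsampled_restricted(self):
        fr = state_specific_rho(40, 49, 397, f=0.0)
        assert fr.rho[0] == 1.0
        assert fr.rho[1] < 1.0

    def test_f_out_of_range(self):
        with pytest.raises(InputError):
            state_specific_rho(40, 49, 397, f=1.2)

    def test_overfull_sampling_rejected(self):
        with pytest.raises(InfeasibleSamplingError):
            state_specific_rho(300, 200, 397, f=0.5)

    def test_pruning_path(self):
        cfg = SimConfig(
            params=SSEParameters.bisse(0.15, 0.15, 0.0, 0.0, 0.05, 0.05),
            stop=("n_tips", 60),
            seed=77,
        )
        rep = simulate_bisse_tree(cfg)
        pruned, fr = apply_incomplete_sampling(
            rep, total_richness=120, f=0.5, n_keep=40, seed=1
        )
        assert pruned.tree.n_tips == 40
        assert validate_ultrametric(pruned.tree, rel_tol=1e-9).passed
        assert set(pruned.tip_states) == set(pruned.tree.tip_labels)
        n0 = sum(1 for s in pruned.tip_states.values() if s == 0)
        expect = state_specific_rho(n0, 40 - n0, 120, 0.5)
        assert np.allclose(fr.rho, expect.rho)
        assert fr.f == 0.5

    def test_infeasible_composition(self):
        cfg = SimConfig(
            params=SSEParameters.bisse(0.2, 0.2, 0.0, 0.0, 0.0, 0.0),
            stop=("n_tips", 30),
            seed=3,
            root_state=0,
        )
        rep = simulate_bisse_tree(cfg)  # all tips state 0
        with pytest.raises(InfeasibleSamplingError):
            # f = 0 asks to drop only state-1 tips, none exist
            apply_incomplete_sampling(rep, total_richness=60, f=0.0, n_keep=10)

    def test_prune_to_tips_preserves_patristic_distances(self, sim_replicate_50):
        tree = sim_replicate_50.tree
        keep = list(tree.tip_labels[::5])
        sub = prune_to_tips(tree, keep)
        assert set(sub.tip_labels) == set(keep)
        assert validate_ultrametric(sub, rel_tol=1e-9).passed

        def pairwise(t, a, b):
            ia, ib = t.tip_index(a), t.tip_index(b)
            depths = t.depths()
            # walk both to the root collecting ancestors
            anc = {}
            node = ia
            while node != -1:
                anc[node] = depths[node]
                node = int(t.parent[node])
            node = ib
            while node not in anc:
                node = int(t.parent[node])
            return (depths[ia] - anc[node]) + (depths[ib] - anc[node])

        for a, b in [(keep[0], keep[1]), (keep[2], keep[-1]), (keep[0], keep[-1])]:
            assert pairwise(sub, a, b) == pytest.approx(pairwise(tree, a, b), rel=1e-9)


class TestPollenGenerator:
    def test_deterministic_output(self):
        truth = {"sp1": "A", "sp2": "R", "sp3": "AR"}
        s1, _ = generate_synthetic_pollen_dataset(truth, (1, 5), seed=13)
        s2, _ = generate_synthetic_pollen_dataset(truth, (1, 5), seed=13)
        assert samples_to_frame(s1).to_csv(index=False) == samples_to_frame(
            s2
        ).to_csv(index=False)

    def test_contaminants_stay_below_filter(self):
        truth = {f"sp{i}": "A" for i in range(20)}
        samples, catalog = generate_synthetic_pollen_dataset(truth, (1, 4), seed=2)
        for s in samples:
            total = sum(s.composition.values())
            for t, pct in s.composition.items():
                if catalog.accessibility(t) == "restricted":
                    assert pct / total < 0.05

    def test_sample_counts_in_range(self):
        truth = {f"sp{i}": "R" for i in range(30)}
        samples, _ = generate_synthetic_pollen_dataset(truth, (2, 6), seed=4)
        per_species = {}
        for s in samples:
            per_species[s.species] = per_species.get(s.species, 0) + 1
        assert all(2 <= n <= 6 for n in per_species.values())

    def test_excessive_contamination_rejected(self):
        with pytest.raises(InputError):
            generate_synthetic_pollen_dataset({"sp": "A"}, contamination_max=0.06)

    def test_bad_state_rejected(self):
        with pytest.raises(InputError):
            generate_synthetic_pollen_dataset({"sp": "B"})
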