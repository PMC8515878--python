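import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import pollendiv as pv
from pollendiv.errors import InputError
from pollendiv.mk import (
    MkMcmcSettings,
    MkModel,
    asr_marginal_posteriors,
    default_rate_prior_mean,
    mk_loglik,
    mk_marginal_posteriors_fixed,
    node_bayes_factor,
    parsimony_change_count,
    transition_matrix,
)
from pollendiv.pollen import CharacterMatrix


def chars_of(**states):
    return CharacterMatrix("PA2", states)


def brute_force_loglik(tree, chars, model):
    """Enumerate internal-node states; P(t) by scipy matrix exponential."""
    Q = np.array([[-model.q01, model.q01], [model.q10, -model.q10]])
    P = [expm(Q * tree.blen[i]) for i in range(tree.n_nodes)]
    codes = chars.state_codes(tree.tip_labels)
    internals = [int(x) for x in tree.postorder]
    prior = model.root_probs()
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for tip_states in itertools.product([0, 1], repeat=tree.n_tips):
            ok = all(codes[i] == 2 or codes[i] == tip_states[i] for i in range(tree.n_tips))
            if not ok:
                continue
            p = prior[amap[tree.root]]
            for i in range(tree.n_nodes):
                if i == tree.root:
                    continue
                s_par = amap[int(tree.parent[i])]
                s_i = tip_states[i] if i < tree.n_tips else amap[i]
                p *= P[i][s_par, s_i]
            total += p
    return np.log(total) if total > 0 else -np.inf


class TestMkLoglik:
    def test_zero_rates_identical_tips(self, cherry):
        ll = mk_loglik(cherry, chars_of(A="0", B="0"), MkModel(0.0, 0.0))
        assert ll == pytest.approx(np.log(0.5))

    def test_zero_rates_impossible_data(self, cherry):
        ll = mk_loglik(cherry, chars_of(A="0", B="1"), MkModel(0.0, 0.0))
        assert ll == -np.inf

    def test_negative_rates_rejected(self):
        with pytest.raises(InputError):
            MkModel(-0.1, 0.2)

    @pytest.mark.parametrize("q01,q10", [(0.1, 0.1), (0.3, 0.05), (1.5, 0.7)])
    def test_matches_enumeration_three_tips(self, q01, q10):
        t = pv.read_tree("((A:1,B:1):1,C:2);")
        for states in [dict(A="0", B="1", C="1"), dict(A="1", B="1", C="0")]:
            m = MkModel(q01, q10)
            assert mk_loglik(t, chars_of(**states), m) == pytest.approx(
                brute_force_loglik(t, chars_of(**states), m), abs=1e-10
            )

    def test_ambiguous_tip_matches_enumeration(self, quartet):
        m = MkModel(0.4, 0.2)
        ch = chars_of(A="0", B="ambiguous", C="1", D="missing")
        assert mk_loglik(quartet, ch, m) == pytest.approx(
            brute_force_loglik(quartet, ch, m), abs=1e-10
        )

    def test_label_swap_symmetry(self, quartet):
        ch = chars_of(A="0", B="0", C="1", D="1")
        swapped = chars_of(A="1", B="1", C="0", D="0")
        assert mk_loglik(quartet, ch, MkModel(0.3, 0.07)) == pytest.approx(
            mk_loglik(quartet, swapped, MkModel(0.07, 0.3)), abs=1e-12
        )

    def test_transition_matrix_is_expm(self):
        P = transition_matrix(0.3, 0.12, 2.5)
        Q = np.array([[-0.3, 0.3], [0.12, -0.12]])
        assert np.allclose(P, expm(Q * 2.5), atol=1e-12)


class TestMarginals:
    def test_rows_sum_to_one(self, quartet):
        marg = mk_marginal_posteriors_fixed(
            quartet, chars_of(A="0", B="0", C="1", D="1"), MkModel(0.3, 0.2)
        )
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)

    def test_node_marginals_match_enumeration(self, quartet):
        model = MkModel(0.35, 0.15)
        ch = chars_of(A="0", B="0", C="1", D="1")
        marg = mk_marginal_posteriors_fixed(quartet, ch, model)
        Q = np.array([[-0.35, 0.35], [0.15, -0.15]])
        P = [expm(Q * quartet.blen[i]) for i in range(quartet.n_nodes)]
        codes = {i: int(ch.states[quartet.tip_labels[i]]) for i in range(4)}
        internals = [int(x) for x in quartet.postorder]
        joint = {n: np.zeros(2) for n in internals}
        for assign in itertools.product([0, 1], repeat=len(internals)):
            amap = dict(zip(internals, assign))
            p = 0.5
            for i in range(quartet.n_nodes):
                if i == quartet.root:
                    continue
                s_par = amap[int(quartet.parent[i])]
                s_i = codes[i] if i < 4 else amap[i]
                p *= P[i][s_par, s_i]
            for n in internals:
                joint[n][amap[n]] += p
        for n in internals:
            expected = joint[n] / joint[n].sum()
            assert np.allclose(marg[n], expected, atol=1e-10)

    def test_symmetric_cherry_root_is_half(self, cherry):
        marg = mk_marginal_posteriors_fixed(
            cherry, chars_of(A="0", B="1"), MkModel(0.2, 0.2)
        )
        assert marg[cherry.root] == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_fixed_rate_mcmc_path_equals_analytic(self, quartet):
        ch = chars_of(A="0", B="0", C="1", D="1")
        res = asr_marginal_posteriors(
            quartet, ch, MkMcmcSettings(fixed_rates=(0.3, 0.2))
        )
        marg = mk_marginal_posteriors_fixed(quartet, ch, MkModel(0.3, 0.2))
        assert np.allclose(res.node_posteriors, marg, atol=1e-12)

    def test_all_tips_state0_posteriors_favor_zero(self, quartet):
        ch = chars_of(A="0", B="0", C="0", D="0")
        marg = mk_marginal_posteriors_fixed(quartet, ch, MkModel(0.05, 0.05))
        assert (marg[[int(x) for x in quartet.postorder], 0] >= 0.5).all()


class TestParsimony:
    def test_single_change(self, quartet):
        assert parsimony_change_count(quartet, chars_of(A="0", B="0", C="1", D="1")) == 1

    def test_no_change(self, quartet):
        assert parsimony_change_count(quartet, chars_of(A="0", B="0", C="0", D="0")) == 0

    def test_prior_mean_floor(self, quartet):
        mean = default_rate_prior_mean(quartet, chars_of(A="0", B="0", C="0", D="0"))
        assert mean == 0.01


class TestRateMcmc:
    def test_prior_recovery_with_constant_likelihood(self, quartet):
        # all tips missing -> likelihood identically 1, posterior = prior
        ch = chars_of(A="missing", B="missing", C="missing", D="missing")
        settings = MkMcmcSettings(
            n_iter=4000, seed=3, rate_prior_mean=0.5, marginal_thin=100
        )
        res = asr_marginal_posteriors(quartet, ch, settings)
        draws = res.rate_samples
        for j in range(2):
            mean = draws[:, j].mean()
            ess_floor = len(draws) / 20  # conservative for slice chains
            mcse = 0.5 / np.sqrt(ess_floor)  # exponential sd = mean
            assert abs(mean - 0.5) < 3 * mcse

    def test_reproducible_given_seed(self, quartet):
        ch = chars_of(A="0", B="0", C="1", D="1")
        s = MkMcmcSettings(n_iter=300, seed=9, marginal_thin=50)
        r1 = asr_marginal_posteriors(quartet, ch, s)
        r2 = asr_marginal_posteriors(quartet, ch, s)
        assert np.array_equal(r1.rate_samples, r2.rate_samples)
        assert np.array_equal(r1.node_posteriors, r2.node_posteriors)


class TestBayesFactor:
    def test_stepping_stone_matches_quadrature(self):
        # 3-tip tree: brute-force the marginal likelihood over both rates
        t = pv.read_tree("((A:1,B:1):1,C:2);")
        ch = chars_of(A="0", B="0", C="1")
        settings = MkMcmcSettings(
            seed=4, rate_prior_mean=0.5, ss_rungs=10, ss_iter_per_rung=400
        )
        from pollendiv.mk import _stepping_stone_lnml

        node = int(t.postorder[0])  # cherry ancestor of A, B
        lnml = _stepping_stone_lnml(t, ch, settings, {node: 0}, seed=11)

        from scipy.integrate import dblquad

        def integrand(q10, q01):
            ll = mk_loglik(t, ch, MkModel(q01, q10), {node: 0})
            prior = np.exp(-(q01 + q10) / 0.5) / 0.25
            return np.exp(ll) * prior

        quad, _ = dblquad(integrand, 1e-8, 20.0, 1e-8, 20.0, epsabs=1e-10)
        assert lnml == pytest.approx(np.log(quad), abs=0.1)

    def test_clear_signal_significant_and_consistent(self):
        # a cherry of state-0 tips deep in a state-0 clade: fixing its
        # ancestor to 0 must beat fixing it to 1
        t = pv.read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")
        ch = chars_of(A="0", B="0", C="0", D="0", E="1")
        settings = MkMcmcSettings(seed=7, ss_iter_per_rung=300)
        node = int(t.postorder[0])
        res = node_bayes_factor(t, ch, node, settings)
        assert res.preferred_state == 0
        assert res.bayes_factor == pytest.approx(
            2 * (res.lnml[0] - res.lnml[1]), abs=1e-12
        )
        assert res.bayes_factor > 0
        # strict threshold semantics
        assert res.significant == (res.bayes_factor > 5)

    def test_symmetric_root_not_significant(self, cherry):
        ch = chars_of(A="0", B="1")
        res = node_bayes_factor(
            cherry, ch, cherry.root, MkMcmcSettings(seed=5, ss_iter_per_rung=300)
        )
        assert abs(res.bayes_factor) < 5
        assert not res.significant

    def test_tip_rejected(self, cherry):
        with pytest.raises(InputError):
            node_bayes_factor(cherry, chars_of(A="0", B="1"), 0, MkMcmcSettings())
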