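"""rho/sigma, clock conversion, HKY85+gamma machinery and the clock ML."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from bovmt import (
    ClockModel,
    SubstitutionModel,
    age_table,
    compute_rho,
    discretize_gamma,
    hky85_transition_matrix,
    ml_divergence,
    to_age,
)
from bovmt.dating import _CladeTopology, _log_likelihood, _tip_partials, hky85_rate_matrix
from bovmt.phylo import BranchMutation, TreeNode
from bovmt.variants import parse_variant_label


def _mk(label_count_tree):
    """Build a TreeNode tree from nested (n_mutations, [children]) specs."""
    counter = itertools.count()

    def rec(spec, parent=None):
        n_mut, children = spec
        muts = tuple(BranchMutation(parse_variant_label(str(1000 + next(counter))))
                     for _ in range(n_mut))
        node = TreeNode(f"n{next(counter)}", mutations=muts,
                        sample_id=None if children else f"tip{next(counter)}")
        for ch in children:
            node.add_child(rec(ch, node))
        return node

    return rec(label_count_tree)


class TestRho:
    def test_single_tip(self):
        clade = _mk((0, [(5, [])]))
        est = compute_rho(clade)
        assert est.rho == 5.0
        assert est.sigma == pytest.approx(math.sqrt(5))

    def test_star_four_tips(self):
        clade = _mk((0, [(3, []), (3, []), (3, []), (3, [])]))
        est = compute_rho(clade)
        assert est.rho == pytest.approx(3.0)
        assert est.sigma == pytest.approx(math.sqrt(12) / 4)

    def test_two_level_tree(self):
        # shared branch l=2 over 2 tips; privates 1 and 3
        clade = _mk((0, [(2, [(1, []), (3, [])])]))
        est = compute_rho(clade)
        assert est.rho == pytest.approx(4.0)
        # sum l_b * n_b^2 = 2*4 + 1*1 + 3*1 = 12
        assert est.sigma == pytest.approx(math.sqrt(12) / 2)

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_bruteforce_on_random_trees(self, data):
        """rho equals the mean root-to-tip count and sigma^2 the explicit
        sum l_b n_b^2 / n^2 on random genealogies of <=12 tips."""
        def random_spec(depth, tips_left):
            n_mut = data.draw(st.integers(0, 4))
            if depth >= 3 or tips_left[0] <= 1 or data.draw(st.booleans()):
                tips_left[0] -= 1
                return (n_mut, [])
            k = data.draw(st.integers(2, 3))
            return (n_mut, [random_spec(depth + 1, tips_left) for _ in range(k)])

        tips_left = [data.draw(st.integers(1, 12))]
        children = []
        while tips_left[0] > 0:
            children.append(random_spec(1, tips_left))
        clade = _mk((0, children))
        est = compute_rho(clade)
        depths = clade.root_to_tip_lengths()
        assert est.rho == pytest.approx(sum(depths.values()) / len(depths))
        s2 = sum(n.branch_length * n.n_tips ** 2
                 for n in clade.walk() if n is not clade)
        assert est.sigma ** 2 == pytest.approx(s2 / clade.n_tips ** 2)


class TestClockConversion:
    @pytest.mark.parametrize("div,unc,T,dT", [
        (5.56, 1.22, 17.64, 3.87),   # haplogroup Q, rho
        (5.60, 1.96, 17.76, 6.22),   # haplogroup Q, ML
        (4.30, 0.49, 13.64, 1.55),   # T2, rho
        (3.95, 0.26, 12.53, 0.82),   # T3, rho
        (15.5, 3.08, 49.17, 9.77),   # PQT, rho
    ])
    def test_reference_clock_rows(self, div, unc, T, dT):
        age = to_age(div, unc)
        assert age.rounded() == (T, dT)

    def test_zero(self):
        assert to_age(0.0, 0.0).rounded() == (0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_age(-1.0, 0.0)

    @given(st.floats(0, 50), st.floats(0, 10))
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, d, u):
        a1 = to_age(d, u)
        a2 = to_age(2 * d, 2 * u)
        assert a2.T_ky == pytest.approx(2 * a1.T_ky)
        assert a2.dT_ky == pytest.approx(2 * a1.dT_ky)

    def test_custom_clock(self):
        age = to_age(10.0, 1.0, ClockModel(years_per_mutation=1000.0))
        assert age.T_ky == pytest.approx(10.0)


class TestHKY85:
    def test_zero_time_is_identity(self):
        m = SubstitutionModel(kappa=3.0, base_freqs=(0.3, 0.2, 0.2, 0.3))
        np.testing.assert_allclose(hky85_transition_matrix(m, 0.0), np.eye(4),
                                   atol=1e-12)

    def test_rows_sum_to_one(self):
        m = SubstitutionModel(kappa=5.0, base_freqs=(0.4, 0.3, 0.1, 0.2))
        P = hky85_transition_matrix(m, 0.37)
        np.testing.assert_allclose(P.sum(axis=1), np.ones(4), atol=1e-12)
        assert (P >= 0).all()

    def test_jukes_cantor_limit(self):
        """kappa=1 and equal frequencies reduce to the JC closed form."""
        m = SubstitutionModel(kappa=1.0)
        for t in (0.05, 0.3, 1.2):
            P = hky85_transition_matrix(m, t)
            same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            np.testing.assert_allclose(np.diag(P), same, rtol=1e-10)

    def test_stationarity_at_large_time(self):
        freqs = (0.35, 0.25, 0.15, 0.25)
        m = SubstitutionModel(kappa=4.0, base_freqs=freqs)
        P = hky85_transition_matrix(m, 200.0)
        for row in P:
            np.testing.assert_allclose(row, freqs, atol=1e-8)

    def test_detailed_balance(self):
        freqs = (0.4, 0.3, 0.1, 0.2)
        m = SubstitutionModel(kappa=7.0, base_freqs=freqs)
        P = hky85_transition_matrix(m, 0.8)
        pi = np.array(freqs)
        np.testing.assert_allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-12)

    def test_unit_mean_rate(self):
        m = SubstitutionModel(kappa=9.0, base_freqs=(0.33, 0.26, 0.13, 0.28))
        Q = hky85_rate_matrix(m)
        assert -np.dot(m.base_freqs, np.diag(Q)) == pytest.approx(1.0)


class TestDiscreteGamma:
    def test_single_category(self):
        np.testing.assert_allclose(discretize_gamma(0.7, 1), [1.0])

    def test_no_heterogeneity_limit(self):
        rates = discretize_gamma(1e6, 8)
        np.testing.assert_allclose(rates, np.ones(8), atol=1e-2)

    def test_rates_average_to_one(self):
        for alpha in (0.1, 0.5, 2.0, 10.0):
            rates = discretize_gamma(alpha, 32)
            assert rates.mean() == pytest.approx(1.0, abs=1e-12)
            assert (rates > 0).all()
            assert (np.diff(rates) > 0).all()

    def test_quadrature_oracle(self):
        """alpha=0.5, k=4: category means match numeric integration."""
        alpha, k = 0.5, 4
        edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
        expected = []
        for a, b in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha), a,
                min(b, 1e3), limit=200)
            expected.append(val * k)
        np.testing.assert_allclose(discretize_gamma(alpha, k), expected, rtol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)
        with pytest.raises(ValueError):
            discretize_gamma(1.0, 0)


def _enumerate_likelihood(topo, sequences, model, h_root):
    """Direct sum over internal-node states (oracle for the pruning algorithm)."""
    from bovmt.dating import _BASE_INDEX

    rates = discretize_gamma(model.alpha, model.n_categories)
    pi = np.array(model.base_freqs)
    nodes = topo.post  # postorder, root last
    internals = [n for n in nodes if n.children]
    tips = [n for n in nodes if not n.children]
    L = len(next(iter(sequences.values())))
    lnl = 0.0
    for site in range(L):
        site_lik = 0.0
        for rate in rates:
            hts = topo.heights(h_root, np.array([]))
            Ps = {}
            for n in nodes:
                if n.parent is not None:
                    t = (hts[id(n.parent)] - hts[id(n)]) * rate
                    Ps[id(n)] = hky85_transition_matrix(model, t)
            for states in itertools.product(range(4), repeat=len(internals)):
                smap = {id(n): s for n, s in zip(internals, states)}
                for tip in tips:
                    smap[id(tip)] = _BASE_INDEX[sequences[tip.sample_id or tip.name][site]]
                p = pi[smap[id(topo.root)]]
                for n in nodes:
                    if n.parent is not None:
                        p *= Ps[id(n)][smap[id(n.parent)], smap[id(n)]]
                site_lik += p
        lnl += math.log(site_lik / len(rates))
    return lnl


class TestPruningLikelihood:
    def test_matches_enumeration_star(self):
        """Pruning likelihood equals exhaustive enumeration over internal
        states (4 taxa, 50 sites, star topology)."""
        rng = np.random.default_rng(11)
        L = 50
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), size=L)) for i in range(4)}
        model = SubstitutionModel(kappa=3.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
                                  alpha=0.7, n_categories=3)
        topo = _CladeTopology.star(list(seqs))
        from bovmt.dating import _compress_patterns, _encode_alignment
        names, data = _encode_alignment(seqs)
        patterns, counts = _compress_patterns(data)
        tip_part = {name: _tip_partials(patterns[i]) for i, name in enumerate(names)}
        h = 0.13
        pruned = _log_likelihood(topo, tip_part, counts, model, h, np.array([]))
        enumerated = _enumerate_likelihood(topo, seqs, model, h)
        assert pruned == pytest.approx(enumerated, abs=1e-10)

    def test_matches_enumeration_nested(self):
        """Same equality on a two-level clock topology (3 taxa)."""
        rng = np.random.default_rng(5)
        L = 30
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), size=L)) for i in range(3)}
        root = TreeNode("r")
        inner = root.add_child(TreeNode("i"))
        inner.add_child(TreeNode("t0", sample_id="t0"))
        inner.add_child(TreeNode("t1", sample_id="t1"))
        root.add_child(TreeNode("t2", sample_id="t2"))
        topo = _CladeTopology(root, list(seqs))
        model = SubstitutionModel(kappa=2.0, alpha=1.3, n_categories=2)
        from bovmt.dating import _compress_patterns, _encode_alignment
        names, data = _encode_alignment(seqs)
        patterns, counts = _compress_patterns(data)
        tip_part = {name: _tip_partials(patterns[i]) for i, name in enumerate(names)}
        h, frac = 0.2, np.array([0.5])
        pruned = _log_likelihood(topo, tip_part, counts, model, h, frac)

        # oracle: enumeration with explicit heights
        hts = topo.heights(h, frac)
        rates = discretize_gamma(model.alpha, model.n_categories)
        pi = np.array(model.base_freqs)
        lnl = 0.0
        for site in range(L):
            site_lik = 0.0
            for rate in rates:
                for s_root in range(4):
                    for s_in in range(4):
                        p = pi[s_root]
                        P_in = hky85_transition_matrix(
                            model, (hts[id(root)] - hts[id(inner)]) * rate)
                        p *= P_in[s_root, s_in]
                        for tip, anc in (("t0", s_in), ("t1", s_in), ("t2", s_root)):
                            node = root.find(tip)
                            t = (hts[id(node.parent)] - 0.0) * rate
                            P = hky85_transition_matrix(model, t)
                            p *= P[anc, "ACGT".index(seqs[tip][site])]
                        site_lik += p
            lnl += math.log(site_lik / len(rates))
        assert pruned == pytest.approx(lnl, abs=1e-10)


class TestMLDivergence:
    def test_identical_sequences_zero_divergence(self):
        seqs = {"a": "ACGT" * 100, "b": "ACGT" * 100}
        est = ml_divergence(seqs, fix_kappa=2.0, fix_alpha=1.0, n_categories=4)
        assert est.divergence == pytest.approx(0.0, abs=1e-3)

    def test_two_taxon_jukes_cantor_oracle(self):
        """With kappa=1, no rate heterogeneity and equal frequencies, twice
        the per-site root height equals the closed-form JC distance."""
        rng = np.random.default_rng(3)
        L = 2000
        a = rng.choice(list("ACGT"), size=L)
        b = a.copy()
        mism = rng.choice(L, size=150, replace=False)
        for i in mism:
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        seqs = {"a": "".join(a), "b": "".join(b)}
        model = SubstitutionModel(kappa=1.0, alpha=1.0, n_categories=1)
        est = ml_divergence(seqs, model=model, fix_kappa=1.0, fix_alpha=1.0,
                            n_categories=1)
        p = 150 / L
        d_jc = -0.75 * math.log(1 - 4 * p / 3)
        assert 2 * est.divergence / L == pytest.approx(d_jc, rel=1e-3)
        assert est.se > 0 and math.isfinite(est.se)

    def test_simulated_star_height_recovered(self):
        """Star clade simulated at known per-site height: ML recovers it."""
        rng = np.random.default_rng(42)
        L = 4000
        h = 0.02
        model = SubstitutionModel(kappa=4.0, base_freqs=(0.3, 0.25, 0.15, 0.3),
                                  alpha=1.0, n_categories=1)
        P = hky85_transition_matrix(model, h)
        pi = np.array(model.base_freqs)
        root = rng.choice(4, size=L, p=pi)
        seqs = {}
        for k in range(5):
            tip = np.array([rng.choice(4, p=P[s]) for s in root])
            seqs[f"t{k}"] = "".join("ACGT"[s] for s in tip)
        est = ml_divergence(seqs, model=model, fix_alpha=1.0, n_categories=1)
        assert est.divergence / L == pytest.approx(h, rel=0.15)
        assert abs(est.divergence / L - h) < 3 * est.se / L + 1e-9

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            ml_divergence({"a": "ACGT"})

    def test_mismatched_topology_rejected(self):
        root = TreeNode("r")
        root.add_child(TreeNode("x", sample_id="x"))
        root.add_child(TreeNode("y", sample_id="y"))
        with pytest.raises(ValueError):
            ml_divergence({"a": "ACGT", "b": "ACGT"}, topology=root)


class TestAgeTable:
    def test_reference_row_formatting(self):
        from bovmt.dating import RhoEstimate
        df = age_table([{"haplogroup": "Q", "n": 18,
                         "rho": RhoEstimate(rho=5.56, sigma=1.22, n=18)}])
        row = df.iloc[0]
        assert (row.T_rho, row.dT_rho) == (17.64, 3.87)
        assert row.N == 18

    def test_empty_input(self):
        df = age_table([])
        assert len(df) == 0
        assert list(df.columns)[:4] == ["haplogroup", "N", "ML", "SE"]

    def test_zero_rho(self):
        from bovmt.dating import RhoEstimate
        df = age_table([{"haplogroup": "X", "rho": RhoEstimate(0.0, 0.0, 2)}])
        assert (df.iloc[0].T_rho, df.iloc[0].dT_rho) == (0.0, 0.0)
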