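"""Likelihood engine: models, pruning, optimization, site log-likelihoods."""

import itertools

import numpy as np
import pytest

from quartetmap import (
    AMINO_ACID,
    NUCLEOTIDE,
    SimulationConfig,
    SiteLogLikelihoodMatrix,
    SubstitutionModel,
    TreeLikelihood,
    discrete_gamma_rates,
    empirical_frequencies,
    optimize_branch_lengths,
    simulate_alignment,
    site_log_likelihoods,
    quartet_tree_newick,
)
from quartetmap.phylik import QuartetEngine
from conftest import matrix_from, random_matrix


# ---------------------------------------------------------------------------
# independent oracle: likelihood by exhaustive summation over internal states

def brute_force_site_logliks(matrix, newick, model):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    k = model.alphabet.size
    rates = model.category_rates
    pmats_by_rate = [
        {id(n): model.transition_matrix((n.edge.length or 0.0) * r) for n in nodes}
        for r in rates
    ]
    out = []
    for site in range(matrix.n_sites):
        obs = {n.taxon.label: matrix.row(n.taxon.label)[site] for n in leaves}
        total = 0.0
        for ri, r in enumerate(rates):
            pm = pmats_by_rate[ri]
            cat_total = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                state = {id(n): s for n, s in zip(internals, assign)}
                prob = model.freqs[state[id(tree.seed_node)]]
                for n in nodes:
                    if n is tree.seed_node:
                        continue
                    parent_state = state[id(n.parent_node)]
                    if n.is_leaf():
                        s = obs[n.taxon.label]
                        prob *= 1.0 if s == k else pm[id(n)][parent_state, s]
                    else:
                        prob *= pm[id(n)][parent_state, state[id(n)]]
                cat_total += prob
            total += cat_total / len(rates)
        out.append(np.log(total))
    return np.array(out)


class TestSubstitutionModel:
    def test_rate_matrix_scaled_to_unit_mean_rate(self):
        m = SubstitutionModel.poisson(alphabet=AMINO_ACID)
        q = m.rate_matrix
        assert -np.sum(m.freqs * np.diag(q)) == pytest.approx(1.0)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_transition_matrix_rows_are_distributions(self, rng):
        freqs = rng.dirichlet(np.ones(4))
        m = SubstitutionModel.gtr(rng.uniform(0.5, 2.0, 6), freqs)
        for t in (0.0, 0.1, 2.0):
            p = m.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(p >= 0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-10)

    def test_stationarity_of_equilibrium_frequencies(self, rng):
        freqs = rng.dirichlet(np.ones(4))
        m = SubstitutionModel.gtr(rng.uniform(0.5, 2.0, 6), freqs)
        assert np.allclose(freqs @ m.transition_matrix(0.7), freqs, atol=1e-10)

    def test_discrete_gamma_category_means_average_to_one(self):
        for shape, k in ((0.3, 4), (1.0, 4), (5.0, 8)):
            rates = discrete_gamma_rates(shape, k)
            assert rates.mean() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(rates) > 0)
        # large shape -> rates concentrate near 1
        assert np.allclose(discrete_gamma_rates(200.0, 4), 1.0, atol=0.15)

    def test_paml_loader_round_trips_exchange_and_freqs(self, tmp_path, rng):
        s = np.zeros((20, 20))
        iu = np.tril_indices(20, k=-1)
        vals = rng.uniform(0.1, 5.0, iu[0].size)
        s[iu] = vals
        freqs = rng.dirichlet(np.ones(20))
        lines = []
        for i in range(1, 20):
            lines.append(" ".join(f"{s[i, j]:.6f}" for j in range(i)))
        lines.append(" ".join(f"{f:.6f}" for f in freqs))
        p = tmp_path / "toy.dat"
        p.write_text("\n".join(lines) + "\n")
        m = SubstitutionModel.from_paml(p)
        assert np.allclose(m.exchange[iu], np.round(vals, 6), atol=1e-6)
        assert np.allclose(m.freqs, freqs / freqs.sum(), atol=1e-5)

    def test_empirical_frequencies_smoothed_positive(self, rng):
        m = random_matrix(rng, alphabet=AMINO_ACID, n_sites=10)
        f = empirical_frequencies(m)
        assert f.shape == (20,) and np.all(f > 0) and f.sum() == pytest.approx(1.0)


class TestPruning:
    def test_zero_length_tree_constant_column_gives_log_pi(self):
        m = matrix_from({"a": "A", "b": "A", "c": "A", "d": "A"})
        model = SubstitutionModel.poisson(alphabet=AMINO_ACID)
        ll = site_log_likelihoods(m, "((a:0,b:0):0,(c:0,d:0):0);", model)
        assert ll[0] == pytest.approx(np.log(model.freqs[0]))

    @pytest.mark.parametrize("t,same", [(0.3, True), (0.3, False), (1.2, True)])
    def test_two_taxon_jc_closed_form(self, t, same):
        m = matrix_from({"a": "A", "b": "A" if same else "C"}, NUCLEOTIDE)
        model = SubstitutionModel.jc()
        ll = site_log_likelihoods(m, f"(a:{t / 2},b:{t / 2});", model)
        p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        expected = np.log(0.25 * (p_same if same else (1 - p_same) / 3.0))
        assert ll[0] == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_state_enumeration(self, rng):
        """Pruning equals brute-force summation over internal states on
        random <=5-taxon instances."""
        shapes = [
            "((a:{0},b:{1}):{2},(c:{3},d:{4}):{5});",
            "(a:{0},(b:{1},(c:{2},d:{3}):{4}):{5});",
            "((a:{0},b:{1}):{2},(c:{3},(d:{4},e:{5}):{0}):{1});",
        ]
        for i in range(12):
            shape = shapes[i % len(shapes)]
            lens = np.round(rng.uniform(0.01, 1.5, 6), 3)
            newick = shape.format(*lens)
            n_leaves = 5 if "e:" in shape else 4
            m = random_matrix(rng, n_taxa=n_leaves, n_sites=8, missing_prob=0.2)
            m.taxa = list("abcde"[:n_leaves])
            model = (
                SubstitutionModel.gtr(rng.uniform(0.5, 2, 6), rng.dirichlet(np.ones(4)))
                if i % 2
                else SubstitutionModel.jc(gamma_shape=0.8, n_cat=2)
            )
            mine = site_log_likelihoods(m, newick, model)
            oracle = brute_force_site_logliks(m, newick, model)
            assert np.allclose(mine, oracle, atol=1e-8)

    def test_pulley_principle_root_placement_irrelevant(self, rng):
        m = random_matrix(rng, n_taxa=5, n_sites=30, missing_prob=0.1)
        m.taxa = list("abcde")
        model = SubstitutionModel.gtr(rng.uniform(0.5, 2, 6), rng.dirichlet(np.ones(4)))
        # same unrooted tree, pruning root placed on different nodes
        rootings = [
            "((a:0.1,b:0.2):0.15,(c:0.3,(d:0.25,e:0.05):0.1):0.05);",
            "(a:0.1,b:0.2,(c:0.3,(d:0.25,e:0.05):0.1):0.2);",
            "(c:0.3,(d:0.25,e:0.05):0.1,(a:0.1,b:0.2):0.2);",
        ]
        lls = [site_log_likelihoods(m, nwk, model) for nwk in rootings]
        assert np.allclose(lls[0], lls[1], atol=1e-8)
        assert np.allclose(lls[0], lls[2], atol=1e-8)

    def test_gamma_site_likelihood_averages_categories(self, rng):
        m = random_matrix(rng, n_taxa=4, n_sites=20, missing_prob=0.0)
        m.taxa = list("abcd")
        nwk = "((a:0.2,b:0.3):0.1,(c:0.15,d:0.4):0.1);"
        model_g = SubstitutionModel.jc(gamma_shape=0.7, n_cat=4)
        rates = model_g.category_rates
        per_cat = []
        for r in rates:
            model0 = SubstitutionModel.jc()
            scaled = (
                f"((a:{0.2 * r},b:{0.3 * r}):{0.1 * r},"
                f"(c:{0.15 * r},d:{0.4 * r}):{0.1 * r});"
            )
            per_cat.append(np.exp(site_log_likelihoods(m, scaled, model0)))
        expected = np.log(np.mean(per_cat, axis=0))
        assert np.allclose(site_log_likelihoods(m, nwk, model_g), expected, atol=1e-10)

    def test_all_missing_column_contributes_zero_loglik(self):
        m = matrix_from({"a": "A-", "b": "C-", "c": "G-", "d": "T-"}, NUCLEOTIDE)
        ll = site_log_likelihoods(m, "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);", SubstitutionModel.jc())
        assert ll[1] == pytest.approx(0.0, abs=1e-12)

    def test_pattern_compression_preserves_totals(self, rng):
        codes = rng.integers(0, 4, size=(4, 10)).astype(np.uint8)
        dup = np.hstack([codes, codes, codes[:, :4]])
        from quartetmap import PartitionScheme, ResidueMatrix

        m = ResidueMatrix(list("abcd"), dup, NUCLEOTIDE, PartitionScheme.single(dup.shape[1]))
        nwk = "((a:0.2,b:0.1):0.05,(c:0.3,d:0.1):0.05);"
        tl = TreeLikelihood(m, nwk, SubstitutionModel.jc())
        assert tl.patterns.shape[1] <= 10
        assert tl.loglik() == pytest.approx(float(tl.site_logliks().sum()), abs=1e-10)


class TestOptimization:
    def test_identical_sequences_drive_lengths_to_floor(self):
        m = matrix_from({t: "ACGTACGTACGTACGT" for t in "abcd"}, NUCLEOTIDE)
        res = optimize_branch_lengths(m, "((a:0.3,b:0.3):0.3,(c:0.3,d:0.3):0.3);", SubstitutionModel.jc())
        assert all(l < 1e-3 for l in res.lengths.values())

    def test_loglik_never_decreases(self, rng):
        m = random_matrix(rng, n_taxa=4, n_sites=60, missing_prob=0.0)
        m.taxa = list("abcd")
        nwk = "((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);"
        model = SubstitutionModel.jc()
        before = TreeLikelihood(m, nwk, model).loglik()
        res = optimize_branch_lengths(m, nwk, model)
        assert res.loglik >= before - 1e-9

    def test_branch_length_recovery_within_ten_percent(self):
        """Simulated quartet with known branch lengths, n = 10,000 sites."""
        true = {"a": 0.25, "b": 0.15, "internal": 0.2, "c": 0.3, "d": 0.1}
        nwk = (
            f"((a:{true['a']},b:{true['b']}):{true['internal'] / 2},"
            f"(c:{true['c']},d:{true['d']}):{true['internal'] / 2});"
        )
        model = SubstitutionModel.jc()
        m = simulate_alignment(SimulationConfig(tree=nwk, model=model, n_sites=10_000, seed=42))
        eng = QuartetEngine(m.codes, model)
        res = eng.optimize()
        for name, t_true in true.items():
            assert res.lengths[name] == pytest.approx(t_true, rel=0.10)

    def test_quartet_engine_agrees_with_generic_optimizer(self, rng):
        m = random_matrix(rng, n_taxa=4, n_sites=150, missing_prob=0.1, alphabet=AMINO_ACID)
        m.taxa = list("abcd")
        model = SubstitutionModel.poisson(freqs=empirical_frequencies(m))
        fast = QuartetEngine(m.codes, model).optimize()
        slow = optimize_branch_lengths(m, "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);", model)
        assert fast.loglik == pytest.approx(slow.loglik, abs=1e-4)

    def test_quartet_engine_loglik_matches_generic_at_fixed_lengths(self, rng):
        m = random_matrix(rng, n_taxa=4, n_sites=80, missing_prob=0.2, alphabet=AMINO_ACID)
        m.taxa = list("abcd")
        model = SubstitutionModel.poisson(gamma_shape=0.9, n_cat=4)
        L = np.array([0.2, 0.1, 0.3, 0.15, 0.25])
        eng_ll = QuartetEngine(m.codes, model).loglik(L)
        nwk = "((a:0.2,b:0.1):0.3,(c:0.15,d:0.25):0.0);"
        assert eng_ll == pytest.approx(TreeLikelihood(m, nwk, model).loglik(), abs=1e-8)


class TestSiteLogLikelihoodMatrix:
    def test_weighted_sums_and_tsv_round_trip(self, tmp_path, rng):
        ll = rng.normal(-3, 1, size=(3, 7))
        w = rng.integers(1, 5, 7).astype(float)
        slm = SiteLogLikelihoodMatrix(labels=["x", "y", "z"], loglik=ll, weights=w)
        assert np.allclose(slm.totals(), ll @ w)
        p = tmp_path / "slm.tsv"
        slm.to_tsv(p)
        back = SiteLogLikelihoodMatrix.from_tsv(p)
        assert back.labels == slm.labels
        assert np.allclose(back.loglik, slm.loglik, atol=1e-9)
        assert np.allclose(back.weights, slm.weights)
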