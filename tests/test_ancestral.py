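"""GTR+Gamma+I likelihood, marginal ASR, NJ trees, bootstrap, model fitting."""

import numpy as np
import pytest
from conftest import likelihood_enumeration_oracle, random_model, random_small_instance

from hyscav.alignment import CodonAlignment
from hyscav.ancestral import (
    SubstitutionModel,
    bootstrap_support,
    build_nj_tree,
    empirical_frequencies,
    fit_model,
    log_likelihood,
    marginal_asr,
    ml_distance_matrix,
    tree_splits,
)
from hyscav.phylo import leaf_names, tree_from_newick
from hyscav.synthetic import SimulationSpec, evolve_codon_alignment, generate_tree


class TestSubstitutionModel:
    def test_rate_matrix_is_scaled_generator(self):
        m = random_model(np.random.default_rng(0))
        q = m.rate_matrix()
        pi = np.asarray(m.base_frequencies)
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0, abs=1e-12)
        # detailed balance (time reversibility)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    @pytest.mark.parametrize("shape", [0.1, 0.5, 1.0, 2.0, 10.0])
    def test_discrete_gamma_rates_have_mean_one(self, shape):
        m = SubstitutionModel(gamma_shape=shape, n_rate_categories=4)
        rates = m.gamma_category_rates()
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(rates) > 0).all()

    def test_mixture_mean_rate_is_one_with_invariant_class(self):
        m = SubstitutionModel(gamma_shape=0.7, p_invariant=0.3)
        w, r = m.rate_mixture()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w * r).sum() == pytest.approx(1.0, abs=1e-9)
        assert r[0] == 0.0  # invariant class

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel(base_frequencies=(0.5, 0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            SubstitutionModel(gamma_shape=-1.0)
        with pytest.raises(ValueError):
            SubstitutionModel(p_invariant=1.0)


class TestPruningLikelihood:
    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            tree, aln, model = random_small_instance(rng)
            ll = log_likelihood(tree, aln, model)
            oracle = likelihood_enumeration_oracle(tree, aln, model)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_zero_branch_identical_leaves_closed_form(self):
        tree = tree_from_newick("(A:0.0,B:0.0);")
        aln = CodonAlignment({"A": "AAA", "B": "AAA"})
        m = SubstitutionModel(base_frequencies=(0.1, 0.2, 0.3, 0.4))
        ll = log_likelihood(tree, aln, m)
        assert ll == pytest.approx(3 * np.log(0.1), abs=1e-10)

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(5)
        tree, aln, model = random_small_instance(rng)
        ll1 = log_likelihood(tree, aln, model)
        reordered = CodonAlignment(dict(reversed(list(aln.sequences.items()))))
        assert log_likelihood(tree, reordered, model) == pytest.approx(ll1, abs=1e-12)

    def test_rerooting_invariance(self):
        # same unrooted 3-leaf tree rooted on two different branches
        model = random_model(np.random.default_rng(9))
        aln = CodonAlignment({"A": "ACGTTT", "B": "ACGGTT", "C": "TCGTAT"})
        t1 = tree_from_newick("((B:0.2,C:0.2):0.04,A:0.06);")
        t2 = tree_from_newick("((A:0.1,C:0.2):0.12,B:0.08);")
        assert log_likelihood(t1, aln, model) == pytest.approx(
            log_likelihood(t2, aln, model), abs=1e-8
        )

    def test_negative_branch_raises(self):
        tree = tree_from_newick("(A:-0.1,B:0.1);")
        aln = CodonAlignment({"A": "AAA", "B": "AAA"})
        with pytest.raises(ValueError, match="negative branch"):
            log_likelihood(tree, aln, SubstitutionModel())

    def test_unbound_leaf_raises(self):
        tree = tree_from_newick("(A:0.1,B:0.1);")
        aln = CodonAlignment({"A": "AAA", "X": "AAA"})
        with pytest.raises(KeyError, match="no row"):
            log_likelihood(tree, aln, SubstitutionModel())


class TestMarginalASR:
    def test_posteriors_normalize(self):
        rng = np.random.default_rng(2)
        tree, aln, model = random_small_instance(rng)
        anc = marginal_asr(tree, aln, model)
        for post in anc.posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_leaves_tiny_branches_recover_shared_base(self):
        tree = tree_from_newick("((A:1e-8,B:1e-8):1e-8,(C:1e-8,D:1e-8):1e-8);")
        aln = CodonAlignment({k: "GGG" for k in "ABCD"})
        anc = marginal_asr(tree, aln, SubstitutionModel())
        for label, seq in anc.map_sequences.items():
            assert seq == "GGG"
            assert anc.posteriors[label][:, 2].min() > 0.999

    def test_recovery_degrades_with_tree_length(self):
        accuracies = {}
        for length in (0.5, 2.0, 5.0):
            spec = SimulationSpec(
                n_leaves=8, n_columns=300, total_tree_length=length, seed=11
            )
            tree = generate_tree(spec)
            aln, truth = evolve_codon_alignment(tree, spec)
            model = SubstitutionModel(
                base_frequencies=empirical_frequencies(aln), gamma_shape=1.0
            )
            anc = marginal_asr(tree, aln, model)
            hits = total = 0
            for node, true_seq in truth.true_ancestral_sequences.items():
                rec = anc.map_sequences[node]
                hits += sum(a == b for a, b in zip(rec, true_seq))
                total += len(true_seq)
            accuracies[length] = hits / total
        assert accuracies[0.5] >= 0.95
        assert accuracies[0.5] > accuracies[2.0] > accuracies[5.0]

    def test_codon_assembly_has_no_stops(self, code):
        spec = SimulationSpec(n_leaves=6, n_columns=60, total_tree_length=2.0, seed=3)
        tree = generate_tree(spec)
        aln, _ = evolve_codon_alignment(tree, spec)
        anc = marginal_asr(tree, aln, SubstitutionModel(gamma_shape=1.0))
        from hyscav.genetics import iter_codons

        for seq in anc.codon_sequences.values():
            assert not any(code.is_stop(c) for c in iter_codons(seq))


class TestNJAndBootstrap:
    def test_three_taxa_unique_topology(self):
        aln = CodonAlignment({"A": "ATGAAATTT", "B": "ATGAAATTC", "C": "ATGCCCTTT"})
        tree = build_nj_tree(aln, SubstitutionModel())
        assert sorted(leaf_names(tree)) == ["A", "B", "C"]
        for edge in tree.preorder_edge_iter():
            assert edge.length is None or edge.length >= 0

    def test_distance_matrix_symmetric_zero_diagonal(self):
        spec = SimulationSpec(n_leaves=5, n_columns=40, total_tree_length=1.0, seed=6)
        tree = generate_tree(spec)
        aln, _ = evolve_codon_alignment(tree, spec)
        d, ids = ml_distance_matrix(aln, SubstitutionModel(gamma_shape=1.0))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_recovers_long_internal_branch_split(self):
        # two clades separated by a deep split: NJ must find it
        newick = "((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5);"
        recovered = 0
        for seed in range(20):
            spec = SimulationSpec(n_leaves=4, n_columns=200, total_tree_length=1.2, seed=seed)
            tree = tree_from_newick(newick)
            aln, _ = evolve_codon_alignment(tree, spec)
            nj_tree = build_nj_tree(
                aln, SubstitutionModel(base_frequencies=empirical_frequencies(aln))
            )
            if frozenset({"C", "D"}) in tree_splits(nj_tree) or frozenset(
                {"A", "B"}
            ) in tree_splits(nj_tree):
                recovered += 1
        assert recovered >= 19

    def test_single_rep_supports_are_zero_or_hundred(self):
        spec = SimulationSpec(n_leaves=5, n_columns=60, total_tree_length=1.0, seed=13)
        tree = generate_tree(spec)
        aln, _ = evolve_codon_alignment(tree, spec)
        sup = bootstrap_support(aln, SubstitutionModel(), n_reps=1, seed=0)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_clean_deep_split_has_high_support(self):
        newick = "(((A:0.05,B:0.05):0.4,(C:0.05,D:0.05):0.4):0.01,(E:0.05,F:0.05):0.4);"
        spec = SimulationSpec(n_leaves=6, n_columns=150, total_tree_length=1.5, seed=21)
        tree = tree_from_newick(newick)
        aln, _ = evolve_codon_alignment(tree, spec)
        sup = bootstrap_support(
            aln, SubstitutionModel(base_frequencies=empirical_frequencies(aln)), n_reps=30, seed=2
        )
        assert all(0.0 <= v <= 100.0 for v in sup.values())
        ab = sup.get(frozenset({"A", "B"}))
        assert ab is None or ab >= 90.0
        # the A+B clade must be present in the point tree with high support
        assert any(v >= 90.0 for v in sup.values())


class TestFitModel:
    def test_fitted_likelihood_beats_generating_model(self):
        spec = SimulationSpec(n_leaves=6, n_columns=80, total_tree_length=1.0, seed=17)
        tree = generate_tree(spec)
        aln, _ = evolve_codon_alignment(tree, spec)
        generating = SubstitutionModel(
            base_frequencies=empirical_frequencies(aln), gamma_shape=1.0
        )
        fit = fit_model(aln, tree)
        assert fit.log_likelihood >= log_likelihood(tree, aln, generating) - 1e-6

    def test_refit_from_fitted_start_is_stable(self):
        spec = SimulationSpec(n_leaves=5, n_columns=60, total_tree_length=1.0, seed=19)
        tree = generate_tree(spec)
        aln, _ = evolve_codon_alignment(tree, spec)
        fit1 = fit_model(aln, tree)
        fit2 = fit_model(aln, tree, start=fit1.model)
        assert fit2.log_likelihood == pytest.approx(fit1.log_likelihood, abs=0.05)

    def test_jukes_cantor_recovery(self):
        # data simulated under equal rates: fitted exchangeabilities near equal
        ratios = []
        for seed in range(5):
            # neutral evolution (omega 1): purifying selection would skew
            # apparent exchangeabilities toward synonymous transitions
            spec = SimulationSpec(
                n_leaves=8,
                n_columns=150,
                total_tree_length=1.5,
                omega_background=1.0,
                seed=100 + seed,
            )
            tree = generate_tree(spec)
            aln, _ = evolve_codon_alignment(tree, spec)
            fit = fit_model(aln, tree, gamma=False, invariant=False)
            ex = np.asarray(fit.model.exchangeabilities)
            ratios.append(ex.max() / ex.min())
        assert np.median(ratios) < 1.2 / 0.8
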