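"""Nei-Gojobori machinery: site counts, pathway averaging, Z-test, profiles."""

import math

import numpy as np
import pytest
from conftest import ng_diff_oracle

from hyscav.alignment import CodonAlignment
from hyscav.genetics import opal_sec_code, standard_code
from hyscav.phylo import tree_from_newick
from hyscav.selection import (
    count_differences,
    count_sites,
    pairwise_ng,
    site_profile,
    summarize_positive_sites,
    z_test,
)


class TestCountSites:
    @pytest.mark.parametrize(
        "codon,S",
        [
            ("TTT", 1 / 3),  # only the third position has a synonymous change
            ("ATG", 0.0),  # Met has no synonymous neighbor
            ("TGG", 0.0),  # Trp likewise (TGA excluded as stop)
        ],
    )
    def test_known_site_fractions(self, code, codon, S):
        counts = count_sites(codon, code)
        assert counts.S == pytest.approx(S, abs=1e-12)
        assert counts.N == pytest.approx(3 - S, abs=1e-12)

    def test_sites_sum_to_three_for_all_sense_codons(self, code):
        for codon in code.sense_codons():
            c = count_sites(codon, code)
            assert c.S + c.N == pytest.approx(3.0, abs=1e-9)
            assert c.S >= 0 and c.N >= 0

    def test_stop_codon_rejected(self, code):
        with pytest.raises(ValueError):
            count_sites("TGA", code)

    def test_opal_code_treats_tga_as_sense(self):
        sec = opal_sec_code()
        counts = count_sites("TGA", sec)
        assert counts.S + counts.N == pytest.approx(3.0, abs=1e-9)
        # under the Sec code TGT/TGC (Cys) are not synonymous with TGA (U)
        assert sec.translate_codon("TGA") == "U"


class TestCountDifferences:
    def test_identity(self, code):
        d = count_differences("TTT", "TTT", code)
        assert (d.Sd, d.Nd) == (0.0, 0.0)

    def test_two_step_pathway_average(self, code):
        # TTT->GTT(nonsyn)->GTA(syn) and TTT->TTA(nonsyn)->GTA(nonsyn)
        d = count_differences("TTT", "GTA", code)
        assert d.Sd == pytest.approx(0.5)
        assert d.Nd == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pathway_oracle_on_random_pairs(self, code, seed):
        rng = np.random.default_rng(seed)
        sense = code.sense_codons()
        for _ in range(200):
            a, b = rng.choice(sense, 2)
            d = count_differences(a, b, code)
            s_o, n_o, admissible = ng_diff_oracle(a, b, code)
            assert d.admissible == admissible
            if admissible:
                assert d.Sd == pytest.approx(s_o, abs=1e-12)
                assert d.Nd == pytest.approx(n_o, abs=1e-12)

    def test_hamming_conservation(self, code):
        rng = np.random.default_rng(7)
        sense = code.sense_codons()
        for _ in range(300):
            a, b = rng.choice(sense, 2)
            d = count_differences(a, b, code)
            if d.admissible:
                ham = sum(x != y for x, y in zip(a, b))
                assert d.Sd + d.Nd == pytest.approx(ham, abs=1e-9)


class TestPairwiseNG:
    def test_identical_sequences_are_zero(self, code):
        seq = "ATGGCTTGGAAA" * 5
        r = pairwise_ng(seq, seq, code, n_bootstrap=10, seed=0)
        assert r.pS == r.pN == r.dS == r.dN == 0.0

    def test_symmetry(self, code):
        rng = np.random.default_rng(3)
        sense = code.sense_codons()
        a = "".join(rng.choice(sense, 40))
        b = "".join(rng.choice(sense, 40))
        r1 = pairwise_ng(a, b, code, n_bootstrap=50, seed=9)
        r2 = pairwise_ng(b, a, code, n_bootstrap=50, seed=9)
        for field in ("pS", "pN", "dS", "dN", "varS", "varN"):
            assert getattr(r1, field) == pytest.approx(getattr(r2, field), rel=1e-12)

    def test_pure_synonymous_third_position_changes(self, code):
        # 100 Leu codons; three of them differ synonymously at position 3
        a = ["CTT"] * 100
        b = list(a)
        for i in (10, 50, 90):
            b[i] = "CTC"
        r = pairwise_ng("".join(a), "".join(b), code, n_bootstrap=10, seed=0)
        assert r.pN == 0.0
        # sum of synonymous differences is exactly 3
        s_sites = 100 * (count_sites("CTT", code).S + count_sites("CTC", code).S) / 2
        assert r.pS * s_sites == pytest.approx(3.0, rel=1e-6)


class TestZTest:
    def test_null_gives_half(self):
        r = z_test(0.1, 0.1, 0.001, 0.001)
        assert r.Z == 0.0
        assert r.p_one_tailed == pytest.approx(0.5)

    def test_worked_example(self):
        r = z_test(0.10, 0.02, 0.0008, 0.0008)
        assert r.Z == pytest.approx(2.0)
        assert r.p_one_tailed == pytest.approx(0.0228, abs=2e-4)

    def test_antisymmetry_under_swap(self):
        r1 = z_test(0.2, 0.05, 0.001, 0.002)
        r2 = z_test(0.05, 0.2, 0.002, 0.001)
        assert r1.Z == pytest.approx(-r2.Z)

    def test_zero_variance_flags(self):
        assert z_test(0.1, 0.1, 0.0, 0.0).Z == 0.0
        r = z_test(0.2, 0.1, 0.0, 0.0)
        assert r.infinite and math.isinf(r.Z)


class TestSiteProfile:
    def test_single_branch_synonymous_change(self, code):
        # one parent->child branch; the only difference is TTT->TTC
        tree = tree_from_newick("(A:0.1)root;")
        alignment = CodonAlignment({"A": "TTCAAA"})
        ancestors = {"root": "TTTAAA"}
        prof = site_profile(alignment, tree, ancestors, code, n_bootstrap=10, seed=0)
        row = prof.table.loc[1]
        assert row["deltaS"] == pytest.approx(3.0)  # 1 / (1/3)
        assert row["deltaN"] == 0.0
        row2 = prof.table.loc[2]
        assert row2["deltaN"] == row2["deltaS"] == 0.0

    def test_identical_column_is_zero_everywhere(self, code):
        tree = tree_from_newick("((A:0.1,B:0.1)N:0.1)root;")
        alignment = CodonAlignment({"A": "GGG", "B": "GGG"})
        ancestors = {"root": "GGG", "N": "GGG"}
        prof = site_profile(alignment, tree, ancestors, code, n_bootstrap=10, seed=0)
        assert prof.table.loc[1, "deltaN"] == 0.0
        assert prof.table.loc[1, "deltaS"] == 0.0

    def test_zero_synonymous_site_column_is_flagged_not_zeroed(self, code):
        # ATG (Met) has no synonymous site: deltaS is undefined there
        tree = tree_from_newick("(A:0.1)root;")
        prof = site_profile(
            CodonAlignment({"A": "ATG"}), tree, {"root": "ATG"}, code, n_bootstrap=5
        )
        assert np.isnan(prof.table.loc[1, "deltaS"])

    def test_missing_ancestor_raises(self, code):
        tree = tree_from_newick("((A:0.1,B:0.1)N:0.1)root;")
        alignment = CodonAlignment({"A": "ATG", "B": "ATG"})
        with pytest.raises(KeyError, match="no reconstructed sequence"):
            site_profile(alignment, tree, {"root": "ATG"}, code, n_bootstrap=5)

    def test_conserved_simulated_columns_never_score_positive(self, code):
        """omega=0 columns keep their amino acid and never show deltaN > deltaS.

        Pathway averaging can attribute fractional nonsynonymous
        differences to synonymous double hits on one branch (e.g. Arg
        CGC->AGA), but such pairs contribute Sd >= Nd against smaller
        synonymous site counts, so deltaN - deltaS stays below zero.
        """
        from hyscav.synthetic import SimulationSpec, evolve_codon_alignment, generate_tree

        for seed in (4, 5, 6):
            spec = SimulationSpec(
                n_leaves=6,
                n_columns=30,
                conserved_columns=frozenset(range(1, 11)),
                total_tree_length=1.5,
                seed=seed,
            )
            tree = generate_tree(spec)
            alignment, truth = evolve_codon_alignment(tree, spec)
            # event-level guarantee: the amino acid never changes
            sequences = dict(alignment.sequences) | truth.true_ancestral_sequences
            for col in range(1, 11):
                aas = {
                    code.translate_codon(seq[3 * (col - 1) : 3 * col])
                    for seq in sequences.values()
                }
                assert len(aas) == 1
            prof = site_profile(
                alignment, tree, truth.true_ancestral_sequences, code, n_bootstrap=10, seed=0
            )
            diff = prof.table.loc[1:10, "deltaN_minus_deltaS"].dropna()
            assert (diff <= 0).all()


class TestSummary:
    def test_all_zero_profile(self, code):
        tree = tree_from_newick("(A:0.0)root;")
        alignment = CodonAlignment({"A": "ATGATG"})
        prof = site_profile(alignment, tree, {"root": "ATGATG"}, code, n_bootstrap=5)
        s = summarize_positive_sites(prof)
        assert s == {"n_positive": 0, "n_total": 2, "fraction": 0.0}

    def test_fraction_bounded(self, code):
        from hyscav.synthetic import SimulationSpec, evolve_codon_alignment, generate_tree

        spec = SimulationSpec(n_leaves=5, n_columns=40, total_tree_length=1.0, seed=8)
        tree = generate_tree(spec)
        alignment, truth = evolve_codon_alignment(tree, spec)
        prof = site_profile(
            alignment, tree, truth.true_ancestral_sequences, code, n_bootstrap=10, seed=1
        )
        s = summarize_positive_sites(prof)
        assert 0.0 <= s["fraction"] <= 1.0
        assert s["n_total"] == 40
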