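"""Synthetic generators: trees, codon evolution, structures, fixture bundles."""

import numpy as np
import pytest
from scipy import stats

from hyscav.genetics import iter_codons, standard_code
from hyscav.phylo import total_tree_length
from hyscav.synthetic import (
    SimulationSpec,
    StructureSpec,
    evolve_codon_alignment,
    generate_structure,
    generate_tree,
    mc_void_volume,
    write_fixture_bundle,
)


class TestSimulationSpec:
    def test_overlapping_column_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SimulationSpec(hotspot_columns=frozenset({1}), conserved_columns=frozenset({1}))

    def test_out_of_range_columns_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_columns=10, hotspot_columns=frozenset({11}))

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_leaves=2)


class TestGenerateTree:
    def test_balanced_three_leaves_shape(self):
        tree = generate_tree(SimulationSpec(n_leaves=3, tree_shape="balanced"))
        internal = [n for n in tree if not n.is_leaf()]
        branches = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        assert len(internal) == 2
        assert len(branches) == 4

    def test_yule_deterministic_for_seed(self):
        t1 = generate_tree(SimulationSpec(n_leaves=8, tree_shape="yule", seed=1))
        t2 = generate_tree(SimulationSpec(n_leaves=8, tree_shape="yule", seed=1))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_total_length_normalized(self):
        tree = generate_tree(
            SimulationSpec(n_leaves=24, total_tree_length=2.0, seed=5)
        )
        assert total_tree_length(tree) == pytest.approx(2.0, abs=1e-9)

    def test_binary_and_rooted(self):
        tree = generate_tree(SimulationSpec(n_leaves=9, seed=3))
        for node in tree:
            assert len(node.child_nodes()) in (0, 2)


class TestEvolveCodonAlignment:
    def test_deterministic_for_seed(self):
        spec = SimulationSpec(n_leaves=5, n_columns=30, seed=9)
        t1, t2 = generate_tree(spec), generate_tree(spec)
        a1, g1 = evolve_codon_alignment(t1, spec)
        a2, g2 = evolve_codon_alignment(t2, spec)
        assert a1.sequences == a2.sequences
        assert g1.true_ancestral_sequences == g2.true_ancestral_sequences

    def test_no_stop_codons_anywhere(self, code):
        spec = SimulationSpec(n_leaves=8, n_columns=50, total_tree_length=3.0, seed=2)
        tree = generate_tree(spec)
        aln, truth = evolve_codon_alignment(tree, spec)
        for seq in list(aln.sequences.values()) + list(
            truth.true_ancestral_sequences.values()
        ):
            assert not any(code.is_stop(c) for c in iter_codons(seq))

    def test_zero_length_tree_keeps_root_sequence(self):
        spec = SimulationSpec(n_leaves=4, n_columns=20, total_tree_length=0.0, seed=1)
        tree = generate_tree(spec)
        aln, truth = evolve_codon_alignment(tree, spec)
        root_seq = next(iter(truth.true_ancestral_sequences.values()))
        roots = {s for s in truth.true_ancestral_sequences.values()}
        assert roots == {root_seq}
        assert set(aln.sequences.values()) == {root_seq}

    def test_hotspot_event_excess_from_log(self, code):
        """omega=5 columns accumulate more nonsynonymous events per
        nonsynonymous site than synonymous events per synonymous site."""
        from hyscav.selection import count_sites

        rate_n = rate_s = 0.0
        for seed in range(30):
            spec = SimulationSpec(
                n_leaves=4,
                n_columns=10,
                hotspot_columns=frozenset(range(1, 11)),
                omega_hotspot=5.0,
                total_tree_length=1.0,
                seed=seed,
            )
            tree = generate_tree(spec)
            _, truth = evolve_codon_alignment(tree, spec)
            n_events = sum(
                1 for e in truth.event_log if e["accepted"] and not e["synonymous"]
            )
            s_events = sum(1 for e in truth.event_log if e["accepted"] and e["synonymous"])
            rate_n += n_events
            rate_s += s_events
        # site counts hover around S ~ 0.8, N ~ 2.2 per codon, so a
        # >2.75x event excess means the per-site nonsynonymous rate wins
        assert rate_n / 2.2 > rate_s / 0.8

    def test_regime_recorded(self):
        spec = SimulationSpec(
            n_leaves=4,
            n_columns=10,
            hotspot_columns=frozenset({1}),
            conserved_columns=frozenset({2}),
            seed=0,
        )
        tree = generate_tree(spec)
        _, truth = evolve_codon_alignment(tree, spec)
        assert truth.true_column_regime[1] == "hotspot"
        assert truth.true_column_regime[2] == "conserved"
        assert truth.true_column_regime[3] == "background"

    def test_divergence_increases_with_tree_length(self):
        """Mean pairwise leaf distance tracks the requested tree length."""

        def mean_pairwise(aln):
            seqs = list(aln.sequences.values())
            total = count = 0
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
                    count += 1
            return total / count

        lengths = np.linspace(0.1, 3.0, 20)
        distances = []
        for k, length in enumerate(lengths):
            spec = SimulationSpec(
                n_leaves=6, n_columns=60, total_tree_length=float(length), seed=k
            )
            tree = generate_tree(spec)
            aln, _ = evolve_codon_alignment(tree, spec)
            distances.append(mean_pairwise(aln))
        rho = stats.spearmanr(lengths, distances).statistic
        assert rho > 0.9


class TestGenerateStructure:
    def test_convex_blob_has_no_void(self):
        _, truth = generate_structure(
            StructureSpec(kind="convex_blob", cage_radius=5.0), mc_samples=100_000
        )
        assert truth.reference_void_volume == 0.0
        assert truth.reference_mouth_count == 0

    def test_sealed_cage_volume_near_closed_form(self):
        spec = StructureSpec(kind="sealed_cage", cage_radius=8.0, n_shell_atoms=200)
        _, truth = generate_structure(spec, mc_samples=400_000)
        closed_form = 4 / 3 * np.pi * (8.0 - 1.8 - 1.4) ** 3
        assert truth.reference_void_volume == pytest.approx(closed_form, rel=0.10)
        assert truth.reference_mouth_count == 0

    def test_aperture_volume_not_above_sealed(self):
        sealed = generate_structure(
            StructureSpec(kind="sealed_cage", cage_radius=8.0, n_shell_atoms=200),
            mc_samples=150_000,
        )[1]
        aperture = generate_structure(
            StructureSpec(
                kind="aperture_cage",
                cage_radius=8.0,
                n_shell_atoms=200,
                aperture_solid_angle=0.8,
            ),
            mc_samples=150_000,
        )[1]
        assert aperture.reference_void_volume <= sealed.reference_void_volume

    def test_aperture_angle_only_for_aperture_kind(self):
        with pytest.raises(ValueError, match="aperture_solid_angle"):
            StructureSpec(kind="sealed_cage", aperture_solid_angle=0.5)

    def test_structure_deterministic(self):
        spec = StructureSpec(kind="sealed_cage", cage_radius=6.0, n_shell_atoms=100)
        s1, _ = generate_structure(spec, mc_samples=10_000)
        s2, _ = generate_structure(spec, mc_samples=10_000)
        assert np.array_equal(s1.coords, s2.coords)

    def test_every_atom_has_a_residue(self):
        s, _ = generate_structure(
            StructureSpec(kind="sealed_cage", cage_radius=6.0, n_shell_atoms=50),
            mc_samples=10_000,
        )
        assert len(np.unique(s.residue_indices)) == s.n_atoms


class TestMonteCarloOracle:
    def test_fewer_than_four_atoms_is_zero(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], float)
        assert mc_void_volume(coords, np.full(3, 1.8), n_samples=1000) == 0.0

    def test_oracle_deterministic_for_seed(self):
        spec = StructureSpec(kind="sealed_cage", cage_radius=6.0, n_shell_atoms=112)
        s, _ = generate_structure(spec, mc_samples=10_000)
        v1 = mc_void_volume(s.coords, s.radii, n_samples=50_000, seed=4)
        v2 = mc_void_volume(s.coords, s.radii, n_samples=50_000, seed=4)
        assert v1 == v2


class TestFixtureBundle:
    def test_roundtrip_and_checksum_determinism(self, tmp_path):
        from hyscav.alignment import CodonAlignment

        spec = SimulationSpec(n_leaves=4, n_columns=10, seed=6)
        tree = generate_tree(spec)
        aln, truth = evolve_codon_alignment(tree, spec)
        s, gt = generate_structure(
            StructureSpec(kind="sealed_cage", cage_radius=6.0, n_shell_atoms=50),
            columns=list(range(1, 51)),
            mc_samples=10_000,
        )
        m1 = write_fixture_bundle(
            tmp_path / "a", aln, tree, truth, {"root": (s, gt)}, seeds={"seed": 6}
        )
        m2 = write_fixture_bundle(
            tmp_path / "b", aln, tree, truth, {"root": (s, gt)}, seeds={"seed": 6}
        )
        assert m1["files"] == m2["files"]
        back = CodonAlignment.from_fasta(tmp_path / "a" / "alignment.fasta")
        assert back.sequences == aln.sequences

    def test_pdb_residue_count_matches(self, tmp_path):
        from hyscav.structures import Structure

        s, gt = generate_structure(
            StructureSpec(kind="sealed_cage", cage_radius=6.0, n_shell_atoms=64),
            mc_samples=10_000,
        )
        s.to_pdb(tmp_path / "cage.pdb")
        back = Structure.from_pdb(tmp_path / "cage.pdb", radii="uniform")
        assert back.n_atoms == s.n_atoms
        assert len(np.unique(back.residue_indices)) == 64
        assert np.allclose(back.coords, s.coords, atol=1e-2)
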