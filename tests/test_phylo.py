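"""Progressive MSA, distances, neighbor joining, bootstrap, monophyly."""

import math

import numpy as np
import pytest

from oracles import random_additive_matrix, tree_path_lengths
from qsmine import phylo as P
from qsmine.synthetic_data import AA20, EvolutionSpec, simulate_family

SIX_LEAF_TREE = "((A:0.02,B:0.03):0.05,(C:0.02,D:0.04):0.05,(E:0.03,F:0.02):0.04);"


def random_protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


class TestProgressiveMsa:
    def test_identical_pair_aligns_gap_free(self):
        msa = P.progressive_msa({"a": "MKTWHAYI", "b": "MKTWHAYI"})
        assert msa.rows == ["MKTWHAYI", "MKTWHAYI"]

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            P.progressive_msa({"a": "MKT"})

    def test_ungapping_recovers_every_input(self):
        rng = np.random.default_rng(4)
        seqs = {}
        for i in range(5):
            n = int(rng.integers(30, 60))
            seqs[f"s{i}"] = "".join(AA20[j] for j in rng.integers(0, 20, size=n))
        msa = P.progressive_msa(seqs)
        for sid, seq in seqs.items():
            assert msa.ungapped(sid) == seq

    def test_low_divergence_family_recovers_true_homology(self):
        spec = EvolutionSpec(
            root_seq=random_protein(300, 9),
            tree_newick=SIX_LEAF_TREE,
            indel_rate=0.02,
            seed=11,
        )
        sim = simulate_family(spec)
        true_msa = sim.true_msa()
        est = P.progressive_msa({k: sim.leaves[k] for k in sorted(sim.leaves)})

        def homology_pairs(msa):
            pairs = set()
            pos = {i: 0 for i in msa.ids}
            for c in range(msa.n_columns):
                col = []
                for i, row in zip(msa.ids, msa.rows):
                    if row[c] != "-":
                        col.append((i, pos[i]))
                        pos[i] += 1
                for x in range(len(col)):
                    for y in range(x + 1, len(col)):
                        pairs.add((col[x], col[y]))
            return pairs

        truth = homology_pairs(true_msa)
        est_pairs = homology_pairs(est)
        assert len(truth & est_pairs) / len(truth) >= 0.95


class TestDistances:
    def test_identical_rows(self):
        assert P.p_distance("ACDEF", "ACDEF") == (0.0, 5)

    def test_disjoint_gap_patterns_undefined(self):
        assert P.p_distance("AC---", "--DEF") == (None, 0)

    def test_quarter_difference(self):
        assert P.p_distance("ABCD".replace("B", "R"), "ARXD") == (0.25, 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            P.p_distance("AC", "ACD")

    def test_poisson_closed_forms(self):
        assert P.poisson_correct(0.0) == 0.0
        assert P.poisson_correct(0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_poisson_undefined_signals(self):
        with pytest.raises(P.UndefinedDistanceError):
            P.poisson_correct(1.0)
        with pytest.raises(P.UndefinedDistanceError):
            P.poisson_correct(None)

    def test_poisson_increasing_convex_and_dominates_p(self):
        ps = np.linspace(0.0, 0.95, 50)
        ds = np.array([P.poisson_correct(p) for p in ps])
        assert np.all(np.diff(ds) > 0)  # strictly increasing
        assert np.all(np.diff(ds, 2) > -1e-12)  # convex
        assert np.all(ds >= ps)
        assert ds[0] == ps[0] == 0.0

    def test_zero_matrix_for_identical_sequences(self):
        msa = P.Msa(["a", "b", "c"], ["ACDEF"] * 3)
        res = P.build_distance_matrix(msa)
        assert np.all(res.d == 0.0) and not res.failures

    def test_gap_disjoint_sequence_recorded_as_failure(self):
        msa = P.Msa(
            ["a", "b", "c", "d"],
            ["ACDEF-----", "ACDEW-----", "ACDEF-----", "-----ACDEF"],
        )
        res = P.build_distance_matrix(msa)
        assert {(f.id_a, f.id_b) for f in res.failures} == {
            ("a", "d"), ("b", "d"), ("c", "d")
        }
        assert all(f.reason == "no_common_sites" for f in res.failures)
        assert res.failed_sequence_ids() == ["d"]

    def test_distances_recover_true_path_lengths(self):
        spec = EvolutionSpec(
            root_seq=random_protein(500, 21), tree_newick=SIX_LEAF_TREE, seed=3
        )
        sim = simulate_family(spec)
        msa = P.progressive_msa({k: sim.leaves[k] for k in sorted(sim.leaves)})
        res = P.build_distance_matrix(msa)
        for (a, b), td in sim.true_distances.items():
            d = res.d[res.ids.index(a), res.ids.index(b)]
            assert d == pytest.approx(td, abs=0.08)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = P.nj_tree(D, ["a", "b", "c"])
        lengths = {name: bl for (node, bl) in tree.root.children
                   for name in [node.name]}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_matrices_reconstructed_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            D, leaves, true_splits = random_additive_matrix(n, rng)
            tree = P.nj_tree(D, leaves)
            assert tree.bipartitions() == true_splits
            paths = tree_path_lengths(tree)
            for i, a in enumerate(leaves):
                for b in leaves[i + 1:]:
                    assert paths[(a, b)] == pytest.approx(
                        D[leaves.index(a), leaves.index(b)], abs=1e-9
                    )

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(6)
        D, leaves, _ = random_additive_matrix(6, rng)
        perm = list(rng.permutation(6))
        D2 = D[np.ix_(perm, perm)]
        leaves2 = [leaves[i] for i in perm]
        t1 = P.nj_tree(D, leaves)
        t2 = P.nj_tree(D2, leaves2)
        assert t1.bipartitions() == t2.bipartitions()
        p1, p2 = tree_path_lengths(t1), tree_path_lengths(t2)
        for key, v in p1.items():
            assert p2[key] == pytest.approx(v, abs=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        # scikit-bio's NJ as an independent route on an additive matrix
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(13)
        D, leaves, _ = random_additive_matrix(7, rng)
        ours = P.nj_tree(D, leaves).bipartitions()
        sk_tree = skbio_nj(DistanceMatrix(D, ids=leaves))
        all_leaves = frozenset(leaves)
        ref = min(leaves)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            canon = side if ref not in side else all_leaves - side
            if 2 <= len(canon) <= len(leaves) - 2:
                theirs.add(canon)
        assert ours == theirs

    def test_input_validation(self):
        with pytest.raises(ValueError):
            P.nj_tree(np.zeros((2, 2)), ["a", "b"])
        bad = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            P.nj_tree(bad, ["a", "b", "c"])


class TestBootstrap:
    def structured_msa(self, seed=0):
        spec = EvolutionSpec(
            root_seq=random_protein(400, 31), tree_newick=SIX_LEAF_TREE, seed=seed
        )
        sim = simulate_family(spec)
        return P.progressive_msa({k: sim.leaves[k] for k in sorted(sim.leaves)})

    def test_structured_msa_full_supports_no_failures(self):
        msa = self.structured_msa()
        boot = P.bootstrap_supports(msa, 100, seed=5)
        assert boot.failed_count == 0 and boot.successful == 100
        for clade in ({"A", "B"}, {"C", "D"}, {"E", "F"}):
            assert boot.supports[boot.tree.canonical(frozenset(clade))] == 100.0

    def test_failed_count_matches_direct_recount(self):
        msa = P.Msa(
            ["a", "b", "c", "d"],
            ["AC-------", "-CDEFGHIK", "ACDEFGHIK", "ACDEWGHIK"],
        )
        boot = P.bootstrap_supports(msa, 150, seed=3)
        fails = 0
        for r in range(150):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=3, spawn_key=(r,))
            )
            cols = rng.integers(0, msa.n_columns, msa.n_columns)
            rows = ["".join(row[c] for c in cols) for row in msa.rows]
            bad = False
            for i in range(4):
                for j in range(i + 1, 4):
                    p, _ = P.p_distance(rows[i], rows[j])
                    if p is None or p >= 1.0:
                        bad = True
            fails += bad
        assert boot.failed_count == fails > 0
        assert boot.failed_count + boot.successful == 150

    def test_same_seed_identical_results(self):
        msa = self.structured_msa()
        b1 = P.bootstrap_supports(msa, 50, seed=9)
        b2 = P.bootstrap_supports(msa, 50, seed=9)
        assert b1.supports == b2.supports
        assert b1.failed_count == b2.failed_count

    def test_supports_invariant_to_column_order_when_saturated(self):
        msa = self.structured_msa()
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(msa.n_columns))
        shuffled = msa.subset_columns(perm)
        b1 = P.bootstrap_supports(msa, 60, seed=2)
        b2 = P.bootstrap_supports(shuffled, 60, seed=2)
        assert b1.supports == b2.supports

    def test_undefined_reference_matrix_rejected(self):
        msa = P.Msa(["a", "b", "c"], ["AC---", "AC---", "---DE"])
        with pytest.raises(P.UndefinedDistanceError):
            P.bootstrap_supports(msa, 10, seed=0)


class TestMonophyly:
    def make_tree(self):
        rng = np.random.default_rng(8)
        D, leaves, splits = random_additive_matrix(6, rng)
        return P.nj_tree(D, leaves), leaves, splits

    def test_full_set_and_singletons(self):
        tree, leaves, _ = self.make_tree()
        assert P.is_monophyletic(tree, leaves)
        assert P.is_monophyletic(tree, [leaves[0]])

    def test_planted_clades_true_mixed_false(self):
        spec = EvolutionSpec(
            root_seq=random_protein(400, 77), tree_newick=SIX_LEAF_TREE, seed=1
        )
        sim = simulate_family(spec)
        msa = P.progressive_msa({k: sim.leaves[k] for k in sorted(sim.leaves)})
        res = P.build_distance_matrix(msa)
        tree = P.nj_tree(res.d, res.ids)
        assert P.is_monophyletic(tree, {"A", "B"})
        assert P.is_monophyletic(tree, {"C", "D"})
        assert not P.is_monophyletic(tree, {"A", "C", "E"})

    def test_unknown_leaf_rejected(self):
        tree, _, _ = self.make_tree()
        with pytest.raises(KeyError):
            P.is_monophyletic(tree, {"nope"})


class TestWriters:
    def test_newick_round_trips_through_dendropy(self, tmp_path):
        import dendropy

        rng = np.random.default_rng(3)
        D, leaves, _ = random_additive_matrix(5, rng)
        msa_ids = leaves
        tree = P.nj_tree(D, leaves)
        path = tmp_path / "t.nwk"
        P.write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(msa_ids)

    def test_phylip_and_fasta_outputs(self, tmp_path):
        msa = P.Msa(["a", "b", "c"], ["ACDEF", "ACDEW", "AC-EW"])
        res = P.build_distance_matrix(msa)
        P.write_phylip(res, tmp_path / "d.phylip")
        P.write_fasta_msa(msa, tmp_path / "m.faa")
        assert (tmp_path / "d.phylip").read_text().startswith("3\n")
        assert (tmp_path / "m.faa").read_text().count(">") == 3
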