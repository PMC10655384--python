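import math
from collections import Counter

import numpy as np
import pytest

from phyloconflict import seq_qc as sq
from phyloconflict import codon_align as ca
from phyloconflict import synthetic_data as sd
from phyloconflict.treemodel import topology_signature, write_newick


class TestModel:
    def test_requires_rooted_binary_positive(self):
        with pytest.raises(ValueError):
            sd.SpeciesTreeModel.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            sd.SpeciesTreeModel.from_newick("((A:0,B:1):1,C:2);")

    def test_anomaly_scenario_shape(self):
        model = sd.make_anomaly_scenario(0.05, 0.05)
        assert model.taxa() == {"A", "B", "C", "D"}
        sig = topology_signature(model.tree)
        assert tuple(sorted(["A", "B"])) in {tuple(c) for c in sig}
        assert tuple(sorted(["A", "B", "C"])) in {tuple(c) for c in sig}

    def test_anomaly_scenario_validates(self):
        with pytest.raises(ValueError):
            sd.make_anomaly_scenario(0.0, 0.1)


class TestSimulateGeneTree:
    def test_two_taxon_coalescence_time_is_exponential(self):
        model = sd.SpeciesTreeModel.from_newick("(A:1e-09,B:1e-09);")
        rng = np.random.default_rng(1)
        n = 10000
        times = [
            sd.simulate_msc_gene_tree(model, rng).leaves()[0].length
            for _ in range(n)
        ]
        se = 1.0 / math.sqrt(n)  # Exp(1): mean 1, sd 1
        assert abs(np.mean(times) - 1.0) <= 3 * se

    def test_long_branches_recover_species_topology(self):
        model = sd.make_balanced_quartet_model(20.0)
        rng = np.random.default_rng(2)
        species_sig = topology_signature(model.tree)
        match = sum(
            topology_signature(sd.simulate_msc_gene_tree(model, rng))
            == species_sig
            for _ in range(1000)
        )
        # closed form: concordance prob 1 - (2/3)e^-10 > 0.99997 per quartet
        assert match > 990

    def test_branch_lengths_positive_and_rooted(self):
        model = sd.make_anomaly_scenario(0.1, 0.1)
        rng = np.random.default_rng(3)
        tree = sd.simulate_msc_gene_tree(model, rng)
        assert tree.rooted
        for node in tree.preorder():
            if node is not tree.root:
                assert node.length >= 0


class TestSimulateSet:
    def test_full_leaf_sets_without_dropout(self):
        model = sd.make_balanced_quartet_model(1.0)
        trees = sd.simulate_gene_tree_set(model, sd.SimConfig(n_trees=50, seed=0))
        assert len(trees) == 50
        assert all(t.taxa() == model.taxa() for t in trees)

    def test_dropout_mean(self):
        model = sd.SpeciesTreeModel.from_newick(
            "((((A:1,B:1):1,(C:1,D:1):1):1,((E:2,F:2):1,G:3):1):1,"
            "((H:2,I:2):2,J:4):1);"
        )
        cfg = sd.SimConfig(n_trees=1000, dropout=0.1, seed=8)
        trees = sd.simulate_gene_tree_set(model, cfg)
        mean_leaves = np.mean([len(t.leaves()) for t in trees])
        # binomial(10, 0.9): mean 9.0, sd ~0.95; SE over 1000 trees ~0.03
        assert abs(mean_leaves - 9.0) < 0.1

    def test_constant_support(self):
        model = sd.make_balanced_quartet_model(1.0)
        trees = sd.simulate_gene_tree_set(
            model, sd.SimConfig(n_trees=10, support=(100.0, 100.0), seed=1)
        )
        for t in trees:
            for node in t.internal_nodes():
                assert node.support == 100.0

    def test_uniform_support_range(self):
        model = sd.make_balanced_quartet_model(1.0)
        trees = sd.simulate_gene_tree_set(
            model, sd.SimConfig(n_trees=200, support=(0.0, 100.0), seed=1)
        )
        supports = [
            n.support for t in trees for n in t.internal_nodes()
        ]
        assert min(supports) < 20 and max(supports) > 80

    def test_determinism_byte_identical(self):
        model = sd.make_anomaly_scenario(0.2, 0.3)
        cfg = sd.SimConfig(n_trees=25, dropout=0.05, support=(0, 100), seed=123)
        a = [write_newick(t) for t in sd.simulate_gene_tree_set(model, cfg)]
        b = [write_newick(t) for t in sd.simulate_gene_tree_set(model, cfg)]
        assert a == b

    def test_degenerate_dropout_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(n_trees=5, dropout=1.0)

    def test_length_scale(self):
        model = sd.make_balanced_quartet_model(1.0)
        t1 = sd.simulate_gene_tree_set(
            model, sd.SimConfig(n_trees=1, seed=5, length_scale=1.0)
        )[0]
        t2 = sd.simulate_gene_tree_set(
            model, sd.SimConfig(n_trees=1, seed=5, length_scale=10.0)
        )[0]
        l1 = sorted(n.length for n in t1.preorder() if n.length is not None)
        l2 = sorted(n.length for n in t2.preorder() if n.length is not None)
        assert np.allclose(np.array(l1) * 10.0, l2)


class TestExpectedQuartetFreqs:
    def test_t_zero_uniform(self):
        assert sd.expected_quartet_freqs(0.0) == pytest.approx((1 / 3,) * 3)

    def test_large_t_limit(self):
        f = sd.expected_quartet_freqs(50.0)
        assert f[0] == pytest.approx(1.0)
        assert f[1] == pytest.approx(0.0, abs=1e-12)

    def test_t_one_value(self):
        f = sd.expected_quartet_freqs(1.0)
        assert round(f[0], 5) == 0.75475
        assert round(f[1], 5) == 0.12263

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sd.expected_quartet_freqs(-0.1)

    def test_sums_to_one(self):
        for t in (0.0, 0.3, 1.7, 9.0):
            assert sum(sd.expected_quartet_freqs(t)) == pytest.approx(1.0)


class TestCrossOracleMsprime:
    def test_topology_spectrum_matches_msprime(self):
        msprime = pytest.importorskip("msprime")
        scipy_stats = pytest.importorskip("scipy.stats")

        t_internal = 1.0
        n = 10000
        model = sd.make_balanced_quartet_model(t_internal)
        trees = sd.simulate_gene_tree_set(model, sd.SimConfig(n_trees=n, seed=77))

        def unrooted_topo(tree):
            sig = {c for c in topology_signature(tree) if len(c) == 2}
            if ("A", "B") in sig or ("C", "D") in sig:
                return 1
            if ("A", "C") in sig or ("B", "D") in sig:
                return 2
            return 3

        ours = Counter(unrooted_topo(t) for t in trees)

        # independent oracle: msprime with matching split times
        # (time unit = 1 coalescent unit: ploidy 1, population size 1)
        demography = msprime.Demography()
        for name in "ABCD":
            demography.add_population(name=name, initial_size=1)
        for name in ("AB", "CD", "R"):
            demography.add_population(name=name, initial_size=1)
        demography.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
        demography.add_population_split(time=1.0, derived=["C", "D"], ancestral="CD")
        # model has two internal branches of t/2 each (x + y = t)
        demography.add_population_split(
            time=1.0 + t_internal / 2.0, derived=["AB", "CD"], ancestral="R"
        )
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1, "D": 1},
            demography=demography,
            ploidy=1,
            num_replicates=n,
            random_seed=4242,
        )
        pair_to_topo = {
            frozenset({0, 1}): 1,
            frozenset({2, 3}): 1,
            frozenset({0, 2}): 2,
            frozenset({1, 3}): 2,
            frozenset({0, 3}): 3,
            frozenset({1, 2}): 3,
        }
        theirs = Counter()
        for ts in reps:
            tree = ts.first()
            # leaves 0..3 = A..D; any two-leaf cherry fixes the unrooted topology
            for leaf in range(4):
                cherry = frozenset(tree.children(tree.parent(leaf)))
                if cherry in pair_to_topo:
                    theirs[pair_to_topo[cherry]] += 1
                    break
            else:  # pragma: no cover - binary trees always have a leaf cherry
                raise AssertionError("no leaf cherry found")
        table = [
            [ours[i] for i in (1, 2, 3)],
            [theirs[i] for i in (1, 2, 3)],
        ]
        _, p, _, _ = scipy_stats.chi2_contingency(table)
        assert p > 0.01


class TestToyFixtures:
    def test_short_sequences_planted_exactly(self):
        fx = sd.make_toy_gene_fixtures(genes=2, samples=5, n_short=3, seed=1)
        for gene, manifest in fx.manifest.items():
            _, removed = sq.filter_short_sequences(
                fx.proteins[gene], manifest["target_length"]
            )
            assert sorted(removed) == sorted(manifest["short_samples"])
            assert len(removed) == 3

    def test_stop_codons_planted_exactly(self):
        fx = sd.make_toy_gene_fixtures(genes=2, samples=4, n_stops=2, seed=2)
        for gene, manifest in fx.manifest.items():
            total_stars = sum(p.count("*") for p in fx.proteins[gene].values())
            assert total_stars == manifest["n_stop_codons"] == 2
            masked = {
                s: ca.mask_stop_codons(p) for s, p in fx.proteins[gene].items()
            }
            changed = sum(
                a != b
                for s in masked
                for a, b in zip(masked[s], fx.proteins[gene][s])
            )
            assert changed == 2

    def test_low_occupancy_columns_planted_exactly(self):
        fx = sd.make_toy_gene_fixtures(
            genes=1, samples=4, n_short=0, n_low_occupancy_columns=4, seed=3
        )
        gene = "g1"
        aln = fx.protein_alignments[gene]
        assert aln.n_rows == 4
        masked = ca.Alignment(
            aln.names, [ca.mask_stop_codons(r) for r in aln.rows], "aa"
        )
        codon, errs = ca.thread_codons(masked, fx.cds[gene])
        assert not errs
        trimmed, kept = ca.trim_low_occupancy_columns(codon)
        removed_codons = (codon.n_columns - len(kept)) // 3
        assert removed_codons == 4

    def test_deterministic(self):
        a = sd.make_toy_gene_fixtures(seed=9)
        b = sd.make_toy_gene_fixtures(seed=9)
        assert a.proteins == b.proteins
        assert a.cds == b.cds
        assert a.manifest == b.manifest
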