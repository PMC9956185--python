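import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecoassembly.assembly import (
    DegenerateNullError,
    PairAssembly,
    ProcessSummary,
    PROCESSES,
    assembly_analysis,
    bmntd,
    bnti,
    bnti_exact,
    classify_pair,
    pair_seed,
    patristic_distances,
    per_site_fractions,
    raup_crick_bc,
    rc_score,
    reconstitute_counts,
    summarize_processes,
)
from ecoassembly.io import OTUTable, ValidationError, to_relative
from ecoassembly.matrices import PairwiseMatrix

from .conftest import patchy_table, random_table, random_ultrametric_tree, tree_from_newick


class TestPatristic:
    def test_cherry_sum_of_lengths(self):
        tree = tree_from_newick("(A:1.0,B:2.0);")
        d = patristic_distances(tree)
        assert d.value("A", "B") == pytest.approx(3.0)

    def test_ultrametric_root_spanning_pairs_equal(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        d = patristic_distances(tree, ["A", "B", "C", "D"])
        across = [d.value(a, b) for a in "AB" for b in "CD"]
        assert np.allclose(across, across[0])
        assert across[0] == pytest.approx(4.0)

    def test_floyd_warshall_oracle(self, rng):
        tree = random_ultrametric_tree(rng, 20, height=2.0)
        # perturb lengths so the tree is not ultrametric
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length += float(rng.uniform(0, 0.1))
        d = patristic_distances(tree)
        g = nx.Graph()
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                g.add_edge(id(node), id(child), weight=child.edge.length)
        tips = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
        sp = dict(nx.all_pairs_dijkstra_path_length(g))
        for i, a in enumerate(d.labels):
            for b in d.labels[i + 1 :]:
                assert d.value(a, b) == pytest.approx(sp[tips[a]][tips[b]], abs=1e-9)

    def test_missing_tip_listed(self, four_tip_tree):
        with pytest.raises(ValueError, match="Z"):
            patristic_distances(four_tip_tree, ["A", "Z"])

    def test_missing_branch_length_errors(self):
        tree = tree_from_newick("(A:1,(B,C:1):1);")
        with pytest.raises(ValueError, match="branch length"):
            patristic_distances(tree)

    def test_pruning_matches_full(self, four_tip_tree):
        full = patristic_distances(four_tip_tree)
        sub = patristic_distances(four_tip_tree, ["A", "C"])
        assert sub.value("A", "C") == pytest.approx(full.value("A", "C"))


class TestBmntd:
    def test_identical_communities_zero(self, four_tip_distances):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        assert bmntd(a, a.copy(), four_tip_distances) == 0.0

    def test_single_taxon_pair_closed_form(self, four_tip_distances):
        a = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 0.0])
        expected = four_tip_distances.value("A", "C")
        assert bmntd(a, b, four_tip_distances) == pytest.approx(expected)

    def test_double_loop_oracle(self, rng):
        tree = random_ultrametric_tree(rng, 6)
        d = patristic_distances(tree)
        a = rng.dirichlet(np.ones(6)) * (rng.uniform(size=6) > 0.3)
        b = rng.dirichlet(np.ones(6)) * (rng.uniform(size=6) > 0.3)
        a[0] = max(a[0], 0.1)
        b[1] = max(b[1], 0.1)
        a, b = a / a.sum(), b / b.sum()

        def oracle(x, y):
            ix = [i for i in range(6) if x[i] > 0]
            iy = [j for j in range(6) if y[j] > 0]
            fx = np.array([x[i] for i in ix])
            fx = fx / fx.sum()
            total = 0.0
            for w, i in zip(fx, ix):
                total += w * min(d.values[i, j] for j in iy)
            return total

        expected = 0.5 * (oracle(a, b) + oracle(b, a))
        assert bmntd(a, b, d) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_property(self, rng):
        tree = random_ultrametric_tree(rng, 10)
        d = patristic_distances(tree)
        for _ in range(10):
            a = rng.dirichlet(np.ones(10)) * (rng.uniform(size=10) > 0.4)
            b = rng.dirichlet(np.ones(10)) * (rng.uniform(size=10) > 0.4)
            if a.sum() == 0 or b.sum() == 0:
                continue
            a, b = a / a.sum(), b / b.sum()
            assert bmntd(a, b, d) == pytest.approx(bmntd(b, a, d), abs=1e-12)

    def test_empty_community_errors(self, four_tip_distances):
        with pytest.raises(ValidationError):
            bmntd(np.zeros(4), np.array([1.0, 0, 0, 0]), four_tip_distances)


def two_sample_table(counts_a, counts_b, taxa=None):
    taxa = taxa or [f"OTU_{i + 1}" for i in range(len(counts_a))]
    return OTUTable(taxa, ["x", "y"], np.column_stack([counts_a, counts_b]).astype(float))


class TestBnti:
    def test_star_phylogeny_degenerate(self):
        star = PairwiseMatrix(
            ["A", "B", "C", "D"], 2.0 * (1 - np.eye(4)), "phylo_patristic"
        )
        table = two_sample_table([5, 1, 0, 0], [0, 0, 3, 2], ["A", "B", "C", "D"])
        with pytest.raises(DegenerateNullError):
            bnti(("x", "y"), table, star, reps=99, seed=0)

    def test_exact_enumeration_vs_monte_carlo(self, four_tip_tree):
        d = patristic_distances(four_tip_tree)
        table = two_sample_table([5, 3, 0, 0], [0, 1, 4, 2], ["A", "B", "C", "D"])
        obs_e, z_e = bnti_exact(("x", "y"), table, d)
        obs_m, z_m = bnti(("x", "y"), table, d, reps=10_000, seed=1)
        assert obs_m == pytest.approx(obs_e, abs=1e-12)
        assert z_m == pytest.approx(z_e, abs=0.1)

    def test_determinism(self, four_tip_tree):
        d = patristic_distances(four_tip_tree)
        table = two_sample_table([5, 3, 0, 1], [0, 1, 4, 2], ["A", "B", "C", "D"])
        r1 = bnti(("x", "y"), table, d, reps=199, seed=11)
        r2 = bnti(("x", "y"), table, d, reps=199, seed=11)
        assert r1 == r2


class TestRaupCrick:
    def diverse_table(self, rng, n_taxa=15, n_samples=8, depth=100):
        return random_table(rng, n_taxa=n_taxa, n_samples=n_samples, depth=depth)

    def test_obs_below_all_nulls_gives_minus_one(self, rng):
        # two identical samples embedded in a diverse region: BC_obs = 0
        t = self.diverse_table(rng)
        counts = t.counts.copy()
        counts[:, 1] = counts[:, 0]
        t = OTUTable(t.taxon_ids, t.sample_ids, counts)
        bc, rc = raup_crick_bc((t.sample_ids[0], t.sample_ids[1]), t, reps=99, seed=0)
        assert bc == 0.0
        assert rc == -1.0

    def test_obs_above_all_nulls_gives_plus_one(self):
        # near-disjoint samples: nulls contain both taxa at balanced regional
        # abundance, so every null BC is far below the observed ~0.96
        counts = np.array(
            [[50.0, 1.0, 25.0, 30.0], [1.0, 50.0, 25.0, 20.0]],
        )
        t = OTUTable(["a", "b"], ["x", "y", "r1", "r2"], counts)
        bc, rc = raup_crick_bc(("x", "y"), t, reps=99, seed=0)
        assert bc == pytest.approx(98 / 102)
        assert rc == 1.0

    def test_rc_score_monotone_in_obs(self, rng):
        nulls = rng.uniform(0, 1, 999)
        values = np.sort(rng.uniform(-0.1, 1.1, 50))
        scores = [rc_score(nulls, v) for v in values]
        assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))
        assert rc_score(nulls, -1.0) == -1.0
        assert rc_score(nulls, 2.0) == 1.0

    def test_cross_implementation_oracle(self, rng):
        """Independent null sampler (different RNG + sequential weighted
        sampling) reproduces RC within +-0.05 on a small fixed table."""
        import random as pyrandom

        counts = np.array(
            [
                [30.0, 2.0, 10.0, 5.0],
                [5.0, 20.0, 10.0, 0.0],
                [0.0, 8.0, 4.0, 6.0],
                [1.0, 0.0, 3.0, 2.0],
                [4.0, 10.0, 0.0, 7.0],
            ]
        )
        t = OTUTable([f"t{i}" for i in range(5)], ["x", "y", "r1", "r2"], counts)
        reps = 4000
        _, rc = raup_crick_bc(("x", "y"), t, reps=reps, seed=5)

        occurrence = (counts > 0).sum(axis=1).astype(float)
        regional = counts.sum(axis=1) / counts.sum()
        pyrng = pyrandom.Random(99)

        def null_sample(col):
            richness = int((col > 0).sum())
            total = int(col.sum())
            chosen: list[int] = []
            avail = list(range(5))
            w = occurrence.tolist()
            for _ in range(richness):
                pick = pyrng.choices(range(len(avail)), weights=[w[a] for a in avail])[0]
                chosen.append(avail.pop(pick))
            p = np.array([regional[c] for c in chosen])
            p = p / p.sum()
            alloc = np.zeros(5)
            extra = np.random.default_rng(pyrng.getrandbits(32)).multinomial(
                total - len(chosen), p
            )
            for c, k in zip(chosen, extra):
                alloc[c] = 1 + k
            return alloc

        obs_bc = np.abs(counts[:, 0] - counts[:, 1]).sum() / (counts[:, 0] + counts[:, 1]).sum()
        nulls = np.empty(reps)
        for r in range(reps):
            na, nb = null_sample(counts[:, 0]), null_sample(counts[:, 1])
            nulls[r] = np.abs(na - nb).sum() / (na + nb).sum()
        rc_oracle = rc_score(nulls, obs_bc)
        assert rc == pytest.approx(rc_oracle, abs=0.05)

    def test_requires_integer_counts(self, rng):
        rel = to_relative(random_table(rng))
        with pytest.raises(ValidationError):
            raup_crick_bc(("s1", "s2"), rel, reps=99, seed=0)

    def test_zero_count_sample_errors(self):
        t = OTUTable(["a"], ["x", "y"], np.array([[1.0, 0.0]]))
        with pytest.raises(ValidationError):
            raup_crick_bc(("x", "y"), t, reps=99, seed=0)

    def test_determinism(self, rng):
        t = self.diverse_table(rng)
        pair = (t.sample_ids[0], t.sample_ids[3])
        assert raup_crick_bc(pair, t, reps=199, seed=4) == raup_crick_bc(
            pair, t, reps=199, seed=4
        )


class TestReconstituteCounts:
    def test_columns_sum_to_depth(self, rng):
        rel = to_relative(random_table(rng))
        counts = reconstitute_counts(rel, depth=10_000)
        np.testing.assert_array_equal(counts.counts.sum(axis=0), 10_000)
        assert np.allclose(counts.counts, np.round(counts.counts))

    def test_proportions_preserved(self, rng):
        rel = to_relative(random_table(rng, depth=1000))
        counts = reconstitute_counts(rel, depth=100_000)
        np.testing.assert_allclose(counts.counts / 100_000, rel.counts, atol=1e-5)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "b,r,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (2.5, -1.0, "heterogeneous_selection"),
            (-2.5, 1.0, "homogeneous_selection"),
            (0.3, 0.99, "dispersal_limitation"),
            (-1.9, -0.97, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.99, "dispersal_limitation"),  # boundary: |bnti| <= 2
            (0.0, 0.95, "undominated"),  # boundary: rc must exceed 0.95
        ],
    )
    def test_truth_table(self, b, r, expected):
        assert classify_pair(b, r) == expected

    def test_grid_partitions_plane(self):
        bvals = np.linspace(-4, 4, 41)
        rvals = np.linspace(-1, 1, 41)
        for b in bvals:
            for r in rvals:
                p = classify_pair(b, r)
                assert p in PROCESSES
                # exhaustive re-derivation from the rule
                if b > 2:
                    assert p == "heterogeneous_selection"
                elif b < -2:
                    assert p == "homogeneous_selection"
                elif r > 0.95:
                    assert p == "dispersal_limitation"
                elif r < -0.95:
                    assert p == "homogenizing_dispersal"
                else:
                    assert p == "undominated"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(np.nan, 0.0)
        with pytest.raises(ValueError):
            classify_pair(0.0, np.inf)


class TestSummaries:
    def pair(self, a, b, process):
        return PairAssembly(a, b, 0.1, 0.0, 0.2, 0.0, process, 99, 1)

    def test_single_class(self):
        pairs = [self.pair("a", "b", "undominated")]
        out = summarize_processes(pairs, strata=("all",))
        assert out[0].fractions["undominated"] == 1.0

    def test_2_1_1_arithmetic(self):
        pairs = [
            self.pair("a", "b", "dispersal_limitation"),
            self.pair("a", "c", "dispersal_limitation"),
            self.pair("b", "c", "heterogeneous_selection"),
            self.pair("c", "d", "undominated"),
        ]
        out = summarize_processes(pairs, strata=("all",))[0]
        assert out.fractions["dispersal_limitation"] == 0.5
        assert out.fractions["heterogeneous_selection"] == 0.25
        assert out.fractions["undominated"] == 0.25
        assert out.n_pairs == 4

    def test_bruteforce_tally_oracle(self, rng):
        procs = [PROCESSES[i] for i in rng.integers(0, len(PROCESSES), 60)]
        pairs = [self.pair(f"a{i}", f"b{i}", p) for i, p in enumerate(procs)]
        out = summarize_processes(pairs, strata=("all",))[0]
        for p in PROCESSES:
            assert out.fractions[p] == pytest.approx(procs.count(p) / 60)
        assert sum(out.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_within_layer_strata(self):
        layer_of = {"s1": "surface", "s2": "surface", "b1": "bottom", "b2": "bottom"}
        pairs = [
            self.pair("s1", "s2", "dispersal_limitation"),
            self.pair("b1", "b2", "undominated"),
            self.pair("s1", "b1", "heterogeneous_selection"),  # cross-layer
        ]
        out = {s.stratum: s for s in summarize_processes(pairs, layer_of=layer_of)}
        assert out["surface"].n_pairs == 1
        assert out["surface"].fractions["dispersal_limitation"] == 1.0
        assert out["bottom"].fractions["undominated"] == 1.0
        assert out["all"].n_pairs == 3

    def test_fraction_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            ProcessSummary("all", {"undominated": 0.5}, 2)

    def test_per_site_fractions(self):
        pairs = pd.DataFrame(
            [
                {"sample_a": "x", "sample_b": "y", "process": "undominated"},
                {"sample_a": "x", "sample_b": "z", "process": "dispersal_limitation"},
            ]
        )
        site_of = {"x": "A", "y": "B", "z": "C"}
        out = per_site_fractions(pairs, site_of).set_index("site_id")
        assert out.loc["A", "n_pairs"] == 2
        assert out.loc["A", "undominated"] == 0.5
        assert out.loc["B", "undominated"] == 1.0


class TestPairSeedAndParallel:
    def test_pair_seed_symmetric_and_stable(self):
        assert pair_seed(42, "a", "b") == pair_seed(42, "b", "a")
        assert pair_seed(42, "a", "b") != pair_seed(43, "a", "b")
        assert pair_seed(42, "a", "b") == pair_seed(42, "a", "b")

    def test_parallel_matches_serial_bitwise(self, rng):
        tree = random_ultrametric_tree(rng, 12)
        table = patchy_table(rng, n_taxa=12, n_samples=5, depth=300)
        serial = assembly_analysis(table, tree, reps=99, seed=5, n_jobs=1)
        parallel = assembly_analysis(table, tree, reps=99, seed=5, n_jobs=2)
        pd.testing.assert_frame_equal(serial, parallel)

    def test_pair_order_does_not_matter(self, rng):
        tree = random_ultrametric_tree(rng, 10)
        table = patchy_table(rng, n_taxa=10, n_samples=4, depth=200)
        pairs = [("s1", "s2"), ("s3", "s4")]
        a = assembly_analysis(table, tree, reps=99, seed=5, pairs=pairs)
        b = assembly_analysis(table, tree, reps=99, seed=5, pairs=pairs[::-1])
        merged = b.sort_values("sample_a").reset_index(drop=True)
        pd.testing.assert_frame_equal(a.sort_values("sample_a").reset_index(drop=True), merged)


class TestNeutralCalibration:
    def test_iid_multinomial_bnti_and_rc_centered(self):
        """Communities drawn i.i.d. from one pool: bNTI ~ 0 and RC central.

        Scaled-down version of the acceptance calibration (20 pairs x 199
        reps); the full 50 x 999 run lives in test_acceptance.py.
        """
        rng = np.random.default_rng(202)
        n_taxa = 40
        tree = random_ultrametric_tree(rng, n_taxa)
        taxa = [f"T{i + 1}" for i in range(n_taxa)]
        # uniform pool with partial occupancy: the occurrence-weighted null
        # then matches the i.i.d. presence process and RC centers on 0
        pool = np.full(n_taxa, 1.0 / n_taxa)
        counts = np.column_stack([rng.multinomial(80, pool) for _ in range(20)])
        table = OTUTable(taxa, [f"s{j}" for j in range(20)], counts.astype(float))
        d = patristic_distances(tree, taxa)
        pairs = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(10)]
        df = assembly_analysis(table, d, reps=199, seed=31, pairs=pairs)
        assert abs(df.bnti.mean()) < 0.5
        assert -0.5 < df.rc.mean() < 0.5
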