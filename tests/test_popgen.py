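import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from skbio.stats.distance import mantel as skbio_mantel

from hrmhap.haplotyping import HaplotypeSet, pairwise_differences, reduce_indels
from hrmhap.popgen import (
    DifferentiationMatrix,
    PopulationTable,
    amova,
    geo_distances,
    haversine_km,
    mantel_ibd,
    nj_populations,
    pairwise_differentiation,
    parsimony_connection_limit,
    sp_network,
)


def make_table(rows):
    """rows: (population, lat, lon, group, {hap: count})"""
    haps = sorted({h for r in rows for h in r[4]})
    data = [
        {"population": p, "latitude": la, "longitude": lo, "group": g,
         **{h: c.get(h, 0) for h in haps}}
        for p, la, lo, g, c in rows
    ]
    return PopulationTable(pd.DataFrame(data))


def oracle_pair(c1, c2, measure):
    """Literal transcription of the pairwise diversity-partition formulas."""
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    n1, n2 = c1.sum(), c2.sum()
    p1, p2 = c1 / n1, c2 / n2
    hs = ((n1 / (n1 - 1)) * (1 - (p1**2).sum())
          + (n2 / (n2 - 1)) * (1 - (p2**2).sum())) / 2
    pbar = (p1 + p2) / 2
    n_harm = 2 / (1 / n1 + 1 / n2)
    ht = 1 - (pbar**2).sum() + hs / (2 * n_harm)
    ht = max(ht, hs)
    if measure == "gst":
        return (ht - hs) / ht if ht > 0 else 0.0
    if measure == "gpp_st":
        return 2 * (ht - hs) / ((2 * ht - hs) * (1 - hs)) if ht > 0 and hs < 1 else 0.0
    if measure == "jost_d":
        return 2 * (ht - hs) / (1 - hs) if hs < 1 else 0.0
    raise ValueError(measure)


class TestDifferentiation:
    def test_identical_frequencies_give_zero(self):
        table = make_table([
            ("p1", 0.0, 0.0, "g", {"A": 10, "B": 10}),
            ("p2", 1.0, 1.0, "g", {"A": 5, "B": 5}),
        ])
        for measure in ("gst", "gpp_st", "jost_d"):
            assert pairwise_differentiation(table, measure).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_for_different_haplotypes_maximizes_jost_d(self, population_table):
        """Two populations fixed for private haplotypes (Hs=0, Ht>0)."""
        mat = pairwise_differentiation(population_table, "jost_d")
        i = mat.populations.index("GAR")  # all D
        j = mat.populations.index("BP")   # all A
        assert mat.values[i, j] == pytest.approx(1.0, abs=1e-9)

    def test_measures_match_literal_formula_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            counts = rng.integers(0, 12, size=(3, 4))
            counts[:, 0] += 1  # nonzero populations
            table = make_table([
                (f"p{i}", float(i), float(i), "g",
                 {f"H{j}": int(counts[i, j]) for j in range(4)})
                for i in range(3)
            ])
            for measure in ("gst", "gpp_st", "jost_d"):
                mat = pairwise_differentiation(table, measure)
                for i, j in itertools.combinations(range(3), 2):
                    expected = min(max(oracle_pair(counts[i], counts[j], measure), 0.0), 1.0)
                    assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matrix_invariants_and_standardization_inflation(self, population_table):
        gst = pairwise_differentiation(population_table, "gst")
        gpp = pairwise_differentiation(population_table, "gpp_st")
        for mat in (gst, gpp):
            v = mat.values
            assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
            assert v.min() >= -1e-9 and v.max() <= 1 + 1e-9
        # G''st >= Gst wherever within-population diversity exists
        counts = population_table.counts.values
        for i, j in itertools.combinations(range(len(counts)), 2):
            hs_raw = oracle_pair(counts[i], counts[j], "gst")
            if gpp.values[i, j] > 0 and gst.values[i, j] < 1:
                assert gpp.values[i, j] >= gst.values[i, j] - 1e-9

    def test_prevosti_counts_indel_once(self):
        table = make_table([
            ("p1", 0.0, 0.0, "g", {"A": 10, "B": 0}),
            ("p2", 1.0, 1.0, "g", {"A": 0, "B": 10}),
        ])
        hapset = reduce_indels(HaplotypeSet("l", {
            "A": "ACGTACGTAT", "B": "ACG----TAT",
        }))
        mat = pairwise_differentiation(table, "prevosti", haplotypes=hapset)
        # one polymorphic (indel-coded) site, fully fixed -> distance 1
        assert mat.values[0, 1] == pytest.approx(1.0)

    def test_prevosti_requires_indel_coded_sequences(self, population_table):
        with pytest.raises(ValueError, match="requires haplotype sequences|indel-coded"):
            pairwise_differentiation(population_table, "prevosti")

    def test_unknown_measure_rejected(self, population_table):
        with pytest.raises(ValueError, match="unknown measure"):
            pairwise_differentiation(population_table, "fst")


class TestGeoDistances:
    def test_self_distance_zero(self, population_table):
        d = geo_distances(population_table)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_antipodal_points_half_circumference(self):
        table = make_table([
            ("p1", 0.0, 0.0, "g", {"A": 1}),
            ("p2", 0.0, 180.0, "g", {"A": 1}),
            ("p3", 45.0, 10.0, "g", {"A": 1}),
        ])
        d = geo_distances(table)
        assert d.values[0, 1] == pytest.approx(np.pi * 6371.0088, abs=1e-6)

    def test_matches_spherical_law_of_cosines_oracle(self):
        """Independent great-circle formula agrees within 0.5%."""
        lat1, lon1, lat2, lon2 = -33.88, 22.40, -33.91, 22.67
        phi1, phi2 = np.radians(lat1), np.radians(lat2)
        dlmb = np.radians(lon2 - lon1)
        oracle = 6371.0088 * np.arccos(
            np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlmb)
        )
        ours = haversine_km(lat1, lon1, lat2, lon2)
        assert abs(ours - oracle) / oracle < 0.005

    def test_log_transform_requires_distinct_coordinates(self):
        table = make_table([
            ("p1", 1.0, 1.0, "g", {"A": 1}),
            ("p2", 1.0, 1.0, "g", {"A": 1}),
        ])
        with pytest.raises(ValueError, match="zero distances"):
            geo_distances(table, transform="log")


class TestMantel:
    def test_affine_relationship_gives_r_one_and_min_p(self):
        rng = np.random.default_rng(0)
        n = 7
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(1, 10, size=len(iu[0]))
        d = d + d.T
        g = 0.3 * d + 2.0
        np.fill_diagonal(g, 0)
        res = mantel_ibd(g, d, n_permutations=999, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        # random permutation sampling can redraw the identity, so the
        # attained p sits at (1 + #identity draws) / (n_perm + 1)
        assert res.p_value <= 4 / 1000

    def test_null_p_values_uniform(self):
        """Independent random matrices: rejection rate at alpha=0.05 stays
        inside the 99.9% binomial envelope over 1000 replicates."""
        rng = np.random.default_rng(2024)
        n = 6
        iu = np.triu_indices(n, 1)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = np.zeros((n, n))
            b = np.zeros((n, n))
            a[iu] = rng.normal(size=len(iu[0]))
            b[iu] = rng.normal(size=len(iu[0]))
            a, b = a + a.T, b + b.T
            res = mantel_ibd(a, b, n_permutations=99, seed=rng)
            if res.p_value <= 0.05:
                rejections += 1
        sd = np.sqrt(reps * 0.05 * 0.95)
        assert abs(rejections - reps * 0.05) < 3.3 * sd

    def test_agrees_with_skbio_reference(self, population_table):
        gst = pairwise_differentiation(population_table, "gst")
        geo = geo_distances(population_table)
        ours = mantel_ibd(gst, geo, n_permutations=999, seed=3)
        ref_r, ref_p, _ = skbio_mantel(
            skbio.DistanceMatrix(gst.values, ids=gst.populations),
            skbio.DistanceMatrix(geo.values, ids=list(geo.columns)),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(ref_r, abs=1e-12)
        assert ours.p_value == pytest.approx(ref_p, abs=0.03)

    def test_constant_matrix_rejected(self):
        g = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel_ibd(g, g * 0 + (1 - np.eye(4)), n_permutations=99, seed=0)

    def test_log_distance_fit_weaker_than_linear_for_gst(self, population_table):
        gst = pairwise_differentiation(population_table, "gst")
        lin = mantel_ibd(gst, geo_distances(population_table), 99, seed=0)
        log = mantel_ibd(gst, geo_distances(population_table, "log"), 99, seed=0,
                         transform="log")
        assert log.r_squared < lin.r_squared


def two_state_hapset():
    return HaplotypeSet("l", {"X": "A" * 49 + "A", "Y": "A" * 49 + "T"}, indel_coded=True)


class TestAmova:
    def test_identical_populations_put_all_variance_within(self):
        table = make_table([
            ("p1", 0.0, 0.0, "g1", {"X": 6, "Y": 6}),
            ("p2", 0.0, 1.0, "g1", {"X": 6, "Y": 6}),
            ("p3", 1.0, 0.0, "g2", {"X": 6, "Y": 6}),
            ("p4", 1.0, 1.0, "g2", {"X": 6, "Y": 6}),
        ])
        res = amova(table, two_state_hapset(), n_permutations=99, seed=0)
        assert res.percentages["within_populations"] == pytest.approx(100.0, abs=1e-9)
        assert res.percentages["among_groups"] == pytest.approx(0.0, abs=1e-9)

    def test_two_fixed_groups_hand_example(self):
        """Two groups of two populations, each group fixed for a private
        haplotype one step apart, n=2 per population.  By hand:
        SS_total = 2, SS within populations and within groups = 0, so the
        among-group component is the only nonzero one (100%)."""
        table = make_table([
            ("p1", 0.0, 0.0, "g1", {"X": 2}),
            ("p2", 0.0, 1.0, "g1", {"X": 2}),
            ("p3", 1.0, 0.0, "g2", {"Y": 2}),
            ("p4", 1.0, 1.0, "g2", {"Y": 2}),
        ])
        res = amova(table, two_state_hapset(), n_permutations=99, seed=0)
        assert res.sums_of_squares["among_groups"] == pytest.approx(2.0)
        assert res.sums_of_squares["within_populations"] == pytest.approx(0.0)
        assert res.percentages["among_groups"] == pytest.approx(100.0)
        assert res.phi["phi_ct"] == pytest.approx(1.0)

    def test_percentages_sum_to_100_and_seed_reproducible(
        self, population_table, wild_haplotypes
    ):
        res1 = amova(population_table, wild_haplotypes, n_permutations=99, seed=5)
        res2 = amova(population_table, wild_haplotypes, n_permutations=99, seed=5)
        assert sum(res1.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert res1.p_values == res2.p_values
        assert res1.phi == res2.phi

    def test_single_group_rejected(self):
        table = make_table([
            ("p1", 0.0, 0.0, "g1", {"X": 2}),
            ("p2", 0.0, 1.0, "g1", {"Y": 2}),
        ])
        with pytest.raises(ValueError, match="one-level"):
            amova(table, two_state_hapset(), n_permutations=9, seed=0)


def minimax_steps(hapset):
    """Oracle: minimax path ('widest path') distances over the complete
    graph of mutational steps; an edge belongs to a tie-preserving minimum
    spanning network iff its direct distance equals the minimax distance."""
    labels = hapset.labels
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_differences(hapset, labels[i], labels[j])
    mm = d.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                mm[i, j] = min(mm[i, j], max(mm[i, k], mm[k, j]))
    return labels, d, mm


class TestSPNetwork:
    def test_single_step_pair(self):
        hapset = HaplotypeSet("l", {"A": "AAAA", "B": "AAAT"}, indel_coded=True)
        net = sp_network(hapset, limit=5)
        assert net.edge_list() == [("A", "B", 1)]
        assert net.haplotype_nodes == ["A", "B"]

    def test_wild_haplotypes_form_star_around_central(self, wild_haplotypes):
        import networkx as nx

        net = sp_network(wild_haplotypes)
        # contract inferred intermediates: haplotype-level adjacency
        adj = {h: set() for h in net.haplotype_nodes}
        g = net.graph
        for a, b in itertools.combinations(net.haplotype_nodes, 2):
            path = nx.shortest_path(g, a, b)
            if all(g.nodes[n].get("inferred", False) for n in path[1:-1]):
                adj[a].add(b)
                adj[b].add(a)
        degrees = {h: len(adj[h]) for h in adj}
        assert degrees["A"] == 4
        assert all(degrees[h] == 1 for h in "BCDE")

    def test_edges_subset_of_msn_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_hap = int(rng.integers(3, 7))
            length = 40
            seqs = {}
            base = rng.choice(list("ACGT"), size=length)
            for i in range(n_hap):
                s = base.copy()
                for site in rng.choice(length, size=rng.integers(0, 4), replace=False):
                    s[site] = rng.choice(list("ACGT"))
                seqs[f"H{i}"] = "".join(s)
            if len(set(seqs.values())) < len(seqs):
                continue
            hapset = HaplotypeSet("l", seqs, indel_coded=True)
            net = sp_network(hapset, limit=length)
            labels, d, mm = minimax_steps(hapset)
            idx = {lab: i for i, lab in enumerate(labels)}
            for u, v, steps in net.edge_list():
                if u in idx and v in idx:  # haplotype-haplotype edges
                    assert d[idx[u], idx[v]] == steps
                    assert mm[idx[u], idx[v]] == steps

    def test_connection_limit_enforced(self):
        hapset = HaplotypeSet("l", {"A": "AAAAAA", "B": "TTTTTT"}, indel_coded=True)
        net = sp_network(hapset, limit=3)
        assert net.edge_list() == []  # 6 steps > limit

    def test_parsimony_limit_scales_with_length(self):
        assert parsimony_connection_limit(561) == 8
        assert parsimony_connection_limit(5610) > parsimony_connection_limit(561)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sp_network(HaplotypeSet("l", {}, indel_coded=True))


class TestNeighborJoining:
    def test_three_populations_unique_topology(self):
        mat = DifferentiationMatrix(
            "jost_d", ("p1", "p2", "p3"),
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.5], [0.4, 0.5, 0]]),
        )
        tree = skbio.TreeNode.read([nj_populations(mat)])
        assert {t.name for t in tree.tips()} == {"p1", "p2", "p3"}

    def test_recovers_additive_tree_metric_exactly(self):
        """Distances generated from a known tree are recovered: NJ on an
        additive metric returns a tree whose path lengths equal the input."""
        newick = "((a:1,b:2):1.5,(c:0.5,d:1):2,e:3);"
        source = skbio.TreeNode.read([newick])
        ids = ["a", "b", "c", "d", "e"]
        dist = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    dist[i, j] = dist[j, i] = source.find(x).distance(source.find(y))
        mat = DifferentiationMatrix("jost_d", tuple(ids), dist)
        tree = skbio.TreeNode.read([nj_populations(mat)])
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    assert tree.find(x).distance(tree.find(y)) == pytest.approx(
                        dist[i, j], abs=1e-9)

    def test_wild_population_tree_isolates_distinct_range(self, population_table):
        """The fully differentiated population is the most distant leaf and
        the identical pure-ancestral populations sit at ~zero distance."""
        mat = pairwise_differentiation(population_table, "jost_d")
        tree = skbio.TreeNode.read([nj_populations(mat)])
        mean_dist = {
            p: np.mean([tree.find(p).distance(tree.find(q))
                        for q in mat.populations if q != p])
            for p in mat.populations
        }
        assert max(mean_dist, key=mean_dist.get) == "GAR"
        assert tree.find("KNYS").distance(tree.find("PLETT")) == pytest.approx(0.0, abs=1e-3)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DifferentiationMatrix("gst", ("a", "b"), np.array([[0, 1.0], [0.5, 0]]))
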