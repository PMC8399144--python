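"""PCoA, neighbor-joining, AMOVA and Evanno ΔK."""


import dendropy
import numpy as np
import pandas as pd
import pytest

from germdiss import (
    DissimilarityMatrix,
    SimConfig,
    amova,
    evanno_delta_k,
    nj_tree,
    pairwise_dissimilarity,
    pairwise_group_distances,
    pcoa,
    simulate_collection,
)


def dm_from(d, ids=None):
    d = np.asarray(d, dtype=float)
    ids = ids or [f"T{i}" for i in range(d.shape[0])]
    return DissimilarityMatrix(ids=list(ids), d=d)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(dm_from(d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        coords = res.coordinates.to_numpy()
        sides = [np.linalg.norm(coords[i] - coords[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        np.testing.assert_allclose(sides, 1.0, atol=1e-10)

    def test_planar_embedding_round_trip(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(size=(15, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm_from(d), n_axes=2)
        coords = res.coordinates.to_numpy()
        back = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(back, d, atol=1e-8)
        # squared-Euclidean input: no meaningfully negative eigenvalues
        assert res.eigenvalues.min() > -1e-8 * abs(res.eigenvalues).max()

    def test_matches_skbio(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(12, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm_from(d), n_axes=4)
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.ordination import pcoa as sk_pcoa

        sk = sk_pcoa(SkDM(d))
        sk_pos = np.sort(sk.eigvals[sk.eigvals > 1e-8].to_numpy())[::-1]
        mine = res.eigenvalues[res.eigenvalues > 1e-8]
        np.testing.assert_allclose(mine[: len(sk_pos)], sk_pos, rtol=1e-6)

    def test_rejects_nan_and_asymmetry(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            pcoa(dm_from(np.nan_to_num(d) * np.nan))
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 0.1, 0.2], [0.3, 0.0, 0.1], [0.2, 0.1, 0.0]]))

    def test_groups_separate_on_first_axes(self):
        from sklearn.metrics import silhouette_score

        cfg = SimConfig(
            n_samples=60, n_markers=2000, n_groups=3, fst_like_divergence=0.3,
            missing_rate_range=(0.0, 0.2), seed=1,
        )
        gm, truth = simulate_collection(cfg)
        dm = pairwise_dissimilarity(gm)
        res = pcoa(dm, n_axes=2)
        labels = [truth.group_of_sample[s] for s in dm.ids]
        assert silhouette_score(res.coordinates.to_numpy(), labels) > 0


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def _random_additive(rng, n_taxa):
    """Random binary tree over taxa T0..T{n-1}; returns (newick-free) distance matrix."""
    nodes = [({i}, {i: 0.0}) for i in range(n_taxa)]  # (leafset, dist-to-node-root)
    d = np.zeros((n_taxa, n_taxa))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (la, da), (lb, db) = nodes[i], nodes[j]
        ea, eb = rng.uniform(0.1, 2.0, size=2)
        for x in la:
            for y in lb:
                d[x, y] = d[y, x] = da[x] + ea + eb + db[y]
        merged = {x: dx + ea for x, dx in da.items()}
        merged.update({y: dy + eb for y, dy in db.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((la | lb, merged))
    return d


def _path_lengths(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ns = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(ns[taxa[i]], ns[taxa[j]])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        nwk = nj_tree(dm_from(d, ids=["a", "b", "c"]))
        got = _path_lengths(nwk, ["a", "b", "c"])
        np.testing.assert_allclose(got, d, atol=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_additive_matrix_reproduced_exactly(self, n_taxa):
        rng = np.random.default_rng(30 + n_taxa)
        d = _random_additive(rng, n_taxa)
        taxa = [f"T{i}" for i in range(n_taxa)]
        nwk = nj_tree(dm_from(d, ids=taxa), precision=15)
        np.testing.assert_allclose(_path_lengths(nwk, taxa), d, atol=1e-9)
        # default 6-significant-digit output stays faithful to printed precision
        np.testing.assert_allclose(
            _path_lengths(nj_tree(dm_from(d, ids=taxa)), taxa), d, rtol=1e-4, atol=1e-4
        )

    def test_duplicate_pair_are_siblings_with_tiny_branches(self):
        cfg = SimConfig(
            n_samples=12, n_markers=600, n_groups=3, fst_like_divergence=0.2,
            n_duplicate_pairs=1, duplicate_mismatch_loci=2,
            missing_rate_range=(0.0, 0.0), seed=31,
        )
        gm, truth = simulate_collection(cfg)
        dm = pairwise_dissimilarity(gm)
        src, dup, _ = truth.duplicate_pairs[0]
        tree = dendropy.Tree.get(data=nj_tree(dm), schema="newick", preserve_underscores=True)
        pdm = tree.phylogenetic_distance_matrix()
        ns = {t.label: t for t in tree.taxon_namespace}
        assert pdm.path_edge_count(ns[src], ns[dup]) == 2  # siblings
        assert pdm.distance(ns[src], ns[dup]) < 0.01

    def test_input_order_invariance(self):
        rng = np.random.default_rng(32)
        pts = rng.normal(size=(9, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        taxa = [f"T{i}" for i in range(9)]
        t1 = dendropy.Tree.get(data=nj_tree(dm_from(d, ids=taxa)), schema="newick")
        perm = rng.permutation(9)
        t2_nwk = nj_tree(dm_from(d[np.ix_(perm, perm)], ids=[taxa[i] for i in perm]))
        tns = t1.taxon_namespace
        t2 = dendropy.Tree.get(data=t2_nwk, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_matches_skbio_topology(self):
        rng = np.random.default_rng(33)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        taxa = [f"T{i}" for i in range(10)]
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        sk_newick = str(sk_nj(SkDM(d, ids=taxa)))
        t1 = dendropy.Tree.get(data=nj_tree(dm_from(d, ids=taxa)), schema="newick")
        t2 = dendropy.Tree.get(data=sk_newick, schema="newick", taxon_namespace=t1.taxon_namespace)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

class TestAmova:
    def test_two_identical_clusters_give_100_percent_among(self):
        n_per = 5
        d = np.zeros((2 * n_per, 2 * n_per))
        d[:n_per, n_per:] = 0.4
        d[n_per:, :n_per] = 0.4
        labels = ["g1"] * n_per + ["g2"] * n_per
        res = amova(d, labels, n_permutations=99, seed=0)
        assert res.percent_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_ssd_decomposition_matches_coordinate_anova(self):
        """On Euclidean distances, the SSD parts equal classic sums of squares."""
        rng = np.random.default_rng(40)
        pts = rng.normal(size=(24, 3)) + np.repeat(rng.normal(size=(3, 3)) * 2, 8, axis=0)
        labels = np.repeat([0, 1, 2], 8)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = amova(d, list(labels), n_permutations=0)
        ss_total = ((pts - pts.mean(axis=0)) ** 2).sum()
        ss_within = sum(
            ((pts[labels == g] - pts[labels == g].mean(axis=0)) ** 2).sum() for g in range(3)
        )
        assert res.ss_within == pytest.approx(ss_within, abs=1e-9)
        assert res.ss_among + res.ss_within == pytest.approx(ss_total, abs=1e-9)

    def test_percent_equals_phi_when_nonnegative(self):
        rng = np.random.default_rng(41)
        cfg = SimConfig(
            n_samples=36, n_markers=400, n_groups=3, fst_like_divergence=0.2,
            missing_rate_range=(0.0, 0.0), seed=42,
        )
        gm, truth = simulate_collection(cfg)
        dm = pairwise_dissimilarity(gm)
        res = amova(dm, [truth.group_of_sample[s] for s in dm.ids], n_permutations=0)
        assert res.percent_among == pytest.approx(100 * res.phi_st, abs=1e-9)

    def test_null_permutation_p_is_roughly_uniform(self):
        rng = np.random.default_rng(43)
        n = 24
        pts = rng.normal(size=(n, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ps = []
        for rep in range(40):
            labels = rng.permutation(np.repeat([0, 1, 2], n // 3))
            ps.append(amova(d, list(labels), n_permutations=199, seed=rep).p_value)
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() < 0.25

    def test_among_percent_monotone_in_divergence(self):
        pct = []
        for f in (0.02, 0.15, 0.4):
            cfg = SimConfig(
                n_samples=60, n_markers=2000, n_groups=3, fst_like_divergence=f,
                missing_rate_range=(0.0, 0.0), seed=44,
            )
            gm, truth = simulate_collection(cfg)
            dm = pairwise_dissimilarity(gm)
            pct.append(
                amova(dm, [truth.group_of_sample[s] for s in dm.ids], n_permutations=0).percent_among
            )
        assert pct[0] < pct[1] < pct[2]

    def test_permutation_p_reproducible_and_groups_validated(self):
        rng = np.random.default_rng(45)
        d = np.abs(rng.normal(size=(10, 10)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2, 2]
        p1 = amova(d, labels, n_permutations=199, seed=7).p_value
        p2 = amova(d, labels, n_permutations=199, seed=7).p_value
        assert p1 == p2
        with pytest.raises(ValueError, match="2 groups"):
            amova(d, [0] * 10)


class TestPairwiseGroupDistances:
    def test_identical_groups_phi_zero_and_fixed_groups_phi_one(self):
        row_a, row_b = ["AA", "CC", "AA"], ["CC", "AA", "CC"]
        from conftest import make_matrix

        gm = make_matrix([row_a, row_a, row_a, row_b, row_b, row_b], samples=list("abcdef"))
        dm = pairwise_dissimilarity(gm)
        labels = {"a": "g1", "b": "g1", "c": "g2", "d": "g3", "e": "g3", "f": "g3"}
        out = pairwise_group_distances(dm, labels, n_permutations=49, seed=0)
        get = lambda g1, g2: out[(out.group1 == g1) & (out.group2 == g2)].iloc[0]
        assert get("g1", "g2")["phi_st"] == pytest.approx(0.0)  # same genotypes
        assert get("g1", "g3")["phi_st"] == pytest.approx(1.0)  # fully fixed difference

    def test_self_consistency_with_full_amova(self):
        cfg = SimConfig(
            n_samples=32, n_markers=500, n_groups=4, fst_like_divergence=0.25,
            missing_rate_range=(0.0, 0.0), seed=46,
        )
        gm, truth = simulate_collection(cfg)
        dm = pairwise_dissimilarity(gm)
        labels = {s: truth.group_of_sample[s] for s in dm.ids}
        out = pairwise_group_distances(dm, labels, n_permutations=0)
        for _, row in out.iterrows():
            keep = [s for s in dm.ids if labels[s] in (row.group1, row.group2)]
            idx = [dm.ids.index(s) for s in keep]
            sub = dm.d[np.ix_(idx, idx)]
            res = amova(sub, [labels[s] for s in keep], n_permutations=0)
            assert row.phi_st == pytest.approx(res.phi_st, abs=1e-12)

    def test_singleton_vs_singleton_flagged(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        out = pairwise_group_distances(d, ["g1", "g2"], n_permutations=9)
        assert np.isnan(out["p_value"].iloc[0])
        assert out["phi_st"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def _runs_table(means, sd_offset=1 / np.sqrt(2)):
    rows = []
    for k, m in enumerate(means, start=1):
        rows.append({"K": k, "run": 1, "lnl": m - sd_offset})
        rows.append({"K": k, "run": 2, "lnl": m + sd_offset})
    return pd.DataFrame(rows)


class TestDeltaK:
    def test_hand_arithmetic(self):
        res = evanno_delta_k(_runs_table([-100, -80, -75, -74]))  # SD = 1 per K
        np.testing.assert_allclose(res.table.loc[2, "delta_k"], 15.0, atol=1e-9)
        np.testing.assert_allclose(res.table.loc[3, "delta_k"], 4.0, atol=1e-9)
        assert res.best_k == 2

    def test_linear_likelihood_gives_zero(self):
        res = evanno_delta_k(_runs_table([-100, -90, -80, -70, -60]))
        interior = res.table["delta_k"].iloc[1:-1]
        np.testing.assert_allclose(interior, 0.0, atol=1e-9)

    def test_elbow_recovered(self):
        rng = np.random.default_rng(50)
        means = [-500, -400, -300, -295, -292, -291]  # elbow at K=3
        rows = [
            {"K": k, "run": r, "lnl": m + rng.normal(0, 0.5)}
            for k, m in enumerate(means, start=1)
            for r in range(8)
        ]
        res = evanno_delta_k(pd.DataFrame(rows))
        assert res.best_k == 3

    def test_zero_sd_flagged_not_fatal(self):
        table = _runs_table([-10, -8, -7], sd_offset=0.0)
        res = evanno_delta_k(table)
        assert np.isnan(res.table.loc[2, "delta_k"])
        assert res.best_k is None

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            evanno_delta_k(_runs_table([-10, -9]))
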