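"""Indel matrix filters, distances, NJ trees, and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from degenexp.phylogeny import (
    IndelMatrix,
    apply_coverage,
    build_matrix,
    distance_matrix,
    filter_matrix,
    grouping_test,
    infer_tree,
    is_clan,
    split_partitions,
)
from degenexp.synthetic import generate_indel_matrix


def tiny_matrix(values, samples=None):
    values = np.asarray(values, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    loci = pd.DataFrame(
        {
            "locus": [f"locus{j:05d}" for j in range(values.shape[1])],
            "chromosome": ["chr1"] * values.shape[1],
            "start": np.arange(values.shape[1]) * 10_000,
            "end": np.arange(values.shape[1]) * 10_000 + 5000,
        }
    )
    vdf = pd.DataFrame(values, index=samples, columns=loci["locus"])
    return IndelMatrix(vdf, loci)


class TestFilters:
    def test_singleton_locus_dropped(self):
        m = tiny_matrix([[1, 1], [0, 1], [0, 0]])
        kept = filter_matrix(m)
        assert list(kept.values.columns) == ["locus00001"]

    def test_locus_with_missing_coverage_dropped(self):
        m = tiny_matrix([[1, 1], [1, -1], [0, 1]])
        kept = filter_matrix(m)
        assert list(kept.values.columns) == ["locus00000"]

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.choice([-1, 0, 1], size=(6, 40), p=[0.1, 0.4, 0.5])
        once = filter_matrix(tiny_matrix(vals))
        twice = filter_matrix(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_nothing_surviving_yields_empty_matrix(self):
        m = tiny_matrix([[1, 0], [0, 0], [0, 0]])
        kept = filter_matrix(m)
        assert kept.n_loci == 0


class TestBuildMatrix:
    def test_reciprocal_overlap_merges_and_presence_scored(self, ant_table):
        calls = {
            "s1": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [100_000], "end": [110_000],
                 "type": ["INS"]}
            ),
            "s2": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [101_000], "end": [111_000],
                 "type": ["INS"]}
            ),
            "s3": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [400_000], "end": [408_000],
                 "type": ["DEL"]}
            ),
        }
        m = build_matrix(calls, None, ant_table)
        assert m.n_loci == 2
        merged = m.values.sum(axis=0)
        assert sorted(merged) == [1, 2]

    def test_insufficient_reciprocal_overlap_stays_split(self, ant_table):
        calls = {
            "s1": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [100_000], "end": [110_000],
                 "type": ["INS"]}
            ),
            "s2": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [109_000], "end": [150_000],
                 "type": ["INS"]}
            ),
        }
        m = build_matrix(calls, None, ant_table)
        assert m.n_loci == 2

    def test_uncovered_absence_marked_missing(self, ant_table):
        calls = {
            "s1": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [100_000], "end": [110_000],
                 "type": ["INS"]}
            ),
            "s2": pd.DataFrame(
                {"chromosome": ["chr1"], "start": [100_500], "end": [110_500],
                 "type": ["INS"]}
            ),
            "s3": pd.DataFrame(columns=["chromosome", "start", "end", "type"]),
        }
        coverage = {
            "s1": pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [10**7]}),
            "s2": pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [10**7]}),
            "s3": pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [50_000]}),
        }
        m = build_matrix(calls, coverage, ant_table)
        assert m.values.loc["s3"].iloc[0] == -1
        assert filter_matrix(m).n_loci == 0


class TestDistances:
    def test_identical_rows_distance_zero(self):
        m = tiny_matrix([[1, 0, 1], [1, 0, 1], [0, 1, 1]])
        d = distance_matrix(m)
        assert d["s0", "s1"] == 0.0

    def test_complementary_rows_distance_is_locus_count(self):
        m = tiny_matrix([[1, 0, 1, 0], [0, 1, 0, 1]])
        d = distance_matrix(m)
        assert d["s0", "s1"] == 4.0

    def test_triangle_inequality_holds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            m = tiny_matrix(rng.integers(0, 2, size=(3, 30)))
            d = distance_matrix(m).data
            assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-12

    def test_jaccard_metric_bounds(self):
        m = tiny_matrix([[1, 1, 0], [1, 0, 1], [0, 0, 0]])
        d = distance_matrix(m, metric="jaccard")
        assert 0 <= d["s0", "s1"] <= 1

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(tiny_matrix([[1, -1], [0, 1]]))


def additive_distances(rng, leaves):
    """Random binary tree plus its exact leaf-to-leaf path distances."""
    clusters = [({lf}, {lf: 0.0}) for lf in leaves]
    dist = {}
    clades = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        sb, db = clusters.pop(j)
        sa, da = clusters.pop(i)
        la, lb = rng.uniform(1, 10, 2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        depths = {x: d + la for x, d in da.items()}
        depths.update({y: d + lb for y, d in db.items()})
        merged = sa | sb
        if len(merged) < len(leaves):
            clades.append(set(merged))
        clusters.append((merged, depths))
    return dist, clades


class TestTrees:
    @pytest.mark.parametrize("seed", range(8))
    def test_nj_reconstructs_additive_trees_exactly(self, seed):
        """NJ is consistent: on additive distances from a random 6-leaf tree
        every clade of the generating tree is a clan of the NJ tree."""
        rng = np.random.default_rng(seed)
        leaves = [f"t{i}" for i in range(6)]
        dist, clades = additive_distances(rng, leaves)
        mat = np.zeros((6, 6))
        for a in range(6):
            for b in range(a + 1, 6):
                mat[a, b] = mat[b, a] = dist[frozenset((leaves[a], leaves[b]))]
        res = infer_tree(DistanceMatrix(mat, ids=leaves))
        for clade in clades:
            assert is_clan(res.tree, set(clade))

    def test_three_leaves_closed_form_branch_lengths(self):
        d12, d13, d23 = 4.0, 6.0, 8.0
        mat = np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]])
        res = infer_tree(DistanceMatrix(mat, ids=["a", "b", "c"]))
        bl = {t.name: t.length for t in res.tree.tips()}
        assert bl["a"] == pytest.approx((d12 + d13 - d23) / 2)
        assert bl["b"] == pytest.approx((d12 + d23 - d13) / 2)
        assert bl["c"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_degenerate_zero_distances_star_tree(self):
        mat = np.zeros((4, 4))
        res = infer_tree(DistanceMatrix(mat, ids=list("abcd")),
                         groups={"g": {"a", "b"}})
        assert res.grouping["g"] is None
        assert res.newick.count(",") == 3

    def test_newick_round_trips(self):
        mat = np.array([[0, 2, 5], [2, 0, 5], [5, 5, 0]], dtype=float)
        res = infer_tree(DistanceMatrix(mat, ids=["a", "b", "c"]))
        from skbio import TreeNode
        import io

        back = TreeNode.read(io.StringIO(res.newick))
        assert {t.name for t in back.tips()} == {"a", "b", "c"}


class TestPlantedRecovery:
    def test_species_and_variant_grouping_recovered(self, ant_table):
        ok_bg = ok_sg = 0
        n = 30
        species = {f"sp{i}": {f"sp{i}_B", f"sp{i}_b"} for i in (1, 2, 3)}
        for seed in range(n):
            values, covered, loci = generate_indel_matrix(seed=seed)
            m = filter_matrix(IndelMatrix(apply_coverage(values, covered), loci))
            bg, sg = split_partitions(m, ant_table)
            variants = {
                "B": {s for s in m.samples if s.endswith("_B")},
                "b": {s for s in m.samples if s.endswith("_b")},
            }
            tb = infer_tree(distance_matrix(bg), "background", species)
            ts = infer_tree(distance_matrix(sg), "supergene", variants)
            ok_bg += all(tb.grouping.values())
            ok_sg += all(ts.grouping.values())
        assert ok_bg >= 0.95 * n
        assert ok_sg >= 0.95 * n

    def test_grouping_test_detects_non_clan(self):
        from skbio import TreeNode
        import io

        tree = TreeNode.read(io.StringIO("((a:1,b:1):1,(c:1,d:1):1);"))
        res = grouping_test(tree, {"good": {"a", "b"}, "bad": {"a", "c"}})
        assert res["good"] is True and res["bad"] is False
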