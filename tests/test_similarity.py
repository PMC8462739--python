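import io

import numpy as np
import pandas as pd
import pytest

from tsgcompare.expression import ExpressionMatrix, ValidationError
from tsgcompare.homology import best_hits
from tsgcompare.similarity import (
    NormalizedProfile,
    SimilarityConfig,
    cluster_profiles,
    export_network,
    minmax_normalize,
    read_sif,
    similarity_matrix,
    tissue_similarity,
    write_sif,
)
from tsgcompare.tsg import TsgCall


def profile(vals, tissues=None, gene="g", degenerate=False):
    tissues = tissues or tuple(f"t{i}" for i in range(len(vals)))
    return NormalizedProfile(gene, tuple(tissues), tuple(vals), degenerate)


class TestMinmaxNormalize:
    def test_basic_rescaling(self):
        p = minmax_normalize({"a": 2.0, "b": 4.0, "c": 10.0})
        assert p.values == (0.0, 0.25, 1.0)
        assert not p.degenerate

    def test_constant_profile_degenerate(self):
        p = minmax_normalize({"a": 5.0, "b": 5.0, "c": 5.0})
        assert p.degenerate
        assert p.values == (0.0, 0.0, 0.0)

    def test_unit_interval_fixed_point(self):
        assert minmax_normalize({"a": 0.0, "b": 1.0}).values == (0.0, 1.0)

    def test_too_few_tissues(self):
        with pytest.raises(ValidationError, match="2 tissues"):
            minmax_normalize({"a": 1.0})

    def test_series_input_keeps_name(self):
        p = minmax_normalize(pd.Series([1.0, 3.0], index=["a", "b"], name="geneX"))
        assert p.gene_id == "geneX"
        assert p.values == (0.0, 1.0)

    def test_endpoints_exact(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 100, 8)
            p = minmax_normalize(dict(zip("abcdefgh", vals)))
            assert min(p.values) == 0.0 and max(p.values) == 1.0


def brute_force_similarity(profiles, threshold):
    """Independent recount: plain double loop over profiles and tissues."""
    usable = [p for p in profiles if not p.degenerate]
    out = {}
    for t in usable[0].tissues:
        n_high = 0
        for p in usable:
            if p.values[p.tissues.index(t)] > threshold:
                n_high += 1
        out[t] = n_high / len(usable)
    return out


class TestTissueSimilarity:
    def test_hand_counted_two_profiles(self):
        # p1 high in a and b, p2 high in a only -> a 1.0, b 0.5, c 0.0
        p1 = profile((1.0, 0.85, 0.0), "abc")
        p2 = profile((1.0, 0.0, 0.3), "abc")
        frac = tissue_similarity([p1, p2])
        assert frac == {"a": 1.0, "b": 0.5, "c": 0.0}
        assert sum(frac.values()) == 1.5  # row sums may exceed 1

    def test_all_high_in_one_tissue(self):
        ps = [profile((1.0, 0.5, 0.2), ("brain", "x", "y"), f"g{i}") for i in range(4)]
        frac = tissue_similarity(ps)
        assert frac == {"brain": 1.0, "x": 0.0, "y": 0.0}

    def test_exactly_at_threshold_not_counted(self):
        frac = tissue_similarity([profile((1.0, 0.8), "ab")])
        assert frac["b"] == 0.0

    def test_degenerate_excluded_from_both_sides(self):
        ps = [profile((1.0, 0.0), "ab"), profile((0.0, 0.0), "ab", degenerate=True)]
        assert tissue_similarity(ps) == {"a": 1.0, "b": 0.0}

    def test_all_degenerate_is_error(self):
        with pytest.raises(ValidationError, match="non-degenerate"):
            tissue_similarity([profile((0.0, 0.0), "ab", degenerate=True)])

    def test_max_always_counted(self, rng):
        # a non-degenerate profile's maximum is 1.0, above any threshold < 1
        for _ in range(20):
            raw = rng.uniform(0, 50, 6)
            raw[rng.integers(6)] += 1.0  # ensure a unique max
            p = minmax_normalize(dict(zip("abcdef", raw)))
            frac = tissue_similarity([p], SimilarityConfig(0.97))
            assert any(v == 1.0 for v in frac.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_recount_oracle(self, seed):
        local = np.random.default_rng(seed)
        n_profiles = int(local.integers(2, 500))
        n_tissues = int(local.integers(2, 30))
        tissues = tuple(f"t{i}" for i in range(n_tissues))
        ps = []
        for i in range(n_profiles):
            raw = local.uniform(0, 10, n_tissues)
            ps.append(minmax_normalize(dict(zip(tissues, raw)), gene_id=f"g{i}"))
        got = tissue_similarity(ps)
        assert got == brute_force_similarity(ps, 0.8)


def call(gene, group="nc"):
    return TsgCall(gene, group, 5.0, 0.1)


def target_matrix(rows, tissues):
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=tissues), units="rpkm"
    )


class TestSimilarityMatrix:
    def test_single_homolog_highest_in_liver(self):
        hmap = best_hits([])
        hmap.set("g1", "mouse", _bh("S1"))
        target = target_matrix({"S1": [100.0, 1.0, 2.0]}, ["liver", "brain", "heart"])
        sim = similarity_matrix([call("g1")], hmap, target, "mouse")
        assert sim.fractions.at["nc", "liver"] == 1.0
        assert sim.denominators == {"nc": 1}

    def test_duplicate_subjects_count_per_tsg(self):
        hmap = best_hits([])
        hmap.set("g1", "mouse", _bh("S1"))
        hmap.set("g2", "mouse", _bh("S1"))
        hmap.set("g3", "mouse", _bh("S2"))
        target = target_matrix(
            {"S1": [100.0, 1.0], "S2": [1.0, 100.0]}, ["liver", "brain"]
        )
        sim = similarity_matrix([call(g) for g in ("g1", "g2", "g3")], hmap, target, "mouse")
        assert sim.denominators == {"nc": 3}
        assert sim.fractions.at["nc", "liver"] == pytest.approx(2 / 3)

    def test_unresolvable_and_degenerate_logged(self):
        hmap = best_hits([])
        hmap.set("g1", "mouse", _bh("MISSING"))
        hmap.set("g2", "mouse", _bh("FLAT"))
        hmap.set("g3", "mouse", _bh("OK"))
        target = target_matrix({"FLAT": [2.0, 2.0], "OK": [9.0, 0.0]}, ["a", "b"])
        sim = similarity_matrix([call(g) for g in ("g1", "g2", "g3")], hmap, target, "mouse")
        assert sim.dropped["nc"] == {"unresolvable": 1, "degenerate": 1}
        assert sim.denominators == {"nc": 1}

    def test_group_with_no_usable_homologs_is_nan(self):
        hmap = best_hits([])
        target = target_matrix({"S": [1.0, 2.0]}, ["a", "b"])
        sim = similarity_matrix([call("g1")], hmap, target, "mouse")
        assert sim.fractions.loc["nc"].isna().all()
        assert sim.denominators == {"nc": 0}

    def test_replicate_averaging(self):
        hmap = best_hits([])
        hmap.set("g1", "mouse", _bh("S1"))
        target = target_matrix({"S1": [10.0, 30.0, 1.0]}, ["brain_r1", "brain_r2", "x"])
        sim = similarity_matrix(
            [call("g1")], hmap, target, "mouse",
            replicate_map={"brain": ["brain_r1", "brain_r2"], "x": ["x"]},
        )
        assert sim.fractions.at["nc", "brain"] == 1.0
        assert list(sim.fractions.columns) == ["brain", "x"]


class TestClusterProfiles:
    def test_identical_profiles_merge_first_at_zero(self):
        ps = [
            profile((0.0, 1.0), "ab", "dup1"),
            profile((0.9, 0.1), "ab", "far"),
            profile((0.0, 1.0), "ab", "dup2"),
        ]
        res = cluster_profiles(ps)
        assert res.merges[0, 2] == 0.0
        assert {int(res.merges[0, 0]), int(res.merges[0, 1])} == {0, 2}

    def test_complete_linkage_three_points(self):
        # distances: d(p1,p2)=1, d(p2,p3)=9, d(p1,p3)=10
        ps = [
            profile((0.0, 0.0), "ab", "p1"),
            profile((1.0, 0.0), "ab", "p2"),
            profile((10.0, 0.0), "ab", "p3"),
        ]
        res = cluster_profiles(ps)
        assert res.merges[0, 2] == pytest.approx(1.0)
        assert res.merges[1, 2] == pytest.approx(10.0)  # complete: the far pair

    def test_permutation_gives_same_heights(self, rng):
        ps = [
            profile(tuple(rng.uniform(0, 1, 4)), "abcd", f"g{i}") for i in range(10)
        ]
        res = cluster_profiles(ps)
        perm = list(rng.permutation(10))
        res2 = cluster_profiles([ps[i] for i in perm])
        np.testing.assert_allclose(
            sorted(res.merges[:, 2]), sorted(res2.merges[:, 2])
        )
        assert set(res.leaf_order) == set(res2.leaf_order)

    def test_too_few_profiles(self):
        with pytest.raises(ValidationError, match="2 profiles"):
            cluster_profiles([profile((0.0, 1.0), "ab")])


class TestExportNetwork:
    def make_sim(self, frame, denom=None):
        from tsgcompare.similarity import SimilarityMatrix

        return SimilarityMatrix(frame, denom or {})

    def test_single_cell_identity(self):
        sim = self.make_sim(pd.DataFrame({"liver": [0.625]}, index=["nc"]))
        edges, nodes = export_network({"mouse": sim})
        assert len(edges) == 1
        assert edges.iloc[0].tolist() == ["nc", 0.625, "mouse:liver"]
        assert set(nodes["node"]) == {"nc", "mouse:liver"}

    def test_min_edge_filter(self):
        sim = self.make_sim(pd.DataFrame({"a": [0.1], "b": [0.3]}, index=["nc"]))
        edges, _ = export_network({"m": sim}, min_edge=0.2)
        assert edges["weight"].tolist() == [0.3]

    def test_empty_matrix_valid_header(self):
        sim = self.make_sim(pd.DataFrame(columns=["a"], index=pd.Index([], dtype=object)))
        edges, _ = export_network({"m": sim})
        assert list(edges.columns) == ["source", "weight", "target"]
        assert len(edges) == 0

    def test_round_trip_reconstructs_cells(self):
        frame = pd.DataFrame(
            {"brain": [0.625, 0.1], "liver": [0.0, 0.286]}, index=["nc", "stomach"]
        )
        sim = self.make_sim(frame)
        edges, _ = export_network({"mouse": sim}, min_edge=0.0)
        buf = io.StringIO()
        write_sif(edges, buf)
        buf.seek(0)
        back = read_sif(buf)
        for _, row in back.iterrows():
            sp, tissue = row["target"].split(":")
            assert frame.at[row["source"], tissue] == row["weight"]
        assert len(back) == (frame.to_numpy() > 0).sum()


def _bh(subject="S"):
    from tsgcompare.homology import BestHit

    return BestHit(subject, 1e-20, 100.0)
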