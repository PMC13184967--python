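"""Dissimilarity, clustering, ordination statistics and diversity."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ecoassembly.community_structure import (
    OrdinationResult,
    anosim,
    bray_curtis,
    community_overlap,
    diversity_indices,
    nmds,
    partition_subcommunities,
    pcoa,
    permdisp,
    procrustes_protest,
    trajectory_distance,
    upgma,
)
from ecoassembly.core_io import CommunityMatrix


def _cm(counts: dict, treatments=None, timepoints=None) -> CommunityMatrix:
    df = pd.DataFrame(counts)
    n = df.shape[1]
    meta = pd.DataFrame(
        {
            "treatment": treatments or ["g"] * n,
            "replicate": [f"R{i + 1}" for i in range(n)],
            "timepoint": timepoints or [0] * n,
        },
        index=df.columns,
    )
    return CommunityMatrix(df, meta)


class TestBrayCurtis:
    def test_identity_zero(self):
        cm = _cm({"a": [3, 1], "b": [3, 1]})
        dm = bray_curtis(cm)
        assert dm["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        cm = _cm({"a": [3, 0], "b": [0, 5]})
        assert bray_curtis(cm)["a", "b"] == pytest.approx(1.0)

    def test_hand_value_on_raw_counts(self):
        cm = _cm({"a": [6, 2], "b": [2, 2]})
        # 1 - 2*(min(6,2)+min(2,2)) / (8+4) = 1 - 8/12
        assert bray_curtis(cm)["a", "b"] == pytest.approx(1 - 8 / 12)


class TestUpgma:
    def test_hand_computed_merge_heights(self):
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        dm = DistanceMatrix(d, ids=["A", "B", "C"])
        res = upgma(dm)
        assert res.heights[0] == pytest.approx(1.0)
        assert res.heights[1] == pytest.approx(4.0)

    def test_ultrametric_fixed_point(self):
        # heights from a known ultrametric tree ((A,B):3,(C,D):1)-ish
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        dm = DistanceMatrix(d, ids=list("ABCD"))
        res = upgma(dm)
        assert sorted(np.round(res.heights, 9)) == [1.0, 2.0, 4.0]

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.random((6, 2))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(6)]
        res1 = upgma(DistanceMatrix(d, ids=ids))
        perm = rng.permutation(6)
        res2 = upgma(DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm]))
        assert np.allclose(sorted(res1.heights), sorted(res2.heights))


class TestOrdination:
    def _line_dm(self, n=10):
        x = np.linspace(0, 1, n)[:, None]
        return DistanceMatrix(squareform(pdist(x)), ids=[f"s{i}" for i in range(n)])

    def test_nmds_embeds_line_with_low_stress(self):
        res = nmds(self._line_dm(), k=2, seed=0, n_restarts=8)
        assert res.stress < 0.01

    def test_nmds_seeded_determinism(self):
        a = nmds(self._line_dm(), seed=3, n_restarts=4)
        b = nmds(self._line_dm(), seed=3, n_restarts=4)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_nmds_rank_preservation(self):
        rng = np.random.default_rng(1)
        pts = rng.random((12, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        res = nmds(dm, seed=0, n_restarts=8)
        emb = pdist(res.coordinates.to_numpy())
        from scipy.stats import spearmanr
        rho = spearmanr(squareform(d, checks=False), emb).statistic
        assert rho > 0.95

    def test_pcoa_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.random((8, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(8)]))
        emb = squareform(pdist(res.coordinates.to_numpy()[:, :3]))
        assert np.allclose(emb, d, atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            nmds(self._line_dm(3), k=3)


class TestPermdisp:
    def test_mirror_groups_give_zero_f(self):
        # two groups that are mirror images: identical dispersion multisets
        pts = np.array([[0, 0], [1, 0], [0, 1], [3, 3], [4, 3], [3, 4]], float)
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=dm.ids)
        res = permdisp(dm, groups, n_perm=99, seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)

    def test_detects_unequal_dispersion(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tight = rng.normal(0, 1, (10, 2))
            diffuse = rng.normal(0, 5, (10, 2))
            pts = np.vstack([tight, diffuse])
            dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(20)])
            groups = pd.Series(["t"] * 10 + ["d"] * 10, index=dm.ids)
            res = permdisp(dm, groups, n_perm=199, seed=seed)
            if res.p_value <= 0.05:
                hits += 1
        assert hits >= 9

    def test_p_on_permutation_grid(self):
        rng = np.random.default_rng(5)
        pts = rng.random((8, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.ids)
        res = permdisp(dm, groups, n_perm=99, seed=1)
        assert res.p_value in {k / 100 for k in range(1, 101)}

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(5)
        pts = rng.random((3, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=["a", "b", "c"])
        with pytest.raises(ValueError):
            permdisp(dm, pd.Series(["x", "x", "y"], index=dm.ids))


class TestAnosim:
    def test_fully_separated_groups_r_one(self):
        # all between distances exceed all within distances
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=dm.ids)
        r, p = anosim(dm, groups, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_random_labels_center_near_zero(self):
        rs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            pts = rng.random((12, 2))
            dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
            groups = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6), index=dm.ids)
            r, _ = anosim(dm, groups, n_perm=49, seed=seed)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1


class TestProcrustes:
    def _ord(self, pts, ids):
        return OrdinationResult(
            pd.DataFrame(pts, index=ids, columns=["axis1", "axis2"]), method="pcoa"
        )

    def test_superimposable_configurations_m2_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b = (a @ rot) * 3.2 + np.array([5.0, -2.0])
        ids = [f"s{i}" for i in range(10)]
        m2, p = procrustes_protest(self._ord(a, ids), self._ord(b, ids), n_perm=99, seed=1)
        assert m2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1 / 100)

    def test_self_comparison_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((8, 2))
        ids = [f"s{i}" for i in range(8)]
        m2, _ = procrustes_protest(self._ord(a, ids), self._ord(a, ids), n_perm=49, seed=0)
        assert m2 == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(2)
        a = self._ord(rng.random((5, 2)), [f"s{i}" for i in range(5)])
        b = self._ord(rng.random((5, 2)), [f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            procrustes_protest(a, b)


class TestDiversity:
    def test_uniform_community(self):
        cm = _cm({"s": [5, 5, 5, 5]})
        div = diversity_indices(cm)
        assert div.loc["s", "inverse_simpson"] == pytest.approx(4.0)

    def test_single_taxon(self):
        cm = _cm({"s": [9]})
        div = diversity_indices(cm)
        assert div.loc["s", "inverse_simpson"] == pytest.approx(1.0)
        assert div.loc["s", "margalef"] == pytest.approx(0.0)

    def test_margalef_closed_form(self):
        cm = _cm({"s": [96, 1, 1, 1, 1]})
        div = diversity_indices(cm)
        assert div.loc["s", "margalef"] == pytest.approx(4 / np.log(100))


class TestSubcommunities:
    def test_threshold_assignment(self):
        # taxon means: 2%, 0.05%, 0.5%, rest
        vals = np.array([0.02, 0.0005, 0.005, 0.9745])
        counts = pd.DataFrame({"s1": (vals * 1e6).astype(int), "s2": (vals * 1e6).astype(int)},
                              index=["main1", "rare1", "mid1", "big"])
        meta = pd.DataFrame(
            {"treatment": ["g", "g"], "replicate": ["R1", "R2"], "timepoint": [0, 0]},
            index=["s1", "s2"],
        )
        part = partition_subcommunities(CommunityMatrix(counts, meta))
        assert "main1" in part.main_taxa and "big" in part.main_taxa
        assert part.rare_taxa == ["rare1"]
        assert part.intermediate_taxa == ["mid1"]

    def test_lists_disjoint_and_exhaustive(self, tiny_cm):
        part = partition_subcommunities(tiny_cm)
        all_listed = part.main_taxa + part.rare_taxa + part.intermediate_taxa
        assert sorted(all_listed) == sorted(tiny_cm.taxa_ids)
        assert len(set(all_listed)) == len(all_listed)


class TestTrajectoryDistance:
    def _ordination(self):
        ids = [f"s{i}" for i in range(6)]
        pts = np.array([[0, 0], [0, 0], [1, 0], [1, 0], [2, 0], [2, 0]], float)
        coords = pd.DataFrame(pts, index=ids, columns=["axis1", "axis2"])
        meta = pd.DataFrame(
            {
                "treatment": ["g"] * 6,
                "replicate": ["R1", "R2"] * 3,
                "timepoint": [0, 0, 12, 12, 24, 24],
            },
            index=ids,
        )
        return OrdinationResult(coords, method="pcoa"), meta

    def test_reference_distance_zero_and_monotone_walk(self):
        ordn, meta = self._ordination()
        td = trajectory_distance(ordn, meta)
        by_tp = td.set_index("timepoint")["distance"]
        assert by_tp[0] == pytest.approx(0.0)
        assert by_tp[12] == pytest.approx(1.0)
        assert by_tp[24] == pytest.approx(2.0)

    def test_static_community_all_zero(self):
        ordn, meta = self._ordination()
        static = OrdinationResult(
            ordn.coordinates * 0.0, method="pcoa"
        )
        td = trajectory_distance(static, meta)
        assert np.allclose(td["distance"], 0.0)

    def test_missing_reference_rejected(self):
        ordn, meta = self._ordination()
        with pytest.raises(ValueError):
            trajectory_distance(ordn, meta, reference=99)


class TestCommunityOverlap:
    def test_boundaries_and_hand_value(self):
        cm = _cm(
            {"a": [6, 2], "b": [2, 2], "c": [6, 2], "d": [0, 7]},
            treatments=["g"] * 4,
            timepoints=[0] * 4,
        )
        ov = community_overlap(cm, [("a", "b"), ("a", "c"), ("a", "d")])
        assert ov[("a", "c")] == pytest.approx(1.0)
        assert ov[("a", "b")] == pytest.approx(8 / 12)  # complement of the BC hand value

    def test_unpaired_input_rejected(self):
        cm = _cm({"a": [1, 2], "b": [2, 1]}, treatments=["g", "h"])
        with pytest.raises(ValueError):
            community_overlap(cm, [("a", "b")])
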