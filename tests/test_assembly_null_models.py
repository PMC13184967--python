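"""Null-model statistics: hand oracles, brute-force equivalence,
calibration and the process decision rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecoassembly.assembly_null_models import (
    PatristicMatrix,
    beta_mntd,
    beta_mntd_matrix,
    beta_nti,
    classify_process,
    make_pairs,
    pair_table,
    partition_processes,
    patristic_matrix,
    raup_crick_bray,
    ses_mpd,
)
from ecoassembly.core_io import CommunityMatrix


def brute_force_beta_mntd(rel_a, rel_b, d):
    """Independent oracle: explicit double loop over taxon pairs."""
    a = np.asarray(rel_a, float); a = a / a.sum()
    b = np.asarray(rel_b, float); b = b / b.sum()
    pres_a = np.where(a > 0)[0]
    pres_b = np.where(b > 0)[0]
    total = 0.0
    for i in pres_a:
        total += a[i] * min(d[i, j] for j in pres_b)
    for j in pres_b:
        total += b[j] * min(d[i, j] for i in pres_a)
    return 0.5 * total


class TestPatristicMatrix:
    def test_hand_path_sums(self, three_tip_tree):
        pm = patristic_matrix(three_tip_tree, ["A", "B", "C"])
        df = pm.to_frame()
        assert df.loc["A", "B"] == pytest.approx(2.0)
        assert df.loc["A", "C"] == pytest.approx(4.0)
        assert df.loc["B", "C"] == pytest.approx(4.0)
        assert np.all(np.diag(pm.distances) == 0)

    def test_star_tree_uniform_distances(self):
        pm = patristic_matrix("(A:3,B:3,C:3,D:3);")
        off = pm.distances[np.triu_indices(4, k=1)]
        assert np.allclose(off, 6.0)

    def test_missing_taxon_listed(self, three_tip_tree):
        with pytest.raises(ValueError, match="ZZ"):
            patristic_matrix(three_tip_tree, ["A", "ZZ"])

    def test_triangle_inequality_on_tree_metric(self):
        from ecoassembly.synthetic_community import simulate_tree_and_traits
        newick, traits = simulate_tree_and_traits(20, 1.0, seed=8)
        d = patristic_matrix(newick, list(traits.index)).distances
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(20, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestBetaMNTD:
    def test_hand_example_single_taxa(self, three_tip_tree):
        pm = patristic_matrix(three_tip_tree, ["A", "B", "C"])
        val = beta_mntd([1, 0, 0], [0, 1, 0], pm)
        assert val == pytest.approx(2.0)

    def test_identical_communities_zero(self, three_tip_tree):
        pm = patristic_matrix(three_tip_tree, ["A", "B", "C"])
        assert beta_mntd([0.5, 0.3, 0.2], [0.5, 0.3, 0.2], pm) == 0.0

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        n = 6
        d = rng.uniform(0.1, 5.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        pm = PatristicMatrix([f"t{i}" for i in range(n)], d)
        for _ in range(200):
            a = rng.random(n) * (rng.random(n) > 0.4)
            b = rng.random(n) * (rng.random(n) > 0.4)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert beta_mntd(a, b, pm) == pytest.approx(
                brute_force_beta_mntd(a, b, d), abs=1e-12
            )

    def test_matrix_form_agrees_with_pairwise(self):
        rng = np.random.default_rng(1)
        n, s = 8, 5
        d = rng.uniform(0.1, 3.0, (n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        rel = rng.random((n, s)) * (rng.random((n, s)) > 0.3)
        rel[0, rel.sum(axis=0) == 0] = 0.5
        rel = rel / rel.sum(axis=0)
        pm = PatristicMatrix([f"t{i}" for i in range(n)], d)
        mat = beta_mntd_matrix(rel, d)
        for a, b in itertools.combinations(range(s), 2):
            assert mat[a, b] == pytest.approx(beta_mntd(rel[:, a], rel[:, b], pm), abs=1e-12)


class TestBetaNTI:
    def test_symmetry(self, three_tip_tree):
        counts = pd.DataFrame(
            {"s1": [5, 3, 2], "s2": [1, 7, 2], "s3": [2, 2, 6]}, index=["A", "B", "C"]
        )
        meta = pd.DataFrame(
            {"treatment": ["g"] * 3, "replicate": ["R1", "R2", "R3"], "timepoint": [0] * 3},
            index=["s1", "s2", "s3"],
        )
        cm = CommunityMatrix(counts, meta)
        pm = patristic_matrix(three_tip_tree, ["A", "B", "C"])
        z = beta_nti(cm, pm, n_null=99, seed=1)
        assert np.allclose(z.to_numpy(), z.to_numpy().T, equal_nan=True)

    def test_branch_length_scale_invariance(self):
        from ecoassembly.synthetic_community import simulate_tree_and_traits
        newick, traits = simulate_tree_and_traits(20, 1.0, seed=5)
        taxa = list(traits.index)
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(20, 4)), index=taxa,
            columns=["s1", "s2", "s3", "s4"],
        )
        counts.iloc[0] += 1
        meta = pd.DataFrame(
            {"treatment": ["g"] * 4, "replicate": list("1234"), "timepoint": [0] * 4},
            index=counts.columns,
        )
        cm = CommunityMatrix(counts, meta)
        pm = patristic_matrix(newick, taxa)
        pm_scaled = PatristicMatrix(taxa, pm.distances * 7.5)
        z1 = beta_nti(cm, pm, n_null=199, seed=9)
        z2 = beta_nti(cm, pm_scaled, n_null=199, seed=9)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9, equal_nan=True)

    def test_null_assembled_communities_calibrated(self):
        """Communities built by per-sample label shuffles should give
        z-scores with near-zero mean and near-unit spread."""
        from ecoassembly.synthetic_community import simulate_tree_and_traits
        newick, traits = simulate_tree_and_traits(60, 1.0, seed=11)
        taxa = list(traits.index)
        rng = np.random.default_rng(4)
        base = rng.lognormal(0, 1, 60) * (rng.random(60) > 0.6)
        base[0] = 1.0
        cols = {}
        for j in range(10):
            perm = rng.permutation(60)
            cols[f"s{j}"] = np.round(base[perm] * 50).astype(int)
        counts = pd.DataFrame(cols, index=taxa)
        counts.iloc[0, counts.sum(axis=0).to_numpy() == 0] = 1
        meta = pd.DataFrame(
            {"treatment": ["g"] * 10, "replicate": [f"R{j}" for j in range(10)],
             "timepoint": [0] * 10},
            index=counts.columns,
        )
        cm = CommunityMatrix(counts, meta)
        z = beta_nti(cm, patristic_matrix(newick, taxa), n_null=299, seed=3)
        vals = z.to_numpy()[np.triu_indices(10, k=1)]
        vals = vals[~np.isnan(vals)]
        assert abs(vals.mean()) < 0.4
        assert 0.6 < vals.std() < 1.4


class TestRaupCrick:
    def test_identical_communities_hit_lower_bound(self):
        """Identical rich communities: observed BC = 0, and with realistic
        richness no null replicate reproduces BC = 0, forcing RC = -1."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(5, 60, size=(12, 3)),
            index=[f"t{i}" for i in range(12)],
            columns=["s1", "s2", "s3"],
        )
        counts["s2"] = counts["s1"]
        meta = pd.DataFrame(
            {"treatment": ["g"] * 3, "replicate": ["R1", "R2", "R3"], "timepoint": [0] * 3},
            index=counts.columns,
        )
        cm = CommunityMatrix(counts, meta)
        rc = raup_crick_bray(cm, [("s1", "s2")], n_null=199, seed=0)
        assert rc.iloc[0] == pytest.approx(-1.0)

    def test_extreme_dissimilarity_near_upper_bound(self):
        """Fully disjoint communities in a large pool: observed BC = 1
        exceeds nearly every null replicate, driving RC toward +1."""
        n = 30
        cols = {"s1": np.zeros(n, int), "s2": np.zeros(n, int), "s3": np.full(n, 5)}
        cols["s1"][:12] = 40
        cols["s2"][12:24] = 40
        counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(n)])
        meta = pd.DataFrame(
            {"treatment": ["g"] * 3, "replicate": ["R1", "R2", "R3"], "timepoint": [0] * 3},
            index=counts.columns,
        )
        cm = CommunityMatrix(counts, meta)
        rc = raup_crick_bray(cm, [("s1", "s2")], n_null=199, seed=1)
        assert rc.iloc[0] > 0.95

    def test_single_sample_pool_rejected(self):
        counts = pd.DataFrame({"s1": [5, 5]}, index=["a", "b"])
        meta = pd.DataFrame(
            {"treatment": ["g"], "replicate": ["R1"], "timepoint": [0]}, index=["s1"]
        )
        cm = CommunityMatrix(counts, meta)
        with pytest.raises(ValueError, match="pool"):
            raup_crick_bray(cm, [("s1", "s1")])


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (-3.1, None, "homogeneous_selection"),
            (-2.5, None, "homogeneous_selection"),
            (2.5, None, "variable_selection"),
            (-2.0, 0.0, "undominated"),       # boundary routed to RC branch
            (2.0, 0.97, "dispersal_limitation"),
            (0.4, 0.97, "dispersal_limitation"),
            (0.4, -0.97, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (0.0, 0.95, "undominated"),       # strict RC threshold
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_decision_rule(self, bnti, rc, expected):
        assert classify_process(bnti, rc) == expected

    def test_missing_rc_in_rc_branch_rejected(self):
        with pytest.raises(ValueError):
            classify_process(0.5, None)


class TestPartitionProcesses:
    def test_degenerate_single_process(self):
        pairs = pd.DataFrame({"process": ["homogeneous_selection"] * 4})
        out = partition_processes(pairs)
        assert out.iloc[0]["homogeneous_selection"] == pytest.approx(100.0)
        assert out.iloc[0].sum() == pytest.approx(100.0)

    def test_fifty_fifty(self):
        pairs = pd.DataFrame(
            {"process": ["homogeneous_selection"] * 2 + ["dispersal_limitation"] * 2}
        )
        out = partition_processes(pairs)
        assert out.iloc[0]["homogeneous_selection"] == pytest.approx(50.0)
        assert out.iloc[0]["dispersal_limitation"] == pytest.approx(50.0)

    def test_grouped_fractions_sum_100(self):
        rng = np.random.default_rng(0)
        procs = rng.choice(
            ["variable_selection", "undominated", "dispersal_limitation"], 60
        )
        pairs = pd.DataFrame({"process": procs, "cls": rng.choice(["w", "b"], 60)})
        out = partition_processes(pairs, group_by=["cls"])
        assert np.allclose(out.sum(axis=1), 100.0)


class TestSesMpd:
    def test_clade_confined_sample_is_clustered(self):
        from ecoassembly.synthetic_community import simulate_tree_and_traits
        import dendropy
        newick, traits = simulate_tree_and_traits(80, 1.0, seed=13)
        taxa = list(traits.index)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        clade = next(
            n for n in tree.preorder_internal_node_iter()
            if 8 <= len(n.leaf_nodes()) <= 15
        )
        members = {l.taxon.label for l in clade.leaf_nodes()}
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            col = np.array([rng.integers(5, 20) if t in members else 0 for t in taxa])
            uniform = np.full(80, 5)
            counts = pd.DataFrame({"clade": col, "all": uniform}, index=taxa)
            meta = pd.DataFrame(
                {"treatment": ["g", "g"], "replicate": ["R1", "R2"], "timepoint": [0, 0]},
                index=["clade", "all"],
            )
            cm = CommunityMatrix(counts, meta)
            z = ses_mpd(cm, patristic_matrix(newick, taxa), n_null=199, seed=seed)
            if z["clade"] < 0:
                hits += 1
            assert abs(z["all"]) < 2  # whole-pool sample matches the null universe
        assert hits >= 9


class TestMakePairs:
    def test_classes_and_time_matching(self):
        meta = pd.DataFrame(
            {
                "treatment": ["a", "a", "b", "a"],
                "replicate": ["R1", "R2", "R1", "R1"],
                "timepoint": [0, 0, 0, 12],
            },
            index=["s1", "s2", "s3", "s4"],
        )
        within = make_pairs(meta, "within_replicates")
        between = make_pairs(meta, "between_cs")
        assert within == [("s1", "s2")]
        assert set(between) == {("s1", "s3"), ("s2", "s3")}
        all_within = make_pairs(meta, "within_replicates", time_matched=False)
        assert ("s2", "s4") in all_within
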