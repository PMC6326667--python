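"""Window filter, class partition, z-scores, medoids and hierarchical
ordering, each checked against rule examples, invariants and brute-force
oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from midtraject import trajectory_classes as tc


def deg(genes_dirs) -> pd.DataFrame:
    idx = pd.Index([g for g, _ in genes_dirs], name="gene_id")
    return pd.DataFrame({"direction": [d for _, d in genes_dirs]}, index=idx)


class TestDiagonalWindowFilter:
    @pytest.mark.parametrize(
        "fc_se,fc_ee,inside",
        [
            (1.0, 1.2, True),
            (1.0, 1.6, False),
            (-0.8, -0.5, True),
            (0.0, 0.0, True),
            (0.0, 0.1, False),
            (1.0, 1.5, True),  # boundary is inclusive
        ],
    )
    def test_rule_examples(self, fc_se, fc_ee, inside):
        out = tc.diagonal_window_filter(
            pd.DataFrame({"fc_se": [fc_se], "fc_ee": [fc_ee]}), 0.5
        )
        assert bool(out["inside_window"].iloc[0]) is inside

    @given(
        st.floats(min_value=-3, max_value=3, allow_nan=False),
        st.floats(min_value=-3, max_value=3, allow_nan=False),
        st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_consistency(self, fc_se, fc_ee, scale):
        # stay away from the exact window boundary, where floating-point
        # rescaling can legitimately flip the comparison
        margin = abs(abs(fc_ee - fc_se) - 0.5 * abs(fc_se))
        assume(margin > 1e-6 * max(1.0, abs(fc_se)))
        base = tc.diagonal_window_filter(
            pd.DataFrame({"fc_se": [fc_se], "fc_ee": [fc_ee]}), 0.5
        )["inside_window"].iloc[0]
        scaled = tc.diagonal_window_filter(
            pd.DataFrame({"fc_se": [fc_se * scale], "fc_ee": [fc_ee * scale]}), 0.5
        )["inside_window"].iloc[0]
        assert base == scaled

    def test_brute_force(self, rng):
        fc = pd.DataFrame(
            {"fc_se": rng.normal(0, 1, 500), "fc_ee": rng.normal(0, 1, 500)}
        )
        out = tc.diagonal_window_filter(fc, 0.5)
        brute = [
            (abs(r.fc_ee - r.fc_se) <= 0.5 * abs(r.fc_se))
            if r.fc_se != 0
            else (r.fc_ee == 0)
            for r in fc.itertuples()
        ]
        assert (out["inside_window"].to_numpy() == brute).all()

    def test_symmetric_rule_option(self):
        fc = pd.DataFrame({"fc_se": [1.0], "fc_ee": [1.9]})
        assert not tc.diagonal_window_filter(fc, 0.5)["inside_window"].iloc[0]
        assert tc.diagonal_window_filter(fc, 0.5, rule="symmetric")[
            "inside_window"
        ].iloc[0]


class TestCombineTemporalDegs:
    def test_disjoint_union(self):
        a = deg([(f"a{i}", "up") for i in range(10)])
        b = deg([(f"b{i}", "down") for i in range(5)])
        out = tc.combine_temporal_degs({"a": a, "b": b})
        assert len(out) == 15

    def test_idempotence(self):
        a = deg([("g1", "up"), ("g2", "down")])
        out = tc.combine_temporal_degs({"x": a, "y": a})
        assert set(out.index) == {"g1", "g2"}

    def test_inclusion_exclusion(self, rng):
        universe = [f"g{i}" for i in range(50)]
        a_genes = [universe[i] for i in rng.choice(50, 25, replace=False)]
        b_genes = [universe[i] for i in rng.choice(50, 25, replace=False)]
        a = deg([(g, "up") for g in a_genes])
        b = deg([(g, "up") for g in b_genes])
        out = tc.combine_temporal_degs({"a": a, "b": b})
        assert len(out) == len(set(a_genes)) + len(set(b_genes)) - len(
            set(a_genes) & set(b_genes)
        )

    def test_conflicting_directions_kept_per_source(self):
        out = tc.combine_temporal_degs(
            {"a": deg([("g", "up")]), "b": deg([("g", "down")])}
        )
        assert out.loc["g", "dir_a"] == "up" and out.loc["g", "dir_b"] == "down"


class TestAssignClasses:
    def test_rule_table(self):
        wt = deg([("c1", "up"), ("c3", "down"), ("conflict", "up")])
        tg = deg([("c1", "up"), ("c2t", "down"), ("conflict", "down")])
        g12 = deg([("c2g", "up")])
        out = tc.assign_classes(wt, tg, g12)
        assert out.loc["c1", "class_label"] == 1 and out.loc["c1", "cluster"] == "1-up"
        assert out.loc["c2t", "class_label"] == 2 and out.loc["c2t", "cluster"] == "2-down"
        assert out.loc["c2g", "class_label"] == 2 and out.loc["c2g", "cluster"] == "2-up"
        assert out.loc["c3", "class_label"] == 3 and out.loc["c3", "cluster"] == "3-down"
        assert out.loc["conflict", "class_label"] == 0
        assert out.loc["conflict", "cluster"] == "unclassified"

    def test_partition_property(self, rng):
        genes = [f"g{i}" for i in range(60)]
        def random_set(k):
            chosen = rng.choice(genes, size=k, replace=False)
            return deg([(g, rng.choice(["up", "down"])) for g in chosen])
        wt, tg, g12 = random_set(25), random_set(25), random_set(25)
        out = tc.assign_classes(wt, tg, g12)
        assert set(out.index) == set(wt.index) | set(tg.index) | set(g12.index)
        assert out["class_label"].isin([0, 1, 2, 3]).all()

    def test_recovery_degrades_toward_threshold(self):
        """End-to-end class recovery is high at lfc=1 and decreases
        monotonically as the planted effect approaches the DEG threshold."""
        from midtraject.benchmarks import class_recovery_benchmark

        recov = {}
        for lfc in (0.4, 0.7, 1.0):
            out = class_recovery_benchmark(11, n_genes=900, lfc_magnitude=lfc)
            recov[lfc] = (out["class2_recovery"] + out["class3_recovery"]) / 2
        assert recov[0.4] < recov[0.7] < recov[1.0]
        assert recov[1.0] > 0.7
        assert class_recovery_benchmark(11, n_genes=900)["null_misassigned"] < 0.1


class TestZscore:
    def test_hand_example_sample_sd(self):
        z = tc.zscore_matrix(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert z.to_numpy()[0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zeroed(self):
        z = tc.zscore_matrix(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert (z.to_numpy() == 0).all()

    def test_row_moments(self, rng):
        z = tc.zscore_matrix(pd.DataFrame(rng.normal(size=(20, 8))))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


class TestClusterMedoids:
    @staticmethod
    def _assignment(clusters):
        idx = pd.Index(list(clusters), name="gene_id")
        return pd.DataFrame(
            {
                "class_label": [int(c[0]) for c in clusters.values()],
                "cluster": list(clusters.values()),
            },
            index=idx,
        )

    def test_singleton_cluster(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["only"],
                                columns=list("abcd"))
        out = tc.cluster_medoids(profiles, self._assignment({"only": "2-up"}))
        assert out.loc[0, "medoid_gene"] == "only"
        assert out.loc[0, "sd_a"] == 0.0

    def test_majority_geometry(self):
        profiles = pd.DataFrame(
            [[0, 0, 0, 0], [0, 0, 0, 0], [5, 5, 5, 5]],
            index=["p1", "p2", "q"], columns=list("abcd"), dtype=float,
        )
        out = tc.cluster_medoids(
            profiles, self._assignment({"p1": "1-up", "p2": "1-up", "q": "1-up"})
        )
        assert out.loc[0, "medoid_gene"] in {"p1", "p2"}
        assert out.loc[0, "medoid_a"] == 0.0

    def test_exhaustive_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(12)]
        profiles = pd.DataFrame(rng.normal(size=(12, 4)), index=genes,
                                columns=list("abcd"))
        out = tc.cluster_medoids(profiles, self._assignment({g: "3-down" for g in genes}))
        sums = {
            g: sum(np.linalg.norm(profiles.loc[g] - profiles.loc[h]) for h in genes)
            for g in genes
        }
        best = min(sorted(genes), key=lambda g: sums[g])
        assert out.loc[0, "medoid_gene"] == best
        assert out.loc[0, "n_members"] == 12


class TestHierarchicalOrder:
    def test_identical_rows_adjacent(self):
        z = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, -2.0]],
            index=["a", "b", "c"],
        )
        order, lk = tc.hierarchical_order(z)
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["a"] - pos["b"]) == 1
        assert lk[0, 2] == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        z = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
        d = tc.correlation_distance_matrix(z)
        assert d[0, 1] == pytest.approx(2.0)

    def test_merge_sequence_matches_brute_force(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(6, 10)), index=[f"g{i}" for i in range(6)]
        )
        _, lk = tc.hierarchical_order(z)
        # independent average-linkage agglomeration
        d = tc.correlation_distance_matrix(z.sort_index())
        clusters = {i: frozenset([i]) for i in range(6)}
        merges = []
        next_id = 6
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                dist = np.mean(
                    [d[a, b] for a in clusters[i] for b in clusters[j]]
                )
                if best is None or dist < best[0] - 1e-12:
                    best = (dist, i, j)
            dist, i, j = best
            clusters[next_id] = clusters[i] | clusters[j]
            merges.append((clusters[next_id], dist))
            del clusters[i], clusters[j]
            next_id += 1
        # compare merge heights and member sets against scipy's linkage
        scipy_members = {i: frozenset([i]) for i in range(6)}
        for row_idx, row in enumerate(lk):
            members = scipy_members[int(row[0])] | scipy_members[int(row[1])]
            scipy_members[6 + row_idx] = members
            assert members == merges[row_idx][0]
            assert row[2] == pytest.approx(merges[row_idx][1])

    def test_constant_gene_gets_maximal_distance(self):
        z = pd.DataFrame(
            [[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]], index=["var", "const"]
        )
        d = tc.correlation_distance_matrix(z)
        assert d[0, 1] == pytest.approx(2.0)
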