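"""Bootstrap co-membership and the community assortativity coefficient."""

import numpy as np
import pytest

from netsubsample import (
    AssociationMatrix,
    GeneratorConfig,
    Partition,
    RoostingData,
    association_matrix,
    bootstrap_partitions,
    comembership,
    community_assortativity,
    fast_greedy_communities,
    generate_population,
    rcom_pipeline,
)


def make_partitions(label_sets):
    return [Partition(labels=dict(ls)) for ls in label_sets]


class TestBootstrapPartitions:
    def test_single_day_data_replicates_identically(self):
        data = RoostingData.from_records(
            [("A", 0, "r1"), ("B", 0, "r1"), ("C", 0, "r2"), ("D", 0, "r2")]
        )
        parts = bootstrap_partitions(data, n_boot=20, seed=1)
        first = parts[0].labels
        assert all(p.labels == first for p in parts)

    def test_disjoint_cliques_split_identically_every_replicate(self, two_cliques_data):
        parts = bootstrap_partitions(two_cliques_data, n_boot=50, seed=2)
        cm = comembership(parts)
        i = {v: k for k, v in enumerate(cm.ids)}
        for a, b in [("A", "B"), ("B", "C"), ("D", "E"), ("E", "F")]:
            assert cm.p_same[i[a], i[b]] == 1.0
        for a, b in [("A", "D"), ("C", "F")]:
            assert cm.p_same[i[a], i[b]] == 0.0

    def test_seeded_determinism(self, structured_small):
        data, _, _ = structured_small
        p1 = bootstrap_partitions(data, n_boot=10, seed=5)
        p2 = bootstrap_partitions(data, n_boot=10, seed=5)
        assert all(a.labels == b.labels for a, b in zip(p1, p2))


class TestComembership:
    def test_direct_proportion(self):
        parts = make_partitions(
            [{"A": 0, "B": 0, "C": 1}] * 6 + [{"A": 0, "B": 1, "C": 1}] * 4
        )
        cm = comembership(parts)
        i = {v: k for k, v in enumerate(cm.ids)}
        assert cm.p_same[i["A"], i["B"]] == pytest.approx(0.6)
        assert cm.p_same[i["B"], i["C"]] == pytest.approx(0.4)
        assert np.allclose(np.diag(cm.p_same), 1.0)
        assert np.allclose(cm.p_same, cm.p_same.T)

    def test_all_singleton_partitions_give_zero_offdiagonal(self):
        parts = make_partitions([{"A": 0, "B": 1, "C": 2}] * 5)
        cm = comembership(parts)
        off = cm.p_same[~np.eye(3, dtype=bool)]
        assert (off == 0).all()

    def test_mismatched_id_sets_rejected(self):
        parts = make_partitions([{"A": 0, "B": 0}, {"A": 0, "C": 0}])
        with pytest.raises(ValueError, match="different individual sets"):
            comembership(parts)


class TestCommunityAssortativity:
    def test_perfectly_modular_network_gives_one(self):
        ids = ["A", "B", "C", "D"]
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        m = AssociationMatrix(ids=ids, w=w)
        obs = Partition(labels={"A": 0, "B": 0, "C": 1, "D": 1})
        cm = comembership(make_partitions([obs.labels] * 10))
        res = community_assortativity(m, obs, cm)
        assert res.r_com == pytest.approx(1.0)
        assert not res.degenerate

    def test_edgeless_network_is_degenerate_zero(self):
        ids = ["A", "B", "C"]
        m = AssociationMatrix(ids=ids, w=np.zeros((3, 3)))
        obs = Partition(labels={"A": 0, "B": 1, "C": 2})
        cm = comembership(make_partitions([obs.labels] * 5))
        res = community_assortativity(m, obs, cm)
        assert res.r_com == 0.0 and res.degenerate

    def test_random_labels_on_uniform_network_score_near_zero(self):
        # labels carry no information about the bootstrap co-membership
        rng = np.random.default_rng(13)
        n = 30
        ids = [f"n{i}" for i in range(n)]
        w = np.ones((n, n)) - np.eye(n)
        m = AssociationMatrix(ids=ids, w=w)
        values = []
        for _ in range(100):
            obs = Partition(labels={i: int(rng.integers(3)) for i in ids})
            p = rng.random((n, n))
            p = (p + p.T) / 2  # arbitrary symmetric co-membership pattern
            np.fill_diagonal(p, 1.0)
            from netsubsample import ComembershipMatrix

            cm = ComembershipMatrix(ids=ids, p_same=p)
            values.append(community_assortativity(m, obs, cm).r_com)
        assert abs(np.mean(values)) < 0.1

    def test_result_always_within_bounds(self, rng):
        from netsubsample import ComembershipMatrix

        n = 8
        ids = [f"n{i}" for i in range(n)]
        for _ in range(50):
            w = rng.random((n, n)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
            p = rng.random((n, n)); p = (p + p.T) / 2; np.fill_diagonal(p, 1.0)
            obs = Partition(labels={i: int(rng.integers(3)) for i in ids})
            res = community_assortativity(
                AssociationMatrix(ids=ids, w=w), obs, ComembershipMatrix(ids=ids, p_same=p)
            )
            assert -1.0 <= res.r_com <= 1.0


class TestRcomPipeline:
    def test_disjoint_cliques_give_high_confidence(self, two_cliques_data):
        res = rcom_pipeline(two_cliques_data, n_boot=200, seed=3)
        assert res.r_com >= 0.99

    def test_repeat_average_equals_mean_of_single_runs(self, structured_small):
        data, _, _ = structured_small
        res = rcom_pipeline(data, n_boot=20, n_repeat=3, seed=11)
        seeds = np.random.SeedSequence(11).generate_state(3) % (2**31)
        m = association_matrix(data)
        obs = fast_greedy_communities(m)
        singles = []
        for s in seeds:
            parts = bootstrap_partitions(data, n_boot=20, seed=int(s))
            singles.append(community_assortativity(m, obs, comembership(parts)).r_com)
        assert res.r_com == pytest.approx(np.mean(singles))

    def test_more_observations_stabilize_assignment(self):
        """Median R_com rises with observations per individual, up to a plateau."""
        medians = []
        for n_days in (8, 30, 90):
            vals = []
            for seed in range(5):
                cfg = GeneratorConfig(
                    n_individuals=24, n_communities=3, n_days=n_days, n_roosts=6,
                    p_detect=0.5, p_drift=0.1, p_fission=0.3, p_home_switch=0.2,
                    drift_concentration=None, seed=100 + seed,
                )
                data, _ = generate_population(cfg)
                vals.append(rcom_pipeline(data, n_boot=50, seed=seed).r_com)
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] + 0.05
        assert medians[1] <= medians[2] + 0.05
        assert medians[2] > 0.8
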