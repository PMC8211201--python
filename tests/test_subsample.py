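"""Reference building, sample drawing, similarity, and the experiment grid."""

import numpy as np
import pandas as pd
import pytest

from netsubsample import (
    GeneratorConfig,
    Partition,
    RoostingData,
    balance_observations,
    build_observed,
    draw_sample,
    dyad_similarity,
    evaluate_sample,
    generate_population,
    run_experiment,
    summarize_grid,
)
from netsubsample.subsample import regime_seed

from conftest import brute_rand_similarity


@pytest.fixture(scope="module")
def small_ref():
    cfg = GeneratorConfig(
        n_individuals=24, n_communities=3, n_days=40, n_roosts=6,
        p_detect=0.8, p_drift=0.05, p_fission=0.3, p_home_switch=0.2,
        drift_concentration=None, seed=21,
    )
    data, _ = generate_population(cfg)
    return build_observed(
        data, min_days=20, obs_cap=20, seed=2, n_rand=100, n_boot=100, n_repeat=2
    )


class TestBalanceAndBuild:
    def test_truncation_is_identity_when_counts_equal_cap(self):
        records = [(f"I{i}", d, "r1") for i in range(3) for d in range(5)]
        data = RoostingData.from_records(records)
        rng = np.random.default_rng(0)
        out = balance_observations(data, min_days=5, obs_cap=5, rng=rng)
        assert out == data

    def test_individual_below_threshold_is_excluded(self):
        records = [("A", d, "r1") for d in range(5)] + [("B", d, "r1") for d in range(4)]
        data = RoostingData.from_records(records)
        out = balance_observations(data, min_days=5, obs_cap=5, rng=np.random.default_rng(0))
        assert out.individuals == ["A"]

    def test_build_requires_two_qualifying_individuals(self):
        data = RoostingData.from_records([("A", d, "r1") for d in range(10)])
        with pytest.raises(ValueError, match="need at least 2"):
            build_observed(data, min_days=5, obs_cap=5, seed=1, n_rand=5, n_boot=5, n_repeat=1)

    def test_reference_is_balanced_and_significant(self, small_ref):
        counts = small_ref.data.frame.groupby("individual_id").size()
        assert (counts == small_ref.obs_cap).all()
        assert small_ref.p_q < 0.05  # structured generator data
        assert small_ref.metrics.n_communities == 3


class TestDrawSample:
    def test_complete_cell_is_rejected(self, small_ref):
        with pytest.raises(ValueError, match="complete"):
            draw_sample(small_ref, small_ref.n_individuals, small_ref.obs_cap, seed=1)

    def test_single_observation_per_individual(self, small_ref):
        sample = draw_sample(small_ref, 10, 1, seed=3)
        counts = sample.frame.groupby("individual_id").size()
        assert len(counts) == 10 and (counts == 1).all()

    def test_fixed_seed_reproduces_sample(self, small_ref):
        assert draw_sample(small_ref, 8, 5, seed=9) == draw_sample(small_ref, 8, 5, seed=9)

    def test_oversampling_raises(self, small_ref):
        with pytest.raises(ValueError, match="cannot sample"):
            draw_sample(small_ref, small_ref.n_individuals + 1, 5, seed=1)
        with pytest.raises(ValueError, match="cannot sample"):
            draw_sample(small_ref, 5, small_ref.obs_cap + 1, seed=1)


class TestDyadSimilarity:
    def test_identical_partitions_give_one(self):
        p = Partition(labels={"A": 0, "B": 0, "C": 1})
        assert dyad_similarity(p, p) == 1.0

    def test_singletons_vs_one_community_give_zero(self):
        s = Partition(labels={"A": 0, "B": 1, "C": 2})
        r = Partition(labels={"A": 0, "B": 0, "C": 0})
        assert dyad_similarity(s, r) == 0.0

    def test_matches_brute_force_on_random_partitions(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 11))
            ids = [f"n{i}" for i in range(n)]
            s = {i: int(rng.integers(3)) for i in ids}
            sub = sorted(rng.choice(ids, size=int(rng.integers(2, n + 1)), replace=False))
            r = {i: int(rng.integers(3)) for i in ids}
            got = dyad_similarity(Partition(labels={i: s[i] for i in sub}), Partition(labels=r))
            assert got == pytest.approx(brute_rand_similarity(s, r, sub))

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            dyad_similarity(Partition(labels={"A": 0}), Partition(labels={"A": 0}))


class TestEvaluateSample:
    def test_edgeless_sample_takes_the_degenerate_path(self, small_ref):
        # one observation per individual rarely yields any co-roosting dyad;
        # craft a certainly edgeless sample instead
        ids = small_ref.ids[:4]
        records = [(ind, d, f"r{d}") for d, ind in enumerate(ids)]
        sample = RoostingData.from_records(records)
        sm = evaluate_sample(sample, small_ref, n_rand=20, n_boot=20, seed=1)
        assert sm.degenerate
        assert sm.metrics.q == 0.0
        assert sm.metrics.n_communities == len(ids)
        assert sm.evidence == 0 and sm.r_com == 0.0 and sm.acceptable_rcom == 0

    def test_metrics_and_flags_are_consistent(self, small_ref):
        sample = draw_sample(small_ref, 12, 10, seed=5)
        sm = evaluate_sample(sample, small_ref, n_rand=50, n_boot=50, seed=5)
        assert (sm.evidence == 1) == (sm.p_q < 0.05 and not sm.degenerate)
        assert (sm.acceptable_rcom == 1) == (0.5 <= sm.r_com <= small_ref.r_com_obs)
        assert 0 <= sm.similarity <= 1
        assert sm.delta_n_comm >= 0 and sm.delta_density >= 0 and sm.delta_clustering >= 0


class TestRunExperiment:
    def test_row_count_covers_grid_minus_excluded_cell(self, small_ref):
        results = run_experiment(
            small_ref, individuals_grid=(6, small_ref.n_individuals),
            obs_grid=(5, small_ref.obs_cap), n_reps=2, n_rand=20, n_boot=20, seed=7,
        )
        assert len(results) == (2 * 2 - 1) * 2

    def test_sample_sizes_match_their_regime(self, small_ref):
        results = run_experiment(
            small_ref, individuals_grid=(6,), obs_grid=(3,), n_reps=3,
            n_rand=20, n_boot=20, seed=7,
        )
        assert (results["n_individuals"] == 6).all()
        assert (results["n_obs"] == 3).all()

    def test_deterministic_given_master_seed(self, small_ref):
        kwargs = dict(
            individuals_grid=(8,), obs_grid=(5,), n_reps=3, n_rand=20, n_boot=20, seed=3
        )
        r1 = run_experiment(small_ref, **kwargs)
        r2 = run_experiment(small_ref, **kwargs)
        pd.testing.assert_frame_equal(r1, r2)

    def test_resume_skips_completed_regimes(self, small_ref, tmp_path):
        out = tmp_path / "results.csv"
        kwargs = dict(obs_grid=(5,), n_reps=2, n_rand=10, n_boot=10, seed=3, out_path=out)
        run_experiment(small_ref, individuals_grid=(6,), **kwargs)
        first = pd.read_csv(out)
        full = run_experiment(small_ref, individuals_grid=(6, 8), **kwargs)
        assert set(map(tuple, full[["n_individuals", "n_obs"]].drop_duplicates().values)) == {
            (6, 5), (8, 5),
        }
        # the previously computed regime is reused untouched
        merged = pd.read_csv(out)
        pd.testing.assert_frame_equal(
            merged[merged["n_individuals"] == 6].reset_index(drop=True), first
        )

    def test_regime_seed_is_stable(self):
        assert regime_seed(1, 10, 5, 0) == regime_seed(1, 10, 5, 0)
        assert regime_seed(1, 10, 5, 0) != regime_seed(1, 10, 5, 1)
        assert 0 <= regime_seed(123, 99, 40, 99) < 2**31


class TestSummarizeGrid:
    def test_counts_are_exact_recounts(self, small_ref):
        results = run_experiment(
            small_ref, individuals_grid=(6, 10), obs_grid=(5, 10), n_reps=4,
            n_rand=20, n_boot=20, seed=11,
        )
        summary = summarize_grid(results, small_ref)
        ref_k = small_ref.metrics.n_communities
        for _, row in summary.iterrows():
            grp = results[
                (results["n_individuals"] == row["n_individuals"])
                & (results["n_obs"] == row["n_obs"])
            ]
            assert row["n_reps"] == len(grp)
            assert row["evidence_count"] == int(grp["evidence"].sum())
            assert row["evidence_count"] <= row["n_reps"]
            assert row["acceptable_rcom_count"] == int(grp["acceptable_rcom"].sum())
            assert row["correct_n_comm_count"] == int((grp["n_communities"] == ref_k).sum())
            assert row["within_one_n_comm_count"] >= row["correct_n_comm_count"]

    def test_empty_results_rejected(self, small_ref):
        with pytest.raises(ValueError, match="empty"):
            summarize_grid(pd.DataFrame(), small_ref)
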