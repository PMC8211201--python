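"""The subsampling experiment: how many individuals, how many observations?

The full detection stream is first balanced — individuals with at least
``min_days`` detections are kept and truncated to exactly ``obs_cap``
randomly chosen observations each — and the resulting 'observed'
reference network is characterized once (metrics, permutation p-value of
modularity, mean R_com over repeated bootstrap runs).

The experiment then crosses a grid of (number of individuals, number of
observations per individual), draws many random subsamples per cell,
recomputes every global metric on each subsample, and scores each
against the reference: evidence for community structure (permutation
p < 0.05), acceptable R_com (0.5 <= R_com <= reference R_com), dyadic
community-assignment similarity, and absolute discrepancies in community
count, density and clustering. The cell equal to the full reference
(all individuals x all observations) is excluded. Edgeless subsample
networks are a defined outcome: Q = 0, one community per individual, no
evidence, R_com = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationMatrix, association_matrix
from .datatypes import GlobalMetrics, Partition, RoostingData
from .netmetrics import fast_greedy_communities, global_metrics
from .nullmodels import monte_carlo_p, null_distribution
from .rcom import bootstrap_partitions, comembership, community_assortativity

ALPHA = 0.05
RCOM_THRESHOLD = 0.5


def balance_observations(
    data: RoostingData, min_days: int, obs_cap: int, rng: np.random.Generator
) -> RoostingData:
    """Keep individuals with >= min_days records, truncated to obs_cap each."""
    frame = data.frame.sort_values(["individual_id", "day"]).reset_index(drop=True)
    kept = []
    for ind, grp in frame.groupby("individual_id", sort=True):
        if len(grp) < min_days:
            continue
        idx = rng.choice(len(grp), size=obs_cap, replace=False)
        kept.append(grp.iloc[np.sort(idx)])
    if not kept:
        return RoostingData.from_records([])
    return RoostingData(pd.concat(kept, ignore_index=True))


@dataclass
class ObservedReference:
    """The balanced full-data network every subsample is compared against."""

    data: RoostingData
    matrix: AssociationMatrix
    metrics: GlobalMetrics
    partition: Partition
    p_q: float
    r_com_obs: float
    min_days: int
    obs_cap: int

    @property
    def ids(self) -> list[str]:
        return list(self.matrix.ids)

    @property
    def n_individuals(self) -> int:
        return len(self.matrix.ids)


@dataclass
class SamplingRegime:
    n_individuals: int
    n_obs: int
    replicate: int
    seed: int


@dataclass
class SampleMetrics:
    """Everything measured on one subsampled network."""

    regime: SamplingRegime
    metrics: GlobalMetrics
    p_q: float
    evidence: int
    r_com: float
    acceptable_rcom: int
    similarity: float
    delta_n_comm: int
    delta_density: float
    delta_clustering: float
    degenerate: bool

    def as_row(self) -> dict:
        return {
            "n_individuals": self.regime.n_individuals,
            "n_obs": self.regime.n_obs,
            "replicate": self.regime.replicate,
            "seed": self.regime.seed,
            **self.metrics.as_dict(),
            "p_q": self.p_q,
            "evidence": self.evidence,
            "r_com": self.r_com,
            "acceptable_rcom": self.acceptable_rcom,
            "similarity": self.similarity,
            "delta_n_comm": self.delta_n_comm,
            "delta_density": self.delta_density,
            "delta_clustering": self.delta_clustering,
            "degenerate": int(self.degenerate),
        }


def build_observed(
    data: RoostingData,
    min_days: int = 40,
    obs_cap: int = 40,
    seed: int = 0,
    n_rand: int = 1000,
    n_boot: int = 1000,
    n_repeat: int = 10,
) -> ObservedReference:
    """Balance the detection stream and characterize the reference network."""
    from .rcom import rcom_pipeline  # local import to keep module load cheap

    rng = np.random.default_rng(seed)
    balanced = balance_observations(data, min_days, obs_cap, rng)
    n_kept = len(balanced.individuals)
    if n_kept < 2:
        raise ValueError(
            f"only {n_kept} individual(s) have >= {min_days} detections; "
            "need at least 2 to build the reference network"
        )
    m = association_matrix(balanced)
    partition = fast_greedy_communities(m)
    gm = global_metrics(m, partition)
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    null = null_distribution(balanced, n_rand=n_rand, seed=int(ss[0]))
    p_q = monte_carlo_p(partition.q, null)
    r_obs = rcom_pipeline(
        balanced, n_boot=n_boot, n_repeat=n_repeat, seed=int(ss[1]),
        obs_partition=partition,
    )
    return ObservedReference(
        data=balanced,
        matrix=m,
        metrics=gm,
        partition=partition,
        p_q=p_q,
        r_com_obs=r_obs.r_com,
        min_days=min_days,
        obs_cap=obs_cap,
    )


def draw_sample(
    ref: ObservedReference, n_individuals: int, n_obs: int, seed: int
) -> RoostingData:
    """Random subsample: n_individuals without replacement, n_obs records each."""
    pop = ref.ids
    if n_individuals > len(pop):
        raise ValueError(f"cannot sample {n_individuals} of {len(pop)} individuals")
    if n_obs > ref.obs_cap:
        raise ValueError(f"cannot sample {n_obs} of {ref.obs_cap} observations")
    if n_individuals == len(pop) and n_obs == ref.obs_cap:
        raise ValueError(
            "the all-individuals, all-observations cell is the complete "
            "reference network and is excluded from sampling"
        )
    rng = np.random.default_rng(seed)
    chosen = [pop[i] for i in np.sort(rng.choice(len(pop), size=n_individuals, replace=False))]
    frame = ref.data.frame
    parts = []
    for ind in chosen:
        grp = frame[frame["individual_id"] == ind]
        idx = rng.choice(len(grp), size=n_obs, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return RoostingData(pd.concat(parts, ignore_index=True))


def dyad_similarity(sample_p: Partition, ref_p: Partition) -> float:
    """Proportion of sampled dyads whose same/different-community status agrees.

    A Rand index restricted to the sampled individuals: 1 means every
    dyad's co-assignment matches the reference partition.
    """
    ids = sorted(sample_p.labels)
    if len(ids) < 2:
        raise ValueError("dyad similarity needs at least 2 individuals")
    missing = [i for i in ids if i not in ref_p.labels]
    if missing:
        raise ValueError(f"sampled individuals missing from reference partition: {missing[:5]}")
    ls = sample_p.label_array(ids)
    lr = ref_p.label_array(ids)
    same_s = ls[:, None] == ls[None, :]
    same_r = lr[:, None] == lr[None, :]
    iu = np.triu_indices(len(ids), 1)
    return float(np.mean(same_s[iu] == same_r[iu]))


def evaluate_sample(
    sample: RoostingData,
    ref: ObservedReference,
    n_rand: int,
    n_boot: int,
    seed: int,
    regime: SamplingRegime | None = None,
) -> SampleMetrics:
    """All metrics, the permutation test, R_com and reference comparisons."""
    if regime is None:
        regime = SamplingRegime(
            n_individuals=len(sample.individuals),
            n_obs=int(sample.frame.groupby("individual_id").size().max()),
            replicate=0,
            seed=seed,
        )
    m = association_matrix(sample)
    n = m.n
    degenerate = not np.any(m.w > 0)
    if degenerate:
        partition = Partition(labels={i: k for k, i in enumerate(m.ids)}, q=0.0, degenerate=True)
        gm = GlobalMetrics(q=0.0, n_communities=n, density=0.0, clustering=0.0)
        p_q, evidence, r_com = 1.0, 0, 0.0
    else:
        partition = fast_greedy_communities(m)
        gm = global_metrics(m, partition)
        ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
        null = null_distribution(sample, n_rand=n_rand, seed=int(ss[0]))
        p_q = monte_carlo_p(partition.q, null)
        evidence = int(p_q < ALPHA)
        parts = bootstrap_partitions(sample, n_boot=n_boot, seed=int(ss[1]))
        r_res = community_assortativity(m, partition, comembership(parts))
        r_com = r_res.r_com
    acceptable = int(RCOM_THRESHOLD <= r_com <= ref.r_com_obs)
    similarity = dyad_similarity(partition, ref.partition)
    return SampleMetrics(
        regime=regime,
        metrics=gm,
        p_q=p_q,
        evidence=evidence,
        r_com=r_com,
        acceptable_rcom=acceptable,
        similarity=similarity,
        delta_n_comm=abs(gm.n_communities - ref.metrics.n_communities),
        delta_density=abs(gm.density - ref.metrics.density),
        delta_clustering=abs(gm.clustering - ref.metrics.clustering),
        degenerate=degenerate,
    )


def regime_seed(master_seed: int, n_individuals: int, n_obs: int, replicate: int) -> int:
    """Deterministic per-replicate seed from the master seed and the regime."""
    ss = np.random.SeedSequence([int(master_seed), n_individuals, n_obs, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    ref: ObservedReference,
    individuals_grid=(5, 10, 15, 20, 25, 35, 50, 75, 99),
    obs_grid=(1, 5, 10, 15, 20, 30, 40),
    n_reps: int = 100,
    n_rand: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    out_path: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """One SampleMetrics row per (regime, replicate); the full-data cell is skipped.

    If ``out_path`` is given, rows are flushed to CSV after each regime and
    already-completed regimes found there are skipped on rerun (resumable).
    """
    done: set[tuple[int, int]] = set()
    existing: pd.DataFrame | None = None
    if out_path is not None and Path(out_path).exists():
        existing = pd.read_csv(out_path)
        done = set(zip(existing["n_individuals"], existing["n_obs"]))

    frames = [] if existing is None else [existing]
    n_pop = ref.n_individuals
    for n_ind in individuals_grid:
        n_ind = int(min(n_ind, n_pop))
        for n_obs in obs_grid:
            n_obs = int(n_obs)
            if n_ind == n_pop and n_obs == ref.obs_cap:
                continue  # the complete reference network
            if (n_ind, n_obs) in done:
                continue
            rows = []
            for rep in range(n_reps):
                s = regime_seed(seed, n_ind, n_obs, rep)
                regime = SamplingRegime(n_individuals=n_ind, n_obs=n_obs, replicate=rep, seed=s)
                sample = draw_sample(ref, n_ind, n_obs, seed=s)
                sm = evaluate_sample(sample, ref, n_rand=n_rand, n_boot=n_boot, seed=s, regime=regime)
                rows.append(sm.as_row())
            frames.append(pd.DataFrame(rows))
            if progress:
                print(f"regime n_individuals={n_ind} n_obs={n_obs}: {n_reps} replicates done")
            if out_path is not None:
                pd.concat(frames, ignore_index=True).to_csv(out_path, index=False)
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return results.sort_values(["n_individuals", "n_obs", "replicate"]).reset_index(drop=True)


def summarize_grid(results: pd.DataFrame, ref: ObservedReference | int) -> pd.DataFrame:
    """Per-regime counts: evidence, acceptable R_com, correct community number.

    'Correct' is reported both as exact equality with the reference count
    and as within +/- 1 of it.
    """
    if results.empty:
        raise ValueError("results table is empty")
    ref_k = ref if isinstance(ref, int) else ref.metrics.n_communities
    rows = []
    for (n_ind, n_obs), grp in results.groupby(["n_individuals", "n_obs"], sort=True):
        rows.append(
            {
                "n_individuals": int(n_ind),
                "n_obs": int(n_obs),
                "n_reps": len(grp),
                "evidence_count": int(grp["evidence"].sum()),
                "acceptable_rcom_count": int(grp["acceptable_rcom"].sum()),
                "correct_n_comm_count": int((grp["n_communities"] == ref_k).sum()),
                "within_one_n_comm_count": int(
                    ((grp["n_communities"] - ref_k).abs() <= 1).sum()
                ),
            }
        )
    return pd.DataFrame(rows)
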