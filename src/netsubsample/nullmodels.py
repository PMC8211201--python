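"""Day-constrained randomization and the Monte-Carlo test for community structure.

The null model randomly reassigns the individuals detected on a given
day to that day's roost groups, holding fixed (i) which individuals were
detected each day and (ii) the multiset of group sizes each day.
Individuals never move across days. Each random network is a full
independent within-day reshuffle — this samples the constrained space
uniformly with no burn-in — after which the association network is
rebuilt and its fast-greedy modularity recorded.

The Monte-Carlo p-value is the fraction of random networks whose
modularity is at least the observed one (ties count toward the
numerator, the conservative reading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import (
    AssociationMatrix,
    DailyGroups,
    compile_data,
    hwi_from_codes,
)
from .datatypes import RoostingData
from .netmetrics import fast_greedy_communities, graph_density, global_clustering


@dataclass
class NullDistribution:
    """Modularity values (and optionally density/clustering) of random networks."""

    q_values: np.ndarray
    n_rand: int
    density_values: np.ndarray | None = None
    clustering_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        if len(self.q_values) != self.n_rand:
            raise ValueError("length of q_values must equal n_rand")


def permute_days(groups: DailyGroups, seed: int | np.random.Generator) -> DailyGroups:
    """Reassign each day's detected individuals uniformly to that day's groups.

    The multiset of group sizes is preserved exactly per day; individuals
    never move across days.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[int, dict[str, set]] = {}
    for day in sorted(groups.by_day):
        roosts = groups.by_day[day]
        members = sorted(set().union(*roosts.values()))
        perm = [members[i] for i in rng.permutation(len(members))]
        day_out: dict[str, set] = {}
        pos = 0
        for roost in sorted(roosts):
            size = len(roosts[roost])
            day_out[roost] = set(perm[pos : pos + size])
            pos += size
        out[day] = day_out
    return DailyGroups(by_day=out)


def _shuffle_codes(R: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Within each day (column), permute roost codes among detected individuals."""
    out = R.copy()
    for d in range(R.shape[1]):
        col = out[:, d]
        idx = np.nonzero(col >= 0)[0]
        if len(idx) > 1:
            col[idx] = col[idx[rng.permutation(len(idx))]]
    return out


def _assert_constraints(orig: np.ndarray, perm: np.ndarray) -> None:
    """Detected sets and per-day group-size multisets must be invariant."""
    if (orig >= 0).sum() != (perm >= 0).sum():
        raise AssertionError("permutation changed the total record count")
    for d in range(orig.shape[1]):
        a, b = orig[:, d], perm[:, d]
        if not np.array_equal(a >= 0, b >= 0):
            raise AssertionError(f"permutation changed the detected set on day {d}")
        if not np.array_equal(np.sort(a[a >= 0]), np.sort(b[b >= 0])):
            raise AssertionError(f"permutation changed group sizes on day {d}")


def null_distribution(
    data: RoostingData,
    n_rand: int,
    seed: int,
    store_all: bool = False,
    check_constraints: bool = True,
) -> NullDistribution:
    """Fast-greedy Q of ``n_rand`` independent day-constrained random networks.

    ``store_all=True`` additionally records graph density and clustering
    of each random network (kept for inspection; only Q feeds the test).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    c = compile_data(data)
    n_roosts = len(c.roosts)
    qs = np.empty(n_rand)
    dens = np.empty(n_rand) if store_all else None
    clus = np.empty(n_rand) if store_all else None
    for r in range(n_rand):
        Rp = _shuffle_codes(c.R, rng)
        if check_constraints:
            _assert_constraints(c.R, Rp)
        w = hwi_from_codes(Rp, n_roosts)
        m = AssociationMatrix(ids=list(c.ids), w=w)
        qs[r] = fast_greedy_communities(m).q
        if store_all:
            dens[r] = graph_density(m)
            clus[r] = global_clustering(m) if m.n >= 3 else 0.0
    return NullDistribution(
        q_values=qs, n_rand=n_rand, density_values=dens, clustering_values=clus
    )


def monte_carlo_p(q_obs: float, null: NullDistribution) -> float:
    """Fraction of null modularities >= the observed modularity."""
    if null.n_rand < 1:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(null.q_values >= q_obs) / null.n_rand)
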