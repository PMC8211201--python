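"""Gambit-of-the-group daily grouping and dyadic association indices.

Individuals detected in the same roost on the same day are taken to be
associating (the gambit of the group). From the daily groups each dyad
(A, B) accumulates four counts over the study:

* ``x``    — days A and B were in the same roost,
* ``y_ab`` — days both were detected but in different roosts,
* ``y_a``  — days A was detected and B was not,
* ``y_b``  — days B was detected and A was not.

The half-weight index HWI = x / (x + y_ab + (y_a + y_b)/2) down-weights
days on which only one member of a dyad was seen, which suits systems
with unmonitored refuges; the simple ratio index SRI = x / (x + y_ab +
y_a + y_b) counts them fully. Dyads never co-detected get index 0 (a
true zero edge, not missing data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import RoostingData


@dataclass
class DailyGroups:
    """Per-day partition of the detected individuals into roost groups."""

    by_day: dict[int, dict[str, set]]

    def individuals(self) -> list[str]:
        out: set = set()
        for groups in self.by_day.values():
            for members in groups.values():
                out |= members
        return sorted(out)

    def detected_on(self, day: int) -> set:
        return set().union(*self.by_day[day].values()) if self.by_day.get(day) else set()

    def group_sizes(self, day: int) -> list[int]:
        return sorted(len(m) for m in self.by_day[day].values())


@dataclass
class DyadCounts:
    """Symmetric together/apart day counts for every dyad of ``ids``."""

    ids: list[str]
    x: np.ndarray
    y_ab: np.ndarray
    y_a: np.ndarray
    y_b: np.ndarray

    def for_dyad(self, a: str, b: str) -> tuple[int, int, int, int]:
        i, j = self.ids.index(a), self.ids.index(b)
        return (
            int(self.x[i, j]),
            int(self.y_ab[i, j]),
            int(self.y_a[i, j]),
            int(self.y_b[i, j]),
        )


@dataclass
class AssociationMatrix:
    """Symmetric dyadic index matrix; entries in [0, 1], zero diagonal."""

    ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.ids)
        if self.w.shape != (n, n):
            raise ValueError(f"matrix shape {self.w.shape} does not match {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        return float(self.w[self.ids.index(a), self.ids.index(b)])


# ---------------------------------------------------------------------------
# Compiled array representation (internal fast path)
# ---------------------------------------------------------------------------


@dataclass
class _Compiled:
    """Dense day-by-individual roost-code matrix.

    ``R[i, d]`` is the integer roost code of individual ``i`` on the d-th
    observed day, or -1 if undetected. Columns are the distinct days on
    which any retained individual was detected, in ascending order.
    """

    ids: list[str]
    days: np.ndarray
    R: np.ndarray
    roosts: list[str]


def compile_data(data: RoostingData, ids: list[str] | None = None) -> _Compiled:
    """Convert a record stream to the dense roost-code matrix.

    When ``ids`` is given, records of other individuals are dropped first,
    i.e. counts are computed as if those individuals never existed.
    """
    frame = data.frame
    if ids is None:
        ids = sorted(frame["individual_id"].unique())
    else:
        ids = [str(i) for i in ids]
        frame = frame[frame["individual_id"].isin(set(ids))]
    days = np.sort(frame["day"].unique())
    roosts = sorted(frame["roost_id"].unique())
    id_idx = {v: k for k, v in enumerate(ids)}
    day_idx = {v: k for k, v in enumerate(days.tolist())}
    roost_idx = {v: k for k, v in enumerate(roosts)}
    R = np.full((len(ids), len(days)), -1, dtype=np.int32)
    if len(frame):
        rows = frame["individual_id"].map(id_idx).to_numpy()
        cols = frame["day"].map(day_idx).to_numpy()
        vals = frame["roost_id"].map(roost_idx).to_numpy()
        R[rows, cols] = vals
    return _Compiled(ids=ids, days=days, R=R, roosts=roosts)


def counts_from_codes(R: np.ndarray, n_roosts: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (x, both, n_det): co-roost days, co-detection days, detection days.

    ``x[i, j]`` = days i and j shared a roost; ``both[i, j]`` = days both
    were detected; ``n_det[i]`` = days i was detected. One matrix product
    per roost: x = sum_k M_k M_k^T with M_k the day-indicator of roost k.
    """
    det = (R >= 0)
    n_det = det.sum(axis=1).astype(np.int64)
    d = det.astype(np.float64)
    both = (d @ d.T).astype(np.int64)
    n = R.shape[0]
    x = np.zeros((n, n), dtype=np.int64)
    for k in range(n_roosts):
        m = (R == k).astype(np.float64)
        x += (m @ m.T).astype(np.int64)
    np.fill_diagonal(x, 0)
    np.fill_diagonal(both, 0)
    return x, both, n_det


def _counts_from_compiled(c: _Compiled) -> DyadCounts:
    x, both, n_det = counts_from_codes(c.R, len(c.roosts))
    y_ab = both - x
    y_a = n_det[:, None] - both
    y_b = n_det[None, :] - both
    np.fill_diagonal(y_a, 0)
    np.fill_diagonal(y_b, 0)
    return DyadCounts(ids=c.ids, x=x, y_ab=y_ab, y_a=y_a, y_b=y_b)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def group_by_day(data: RoostingData) -> DailyGroups:
    """Restructure detections into per-day roost groups (no records dropped)."""
    by_day: dict[int, dict[str, set]] = {}
    for ind, day, roost in data.frame.itertuples(index=False, name=None):
        by_day.setdefault(int(day), {}).setdefault(roost, set()).add(ind)
    return DailyGroups(by_day=by_day)


def groups_to_data(groups: DailyGroups) -> RoostingData:
    """Inverse of :func:`group_by_day`."""
    records = [
        (ind, day, roost)
        for day, roosts in groups.by_day.items()
        for roost, members in roosts.items()
        for ind in members
    ]
    return RoostingData.from_records(records)


def dyad_counts(groups: DailyGroups, ids: list[str] | None = None) -> DyadCounts:
    """Together/apart counts for every dyad of ``ids``.

    Individuals outside ``ids`` are ignored entirely, including for the
    y_a / y_b bookkeeping of retained dyads.
    """
    present = groups.individuals()
    if ids is None:
        ids = present
    else:
        ids = [str(i) for i in ids]
        if not set(present) <= set(ids):
            # restriction allowed: drop outsiders
            pass
    return _counts_from_compiled(compile_data(groups_to_data(groups), ids=ids))


def _index_matrix(counts: DyadCounts, denom: np.ndarray) -> AssociationMatrix:
    w = np.zeros_like(denom, dtype=float)
    np.divide(counts.x, denom, out=w, where=denom > 0)
    np.fill_diagonal(w, 0.0)
    return AssociationMatrix(ids=list(counts.ids), w=w)


def half_weight_index(counts: DyadCounts) -> AssociationMatrix:
    """HWI = x / (x + y_ab + (y_a + y_b)/2); zero-denominator dyads get 0."""
    denom = counts.x + counts.y_ab + 0.5 * (counts.y_a + counts.y_b)
    return _index_matrix(counts, denom)


def simple_ratio_index(counts: DyadCounts) -> AssociationMatrix:
    """SRI = x / (x + y_ab + y_a + y_b); zero-denominator dyads get 0."""
    denom = (counts.x + counts.y_ab + counts.y_a + counts.y_b).astype(float)
    return _index_matrix(counts, denom)


def hwi_from_codes(R: np.ndarray, n_roosts: int) -> np.ndarray:
    """Half-weight index straight from a roost-code matrix (fast path).

    Uses the identity x + y_ab + (y_a + y_b)/2 = (n_i + n_j)/2, where n_i
    is the number of days individual i was detected.
    """
    x, _, n_det = counts_from_codes(R, n_roosts)
    denom = 0.5 * (n_det[:, None] + n_det[None, :])
    w = np.zeros_like(denom)
    np.divide(x, denom, out=w, where=denom > 0)
    np.fill_diagonal(w, 0.0)
    return w


def association_matrix(
    data: RoostingData, ids: list[str] | None = None, index: str = "hwi"
) -> AssociationMatrix:
    """One-call pipeline: records -> daily groups -> counts -> index matrix."""
    c = compile_data(data, ids=ids)
    counts = _counts_from_compiled(c)
    if index == "hwi":
        return half_weight_index(counts)
    if index == "sri":
        return simple_ratio_index(counts)
    raise ValueError(f"unknown association index {index!r} (use 'hwi' or 'sri')")
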