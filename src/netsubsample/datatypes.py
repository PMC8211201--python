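"""Shared containers for roosting detection data and network partitions.

The raw observation stream is a long table of daily roost detections:
one row states that one individual was assigned to one roost on one day
(in PIT-tag systems, the last reader hit before sunrise). Everything
downstream — association indices, networks, permutation nulls — is a
function of this table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ("individual_id", "day", "roost_id")


class DataIntegrityError(ValueError):
    """Raised when detection records violate the one-record-per-individual-day rule."""


@dataclass
class RoostingData:
    """Long-format daily roost detections.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``individual_id`` (str), ``day`` (int, abstract day index),
        ``roost_id`` (str). At most one row per (individual, day).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataIntegrityError(f"missing columns: {missing}")
        self.frame = self.frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.frame["individual_id"] = self.frame["individual_id"].astype(str)
        self.frame["roost_id"] = self.frame["roost_id"].astype(str)
        self.frame["day"] = self.frame["day"].astype(np.int64)
        dup = self.frame.duplicated(subset=["individual_id", "day"])
        if dup.any():
            rows = self.frame.loc[dup, ["individual_id", "day"]].head(10)
            raise DataIntegrityError(
                f"duplicate (individual, day) records, e.g.:\n{rows.to_string(index=False)}"
            )

    @classmethod
    def from_records(cls, records) -> "RoostingData":
        """Build from an iterable of (individual_id, day, roost_id) tuples."""
        return cls(pd.DataFrame(list(records), columns=list(COLUMNS)))

    @property
    def records(self) -> list[tuple[str, int, str]]:
        return list(self.frame.itertuples(index=False, name=None))

    @property
    def individuals(self) -> list[str]:
        return sorted(self.frame["individual_id"].unique())

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.frame["day"].unique())

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def restrict(self, ids) -> "RoostingData":
        """Keep only records of the given individuals (order-insensitive)."""
        keep = self.frame["individual_id"].isin(set(map(str, ids)))
        return RoostingData(self.frame.loc[keep])

    def __eq__(self, other) -> bool:
        if not isinstance(other, RoostingData):
            return NotImplemented
        a = self.frame.sort_values(list(COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(COLUMNS)).reset_index(drop=True)
        return a.equals(b)


@dataclass
class Partition:
    """Assignment of individuals to communities, with the modularity it attains.

    ``labels`` maps individual id -> integer community label; ``q`` is the
    (weighted Newman) modularity of this partition on the network it was
    detected on. Labels are arbitrary integers; only the grouping matters.
    """

    labels: dict[str, int]
    q: float = 0.0
    degenerate: bool = False

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def label_array(self, ids) -> np.ndarray:
        return np.array([self.labels[i] for i in ids], dtype=np.int64)


@dataclass
class GlobalMetrics:
    """Global structure summary of one association network."""

    q: float
    n_communities: int
    density: float
    clustering: float

    def as_dict(self) -> dict:
        return {
            "q": self.q,
            "n_communities": self.n_communities,
            "density": self.density,
            "clustering": self.clustering,
        }
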