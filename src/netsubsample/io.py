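"""File formats, run configuration, and metadata sidecars.

Detection data travel as long-format CSV with header
``individual_id,day,roost_id``; days are abstract integer indices (a
loader option maps ISO dates to indices since the analysis needs only
day identity). Association matrices are square CSVs with ids as header
and row names. Every artifact a run writes gets a JSON sidecar stating
the configuration hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import AssociationMatrix
from .datatypes import COLUMNS, DataIntegrityError, RoostingData
from .generator import GeneratorConfig


def read_roosting_csv(path: str | Path, parse_dates: bool = False) -> RoostingData:
    """Load and validate a detection CSV.

    With ``parse_dates``, the ``day`` column is read as ISO dates and
    converted to integer indices counted from the earliest date.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"individual_id": str, "roost_id": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DataIntegrityError(f"{path}: missing columns {missing}")
    if parse_dates:
        dates = pd.to_datetime(frame["day"])
        frame["day"] = (dates - dates.min()).dt.days
    else:
        try:
            frame["day"] = frame["day"].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise DataIntegrityError(
                f"{path}: unparseable day values (use parse_dates for ISO dates): {exc}"
            ) from exc
    return RoostingData(frame)


def write_roosting_csv(data: RoostingData, path: str | Path) -> None:
    data.frame.to_csv(path, index=False)


def write_association_csv(m: AssociationMatrix, path: str | Path) -> None:
    pd.DataFrame(m.w, index=m.ids, columns=m.ids).to_csv(path)


def read_association_csv(path: str | Path) -> AssociationMatrix:
    frame = pd.read_csv(path, index_col=0)
    return AssociationMatrix(ids=[str(c) for c in frame.columns], w=frame.to_numpy(dtype=float))


def write_graphml(m: AssociationMatrix, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(m.ids)
    n = m.n
    for i in range(n):
        for j in range(i + 1, n):
            if m.w[i, j] > 0:
                g.add_edge(m.ids[i], m.ids[j], weight=float(m.w[i, j]))
    nx.write_graphml(g, str(path))


def load_generator_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh) or {})


def save_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


PROFILES = {"fast": {"n_rand": 200, "n_boot": 200}, "full": {"n_rand": 1000, "n_boot": 1000}}


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_path: str | None = None  # load detections instead of generating
    min_days: int = 40
    obs_cap: int = 40
    individuals_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 35, 50, 75, 99)
    obs_grid: tuple[int, ...] = (1, 5, 10, 15, 20, 30, 40)
    n_reps: int = 100
    n_rand: int = 1000
    n_boot: int = 1000
    n_repeat_rcom: int = 10
    seed: int = 0
    profile: str = "full"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; use one of {sorted(PROFILES)}")
        self.individuals_grid = tuple(int(v) for v in self.individuals_grid)
        self.obs_grid = tuple(int(v) for v in self.obs_grid)
        self.seed = int(self.seed)

    def effective(self, key: str) -> int:
        """n_rand / n_boot after applying the fast/full profile cap."""
        return min(getattr(self, key), PROFILES[self.profile][key])

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "input_path", "min_days", "obs_cap", "n_reps", "n_rand", "n_boot",
            "n_repeat_rcom", "seed", "profile", "out_dir",
        )}
        d["generator"] = self.generator.to_dict()
        d["individuals_grid"] = list(self.individuals_grid)
        d["obs_grid"] = list(self.obs_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and d["generator"] is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        return cls(**d)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: RunConfig | GeneratorConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_metadata(path: str | Path, config, seed: int) -> None:
    """JSON sidecar declaring the config hash and master seed of an artifact."""
    meta = {"config_hash": config_hash(config), "master_seed": int(seed)}
    with open(Path(path).with_suffix(Path(path).suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
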