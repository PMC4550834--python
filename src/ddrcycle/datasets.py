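"""Observation datasets and their on-disk formats.

A dataset is a flat table of observations — one row per replicate
measurement — plus a mapping from condition id to the exposure schedule
and seed population that produced it.  The CSV schema is::

    condition_id, readout, time_h, value, sd, n

where ``sd``/``n`` describe the replicate group the row belongs to.
Conditions and generating-truth metadata travel in YAML sidecars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .cell_cycle import CellCycleState, ExposureSchedule

logger = logging.getLogger(__name__)

DATASET_COLUMNS = ("condition_id", "readout", "time_h", "value", "sd", "n")
READOUT_KINDS = ("gammaH2AX_pct", "gammaH2AX_ir_pct", "cell_count", "tumor_volume")


@dataclass(frozen=True)
class Observation:
    condition_id: str
    readout: str
    time_h: float
    value: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.readout not in READOUT_KINDS:
            raise ValueError(f"unknown readout kind {self.readout!r}")
        if self.time_h < 0:
            raise ValueError(f"observation time must be >= 0 h, got {self.time_h!r}")
        if not np.isfinite(self.value):
            raise ValueError("observation value must be finite")
        if self.sd < 0 or self.n < 1:
            raise ValueError("replicate sd must be >= 0 and n >= 1")


@dataclass(frozen=True)
class Condition:
    """In vitro condition: exposure schedule plus the seeded population."""

    schedule: ExposureSchedule
    initial_state: CellCycleState


class Dataset:
    """Validated observation table with condition mapping and metadata."""

    def __init__(self, df: pd.DataFrame, conditions: dict, metadata: dict | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        df = df.loc[:, list(DATASET_COLUMNS)].reset_index(drop=True)
        self._validate(df)
        unknown = set(df["condition_id"]) - set(conditions)
        if unknown:
            raise ValueError(f"observations reference unknown conditions: {sorted(unknown)}")
        self.df = df
        self.conditions = dict(conditions)
        self.metadata = dict(metadata or {})

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for col in ("time_h", "value", "sd", "n"):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[numeric.isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric {col!r} in dataset rows {list(bad + 2)} (1-based incl. header)"
                )
            df[col] = numeric
        bad = df.index[df["time_h"] < 0]
        if len(bad):
            raise ValueError(f"negative time_h in dataset rows {list(bad + 2)} (1-based incl. header)")
        bad = df.index[~df["readout"].isin(READOUT_KINDS)]
        if len(bad):
            raise ValueError(
                f"unknown readout kind in dataset rows {list(bad + 2)}; "
                f"allowed: {READOUT_KINDS}"
            )
        bad = df.index[(df["sd"] < 0) | (df["n"] < 1)]
        if len(bad):
            raise ValueError(f"invalid sd/n in dataset rows {list(bad + 2)}")

    def __len__(self) -> int:
        return len(self.df)

    def observations(self) -> Iterator[Observation]:
        for row in self.df.itertuples(index=False):
            yield Observation(
                condition_id=row.condition_id, readout=row.readout,
                time_h=float(row.time_h), value=float(row.value),
                sd=float(row.sd), n=int(row.n),
            )


def concat_datasets(datasets: list) -> Dataset:
    """Merge datasets with disjoint condition ids into one table."""
    if not datasets:
        raise ValueError("need at least one dataset")
    conditions: dict = {}
    for ds in datasets:
        clash = set(conditions) & set(ds.conditions)
        if clash:
            raise ValueError(f"condition ids clash across datasets: {sorted(clash)}")
        conditions.update(ds.conditions)
    df = pd.concat([ds.df for ds in datasets], ignore_index=True)
    metadata = dict(datasets[0].metadata)
    metadata["designs"] = [ds.metadata.get("design") for ds in datasets]
    return Dataset(df, conditions, metadata)


def _schedule_to_config(schedule: ExposureSchedule) -> dict:
    return {
        "segments": [[t, c] for t, c in schedule.segments],
        "ir_events": [[t, d] for t, d in schedule.ir_events],
    }


def _schedule_from_config(cfg: dict) -> ExposureSchedule:
    return ExposureSchedule(
        segments=tuple(tuple(seg) for seg in cfg.get("segments", [[0.0, 0.0]])),
        ir_events=tuple(tuple(ev) for ev in cfg.get("ir_events", [])),
    )


def conditions_to_config(conditions: dict) -> dict:
    out = {}
    for cid, cond in conditions.items():
        out[cid] = {
            **_schedule_to_config(cond.schedule),
            "initial": {k: float(v) for k, v in
                        zip(("g1", "s", "sd", "g2m", "g1ir", "sir", "g2mir"),
                            cond.initial_state.as_array())},
        }
    return out


def conditions_from_config(cfg: dict) -> dict:
    out = {}
    for cid, c in cfg.items():
        out[cid] = Condition(
            schedule=_schedule_from_config(c),
            initial_state=CellCycleState(**c.get("initial", {})),
        )
    return out


def write_dataset(dataset: Dataset, path, conditions_path=None, metadata_path=None) -> None:
    """Write the observation CSV plus optional conditions/metadata YAML sidecars."""
    path = Path(path)
    dataset.df.to_csv(path, index=False)
    if conditions_path is not None:
        with open(conditions_path, "w") as fh:
            yaml.safe_dump(conditions_to_config(dataset.conditions), fh, sort_keys=True)
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            yaml.safe_dump(dataset.metadata, fh, sort_keys=True)


def load_dataset(path, conditions_path=None, metadata_path=None) -> Dataset:
    """Load and validate a dataset CSV (+ YAML sidecars); errors name the row."""
    df = pd.read_csv(path)
    if len(df) == 0:
        logger.warning("dataset %s is empty", path)
    conditions: dict = {}
    if conditions_path is not None:
        with open(conditions_path) as fh:
            conditions = conditions_from_config(yaml.safe_load(fh) or {})
    else:
        # Without a conditions file, register bare placeholders so the table loads.
        conditions = {
            cid: Condition(ExposureSchedule.constant(0.0), CellCycleState(g1=1.0))
            for cid in df.get("condition_id", pd.Series(dtype=str)).unique()
        }
    metadata: dict = {}
    if metadata_path is not None:
        with open(metadata_path) as fh:
            metadata = yaml.safe_load(fh) or {}
    return Dataset(df, conditions, metadata)
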