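"""Tabular readers/writers, dataset preprocessing and fixture generation.

Datasets persist as comma-separated text with a header row; RTs are stored
in seconds with six decimals and correctness as 0/1.  Millisecond inputs are
converted to seconds at this I/O edge only — everything in memory is in
seconds.  Parameter sets and run metadata round-trip through flat YAML.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import ModelParams, params_from_dict, params_to_dict
from .simulate import RTDataset, simulate_dataset

__all__ = [
    "SchemaError",
    "StudySchema",
    "read_rt_table",
    "write_rt_table",
    "filter_anticipatory",
    "label_phases",
    "generate_fixture",
    "load_params",
    "save_params",
    "load_yaml",
    "save_yaml",
    "file_sha256",
]

logger = logging.getLogger(__name__)

MIN_RT_DEFAULT = 0.180  # s; anticipatory-response cutoff


class SchemaError(ValueError):
    """The file does not conform to the declared study schema."""


@dataclass
class StudySchema:
    """Column names, declared condition factors and the RT unit of a table."""

    participant: str = "participant"
    rt: str = "rt"
    correct: str = "correct"
    factors: Dict[str, Sequence] = field(default_factory=dict)
    rt_unit: str = "s"  # "s" | "ms"
    block: Optional[str] = None

    def __post_init__(self):
        if self.rt_unit not in ("s", "ms"):
            raise SchemaError(f"rt unit must be 's' or 'ms', got {self.rt_unit!r}")


def read_rt_table(path, schema: Optional[StudySchema] = None) -> RTDataset:
    """Read and validate a trial table; malformed rows are named by line.

    Line numbers in error messages count the header as line 1.
    """
    schema = schema or StudySchema()
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    required = [schema.participant, schema.rt, schema.correct] + list(schema.factors)
    if schema.block:
        required.append(schema.block)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    rt = pd.to_numeric(df[schema.rt], errors="coerce")
    bad = df.index[rt.isna() | (rt <= 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise SchemaError(
            f"{path}: {len(bad)} row(s) with missing/non-positive RT "
            f"(first lines: {lines})"
        )
    if schema.rt_unit == "ms":
        rt = rt / 1000.0

    correct_raw = df[schema.correct]
    valid = correct_raw.isin([0, 1, True, False, "0", "1"])
    if not valid.all():
        lines = [int(i) + 2 for i in df.index[~valid][:10]]
        raise SchemaError(f"{path}: unparseable correctness values (first lines: {lines})")

    out = pd.DataFrame(
        {
            "participant": df[schema.participant].astype(str),
            "rt": rt.astype(float),
            "correct": correct_raw.astype(int).astype(bool),
        }
    )
    for factor, levels in schema.factors.items():
        col = df[factor]
        if levels:
            unknown = set(col.unique()) - set(levels)
            if unknown:
                raise SchemaError(
                    f"{path}: factor {factor!r} has undeclared level(s) {sorted(map(str, unknown))}"
                )
        out[factor] = col
    if schema.block:
        out["block"] = df[schema.block]
    return RTDataset(trials=out, meta={"source": str(path)}).validate()


def write_rt_table(data: RTDataset, path) -> None:
    """Write trials as CSV: rt in seconds (6 decimals), correctness as 0/1."""
    df = data.trials.copy()
    df["rt"] = df["rt"].map(lambda v: f"{v:.6f}")
    df["correct"] = df["correct"].astype(int)
    df.to_csv(path, index=False)


def filter_anticipatory(data: RTDataset, min_rt: float = MIN_RT_DEFAULT) -> RTDataset:
    """Drop trials with RT strictly below ``min_rt`` (default 180 ms).

    "Below" is strict, so a trial at exactly the cutoff is retained.
    """
    if min_rt < 0:
        raise ValueError(f"min_rt must be >= 0, got {min_rt}")
    keep = data.trials["rt"] >= min_rt
    removed = int((~keep).sum())
    if removed:
        logger.info("filtered %d anticipatory trial(s) below %.3f s", removed, min_rt)
    meta = dict(data.meta, n_filtered_anticipatory=removed)
    return RTDataset(
        trials=data.trials[keep].reset_index(drop=True),
        n_undecided=data.n_undecided,
        meta=meta,
    )


def label_phases(data: RTDataset, block_column: str = "block") -> RTDataset:
    """Add an early/late ``phase`` factor split at the block-sequence midpoint.

    The block sequence is the ordered set of block labels across the whole
    dataset; the first half is labelled ``early``, the second ``late``.
    Participants missing any block are flagged and excluded (with a logged
    warning), since they lack trials in a full half of the design.
    """
    df = data.trials
    if block_column not in df.columns:
        raise ValueError(f"no block column {block_column!r} in the dataset")
    blocks = sorted(df[block_column].unique())
    if len(blocks) < 2:
        raise ValueError("need at least two blocks to define early/late phases")
    half = len(blocks) // 2
    early = set(blocks[:half])
    expected = set(blocks)
    flagged = []
    for pid, sub in df.groupby("participant", sort=False):
        if set(sub[block_column].unique()) != expected:
            flagged.append(pid)
    if flagged:
        logger.warning(
            "excluding participant(s) with incomplete block coverage: %s", flagged
        )
    out = df[~df["participant"].isin(flagged)].copy()
    out["phase"] = np.where(out[block_column].isin(early), "early", "late")
    counts = out["phase"].value_counts().to_dict()
    meta = dict(
        data.meta,
        phase_counts={k: int(v) for k, v in counts.items()},
        excluded_participants=list(flagged),
        early_blocks=sorted(early),
    )
    return RTDataset(trials=out.reset_index(drop=True), n_undecided=data.n_undecided, meta=meta)


def generate_fixture(
    params_by_condition: Dict[str, ModelParams],
    n_trials_per_condition: int,
    seed: int,
    out_dir,
    factor: str = "stimulus",
    participant: str = "p01",
    dt: float = 5e-4,
    t_max: float = 5.0,
):
    """Write a synthetic study dataset plus its ground-truth sidecar.

    One simulated block of ``n_trials_per_condition`` trials per condition
    level, concatenated into ``dataset.csv``; the generating parameters,
    seed and undecided counts go to ``dataset.ground_truth.yaml``.  The
    dataset round-trips through :func:`read_rt_table`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).generate_state(len(params_by_condition))
    frames, truth = [], {"seed": int(seed), "factor": factor, "conditions": {}}
    for (level, params), sub_seed in zip(params_by_condition.items(), children):
        ds = simulate_dataset(
            params,
            n_trials_per_condition,
            dt=dt,
            t_max=t_max,
            seed=int(sub_seed & 0x7FFFFFFF),
            participant=participant,
            conditions={factor: level},
        )
        frames.append(ds.trials)
        truth["conditions"][str(level)] = {
            "params": params_to_dict(params),
            "n_trials": n_trials_per_condition,
            "n_undecided": ds.n_undecided,
        }
    combined = RTDataset(trials=pd.concat(frames, ignore_index=True))
    data_path = out_dir / "dataset.csv"
    sidecar_path = out_dir / "dataset.ground_truth.yaml"
    write_rt_table(combined, data_path)
    save_yaml(truth, sidecar_path)
    return data_path, sidecar_path


# -- structured text configs ------------------------------------------------

def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_params(path) -> ModelParams:
    """Read a parameter set from a flat key/value YAML file."""
    return params_from_dict(load_yaml(path))


def save_params(params: ModelParams, path) -> None:
    save_yaml(params_to_dict(params), path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
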