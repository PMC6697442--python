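"""Reading and writing the pipeline's text formats.

Trajectories travel as tidy TSV with columns ``condition, replicate,
time_h, species, abundance_cfu_per_ml`` (plus an optional ``censored``
0/1 column); parameters and ground-truth records as YAML documents with
explicit species ordering.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .model import GLVModelError, GLVParameters, Trajectory
from .synth import GroundTruthRecord

__all__ = [
    "REQUIRED_COLUMNS",
    "DataFormatError",
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_frame",
    "read_parameters",
    "write_parameters",
    "read_ground_truth",
    "write_ground_truth",
]

REQUIRED_COLUMNS = (
    "condition",
    "replicate",
    "time_h",
    "species",
    "abundance_cfu_per_ml",
)


class DataFormatError(ValueError):
    """Malformed input data file."""


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Tidy long-format DataFrame, one row per (condition, replicate, time,
    species) observation."""
    rows = []
    any_cens = any(t.censored is not None for t in trajectories)
    for t in trajectories:
        for k, time in enumerate(t.times):
            for i, sp in enumerate(t.species):
                row = {
                    "condition": t.condition,
                    "replicate": t.replicate,
                    "time_h": float(time),
                    "species": sp,
                    "abundance_cfu_per_ml": float(t.abundances[k, i]),
                }
                if any_cens:
                    row["censored"] = int(
                        bool(t.censored[k, i]) if t.censored is not None else 0
                    )
                for key, vals in t.extra.items():
                    row[key] = vals[k, i]
                rows.append(row)
    return pd.DataFrame(rows)


def write_trajectories(
    trajectories: Sequence[Trajectory], path: Union[str, Path]
) -> None:
    df = trajectories_to_frame(trajectories)
    df.to_csv(path, sep="\t", index=False)


def read_trajectories(path: Union[str, Path]) -> list[Trajectory]:
    """Parse a tidy TSV into trajectories (one per condition x replicate).

    Species ordering follows first appearance in the file; unknown columns
    are preserved on each trajectory's ``extra`` mapping.  Missing columns,
    non-numeric or negative abundances, and duplicate
    (condition, replicate, time, species) rows are rejected with the
    offending row number (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"condition": str, "species": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")
    ab = pd.to_numeric(df["abundance_cfu_per_ml"], errors="coerce")
    bad = np.flatnonzero(ab.isna().to_numpy())
    if bad.size:
        raise DataFormatError(
            f"{path}: non-numeric abundance at row {bad[0] + 1}"
        )
    neg = np.flatnonzero((ab < 0).to_numpy())
    if neg.size:
        raise DataFormatError(f"{path}: negative abundance at row {neg[0] + 1}")
    df["abundance_cfu_per_ml"] = ab
    dup = df.duplicated(
        subset=["condition", "replicate", "time_h", "species"], keep="first"
    )
    if dup.any():
        raise DataFormatError(
            f"{path}: duplicate (condition, replicate, time, species) at row "
            f"{int(np.flatnonzero(dup.to_numpy())[0]) + 1}"
        )
    species = tuple(dict.fromkeys(df["species"]))
    extra_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c != "censored"
    ]
    has_cens = "censored" in df.columns
    trajectories = []
    # preserve file order of (condition, replicate) groups
    keys = list(dict.fromkeys(zip(df["condition"], df["replicate"])))
    for cond, rep in keys:
        sub = df[(df["condition"] == cond) & (df["replicate"] == rep)]
        times = np.sort(sub["time_h"].unique())
        abund = np.full((times.size, len(species)), np.nan)
        cens = np.zeros((times.size, len(species)), dtype=bool)
        extra = {c: np.full((times.size, len(species)), np.nan) for c in extra_cols}
        t_idx = {t: k for k, t in enumerate(times)}
        s_idx = {s: i for i, s in enumerate(species)}
        for _, row in sub.iterrows():
            k, i = t_idx[row["time_h"]], s_idx[row["species"]]
            abund[k, i] = row["abundance_cfu_per_ml"]
            if has_cens:
                cens[k, i] = bool(row["censored"])
            for c in extra_cols:
                extra[c][k, i] = row[c]
        if np.isnan(abund).any():
            raise DataFormatError(
                f"{path}: condition {cond!r} replicate {rep} is missing "
                "observations for some (time, species) combinations"
            )
        try:
            trajectories.append(
                Trajectory(
                    times=times,
                    abundances=abund,
                    species=species,
                    condition=cond,
                    replicate=int(rep),
                    censored=cens if has_cens else None,
                    extra=extra,
                )
            )
        except GLVModelError as exc:
            raise DataFormatError(f"{path}: {exc}") from exc
    return trajectories


# ---------------------------------------------------------------------------
# YAML documents
# ---------------------------------------------------------------------------


def write_parameters(params: GLVParameters, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def read_parameters(path: Union[str, Path]) -> GLVParameters:
    return GLVParameters.from_dict(yaml.safe_load(Path(path).read_text()))


def write_ground_truth(record: GroundTruthRecord, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(record.to_dict(), sort_keys=False))


def read_ground_truth(path: Union[str, Path]) -> GroundTruthRecord:
    return GroundTruthRecord.from_dict(yaml.safe_load(Path(path).read_text()))
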