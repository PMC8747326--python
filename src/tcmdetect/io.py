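"""Readers and writers for the pipeline's CSV/JSON artifacts.

Formats
-------
Session CSV
    ``time_s,s1_ax,s1_ay,s1_az,s2_ax,...,s3_az,marker`` — one row per
    sample; the marker column is a 0/1 impulse train (1 on push-button
    rows).  One file per (subject, exercise, category, set), named
    ``<subject>_<exercise>_<category>_set<k>.csv``; a ``manifest.csv``
    lists file, subject, exercise, category, set, side.
Averaged-set CSV
    ``norm_time_pct`` plus the 9 channel columns; an ``index.csv`` with the
    per-set metadata sits next to the files.
Feature-matrix CSV
    ``subject_id,category,set_index`` plus the z-scored feature columns; a
    JSON sidecar records exercise, mode and the per-column raw mean/SD used
    for z-scoring, so the raw values are recoverable.

Floats are written with 17 significant digits, which round-trips IEEE
doubles exactly.
"""

from __future__ import annotations

import json
import hashlib
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import AveragedSet
from .features import FeatureMatrix
from .synthetic import CHANNEL_NAMES, SessionRecording

__all__ = [
    "write_session_csv",
    "read_session_csv",
    "write_cohort",
    "read_cohort",
    "write_averaged_sets",
    "read_averaged_sets",
    "write_feature_matrix",
    "read_feature_matrix",
    "sha256_file",
]

_FLOAT_FMT = "%.17g"
_SESSION_RE = re.compile(r"^(?P<subject>[^_]+)_(?P<exercise>.+)_(?P<category>CPE|TCM)_set(?P<set>\d+)\.csv$")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# -- sessions ---------------------------------------------------------------

def write_session_csv(rec: SessionRecording, path) -> Path:
    path = Path(path)
    rec.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_session_csv(path, subject_id=None, exercise=None, category=None, set_index=None) -> SessionRecording:
    """Read a session CSV; metadata defaults to the filename convention."""
    path = Path(path)
    if None in (subject_id, exercise, category, set_index):
        m = _SESSION_RE.match(path.name)
        if m is None:
            raise ValueError(
                f"cannot infer session metadata from filename {path.name!r}; "
                "pass subject_id/exercise/category/set_index explicitly"
            )
        subject_id = subject_id or m["subject"]
        exercise = exercise or m["exercise"]
        category = category or m["category"]
        set_index = set_index if set_index is not None else int(m["set"])
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_s", *CHANNEL_NAMES, "marker"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected session CSV columns in {path}: {list(df.columns)}")
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 200.0
    return SessionRecording(
        subject_id=subject_id,
        exercise=exercise,
        category=category,
        set_index=set_index,
        sampling_rate=float(round(rate, 6)),
        channels=df[list(CHANNEL_NAMES)].to_numpy().T,
        markers=np.flatnonzero(df["marker"].to_numpy() == 1),
    )


def write_cohort(recordings: Sequence[SessionRecording], manifest: pd.DataFrame, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, file in zip(recordings, manifest["file"]):
        write_session_csv(rec, out_dir / file)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_cohort(data_dir) -> tuple[list[SessionRecording], pd.DataFrame]:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv", keep_default_na=False)
    recs = [
        read_session_csv(
            data_dir / row["file"],
            subject_id=row["subject_id"],
            exercise=row["exercise"],
            category=row["category"],
            set_index=int(row["set_index"]),
        )
        for _, row in manifest.iterrows()
    ]
    return recs, manifest


# -- averaged sets ----------------------------------------------------------

def write_averaged_sets(sets: Sequence[AveragedSet], out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for aset in sets:
        name = f"{aset.subject_id}_{aset.exercise}_{aset.category}_set{aset.set_index}_avg.csv"
        df = pd.DataFrame({"norm_time_pct": aset.norm_time_pct})
        for i, ch in enumerate(CHANNEL_NAMES):
            df[ch] = aset.channels[i]
        df.to_csv(out_dir / name, index=False, float_format=_FLOAT_FMT)
        rows.append(
            {
                "file": name,
                "subject_id": aset.subject_id,
                "exercise": aset.exercise,
                "category": aset.category,
                "set_index": aset.set_index,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "index.csv", index=False)
    return out_dir


def read_averaged_sets(data_dir) -> list[AveragedSet]:
    data_dir = Path(data_dir)
    index = pd.read_csv(data_dir / "index.csv")
    sets = []
    for _, row in index.iterrows():
        df = pd.read_csv(data_dir / row["file"], float_precision="round_trip")
        sets.append(
            AveragedSet(
                subject_id=row["subject_id"],
                exercise=row["exercise"],
                category=row["category"],
                set_index=int(row["set_index"]),
                channels=df[list(CHANNEL_NAMES)].to_numpy().T,
            )
        )
    return sets


# -- feature matrix ---------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path) -> Path:
    path = Path(path)
    out = pd.concat([matrix.meta.reset_index(drop=True), matrix.X.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "exercise": matrix.exercise,
        "mode": matrix.mode,
        "scale": {
            name: {"mean": float(matrix.scale.loc[name, "mean"]),
                   "sd": float(matrix.scale.loc[name, "sd"])}
            for name in matrix.scale.index
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    meta = df[["subject_id", "category", "set_index"]].copy()
    X = df.drop(columns=["subject_id", "category", "set_index"])
    scale = pd.DataFrame(
        {
            "mean": {k: v["mean"] for k, v in sidecar["scale"].items()},
            "sd": {k: v["sd"] for k, v in sidecar["scale"].items()},
        }
    ).loc[list(X.columns)]
    sd_safe = scale["sd"].replace(0.0, 1.0)
    raw = X * sd_safe + scale["mean"]
    return FeatureMatrix(
        exercise=sidecar["exercise"],
        mode=sidecar["mode"],
        meta=meta,
        raw=raw,
        X=X,
        scale=scale,
    )
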