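"""Tilt angles, statistical features and the z-scored feature matrix.

From every averaged set trace the pipeline derives, per acceleration channel,
five statistics — root mean square (aRMS), maximum, variance, skewness and
kurtosis — plus, from the gravity-derived tilt angle of each sensor, the
tilt RMS (phiRMS) and the maxima of the pairwise tilt differences between
the adjacent sensors, max(dphi_1,2) and max(dphi_2,3).

The tilt angle is the angle between the sensor's Z axis and gravity,

    phi = arccos(A_Z / sqrt(A_X^2 + A_Y^2 + A_Z^2)),  phi in [0, 180] deg,

which is exact while the movement is slow enough for the measured
acceleration to be dominated by gravity.

All moments are population moments (divide by N); kurtosis is raw
(a normal distribution gives 3, not 0).  Each feature column is z-scored
over all rows of the matrix with the population SD, z = (n - mean) / sd.

Full mode yields 50 features (5 stats x 9 channels + phiRMS_1..3 +
maxdphi_1_2 + maxdphi_2_3); single-sensor mode yields 16 (5 stats x 3 axes
+ phiRMS of that sensor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import AveragedSet

__all__ = [
    "tilt_angle",
    "max_delta_tilt",
    "stat_features",
    "feature_names",
    "FeatureMatrix",
    "build_feature_matrix",
    "MODES",
]

MODES = ("all", "s1", "s2", "s3")

_STATS = ("aRMS", "max", "var", "skew", "kurt")
_CHANNELS = tuple(f"{ax}{s}" for s in (1, 2, 3) for ax in ("X", "Y", "Z"))

#: a set is rejected when more than this fraction of tilt samples is invalid
MAX_INVALID_FRACTION = 0.01


def tilt_angle(ax, ay, az):
    """Tilt angle (degrees) between the sensor Z axis and gravity.

    Element-wise over series.  A zero-norm sample has no defined direction:
    scalar input raises, array input yields NaN for the affected samples
    (treated as missing downstream).
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    scalar = norm.ndim == 0
    if scalar:
        if norm == 0:
            raise ValueError("zero-norm acceleration vector: tilt undefined")
        return float(np.degrees(np.arccos(np.clip(az / norm, -1.0, 1.0))))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norm > 0, az / np.where(norm > 0, norm, 1.0), np.nan)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def max_delta_tilt(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """Maximum over time of the signed tilt difference ``phi_a - phi_b``."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError("tilt series must have equal length")
    return float(np.nanmax(phi_a - phi_b))


def stat_features(x) -> dict[str, float]:
    """Population statistics of one series: aRMS, max, variance, skew, kurt.

    Raw (non-excess) kurtosis; a constant series has undefined skewness and
    kurtosis, which are reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("series must contain at least 2 valid samples")
    mean = x.mean()
    var = float(np.mean((x - mean) ** 2))
    out = {
        "aRMS": float(np.sqrt(np.mean(x**2))),
        "max": float(x.max()),
        "var": var,
    }
    if var == 0.0:
        warnings.warn("constant series: skewness/kurtosis undefined, set to 0")
        out["skew"] = 0.0
        out["kurt"] = 0.0
    else:
        sd = np.sqrt(var)
        out["skew"] = float(np.mean((x - mean) ** 3) / sd**3)
        out["kurt"] = float(np.mean((x - mean) ** 4) / sd**4)
    return out


def feature_names(mode: str = "all") -> list[str]:
    """Stable feature vocabulary for a mode (50 names full, 16 per sensor)."""
    if mode == "all":
        names = [f"{st}_{ch}" for ch in _CHANNELS for st in _STATS]
        names += ["phiRMS_1", "phiRMS_2", "phiRMS_3", "maxdphi_1_2", "maxdphi_2_3"]
        return names
    if mode in ("s1", "s2", "s3"):
        s = int(mode[1])
        chans = [f"{ax}{s}" for ax in ("X", "Y", "Z")]
        return [f"{st}_{ch}" for ch in chans for st in _STATS] + [f"phiRMS_{s}"]
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _set_features(aset: AveragedSet) -> dict[str, float]:
    feats: dict[str, float] = {}
    tilts = {}
    for s in (1, 2, 3):
        block = aset.channels[3 * (s - 1) : 3 * s]
        phi = tilt_angle(block[0], block[1], block[2])
        invalid = np.isnan(phi).mean()
        if invalid > MAX_INVALID_FRACTION:
            raise ValueError(
                f"set {aset.subject_id}/{aset.exercise}/{aset.category}/"
                f"{aset.set_index}: {invalid:.1%} invalid tilt samples on sensor {s}"
            )
        tilts[s] = phi
        for ax_i, ax in enumerate(("X", "Y", "Z")):
            stats = stat_features(block[ax_i])
            for st in _STATS:
                feats[f"{st}_{ax}{s}"] = stats[st]
        valid = phi[~np.isnan(phi)]
        feats[f"phiRMS_{s}"] = float(np.sqrt(np.mean(valid**2)))
    feats["maxdphi_1_2"] = max_delta_tilt(tilts[1], tilts[2])
    feats["maxdphi_2_3"] = max_delta_tilt(tilts[2], tilts[3])
    return feats


@dataclass
class FeatureMatrix:
    """Z-scored feature matrix of one exercise.

    ``meta`` holds (subject_id, category, set_index) per row, ``raw`` the
    unscaled features, ``X`` the z-scored values, and ``scale`` the
    per-column mean/SD used for scaling (population SD over all rows).
    """

    exercise: str
    mode: str
    meta: pd.DataFrame
    raw: pd.DataFrame
    X: pd.DataFrame
    scale: pd.DataFrame  # index: feature, columns: mean, sd

    @property
    def y(self) -> np.ndarray:
        return self.meta["category"].to_numpy(dtype=object)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def rescaled(self, train_mask: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Leakage-free variant: z-score train and test with train statistics."""
        train_mask = np.asarray(train_mask, dtype=bool)
        tr = self.raw.loc[train_mask]
        mean = tr.mean(axis=0)
        sd = tr.std(axis=0, ddof=0).replace(0.0, 1.0)
        return (self.raw.loc[train_mask] - mean) / sd, (self.raw.loc[~train_mask] - mean) / sd


def _zscore(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    degenerate = sd[sd == 0.0].index.tolist()
    if degenerate:
        warnings.warn(f"constant feature columns z-scored to 0: {degenerate}")
    sd_safe = sd.replace(0.0, 1.0)
    X = (raw - mean) / sd_safe
    scale = pd.DataFrame({"mean": mean, "sd": sd})
    return X, scale


def build_feature_matrix(sets: Sequence[AveragedSet], mode: str = "all") -> FeatureMatrix:
    """Compute the feature matrix of one exercise from its averaged sets."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    sets = list(sets)
    if len(sets) == 0:
        raise ValueError("at least one averaged set is required")
    exercises = {s.exercise for s in sets}
    if len(exercises) > 1:
        raise ValueError(f"mixed exercises in one matrix: {sorted(exercises)}")
    names = feature_names(mode)
    rows = []
    meta_rows = []
    for aset in sets:
        feats = _set_features(aset)
        rows.append({k: feats[k] for k in names})
        meta_rows.append(
            {
                "subject_id": aset.subject_id,
                "category": aset.category,
                "set_index": aset.set_index,
            }
        )
    raw = pd.DataFrame(rows, columns=names)
    meta = pd.DataFrame(meta_rows)
    X, scale = _zscore(raw)
    return FeatureMatrix(
        exercise=exercises.pop(), mode=mode, meta=meta, raw=raw, X=X, scale=scale
    )
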