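"""Assemble raw sensor frames into 3D movement trajectories.

The webcam contributes the transverse centroid (u, v) in pixels and the
ultrasonic array the longitudinal range z in cm; the two live on very
different scales, so model inputs are decorrelated and whitened (ZCA)
with statistics fitted on training data only.

Pipeline per event: fuse the three ultrasonic channels into one range,
carry the face centroid through tracking dropouts, differentiate to get
per-axis speeds, then window to the 30 retained samples (raw 1-based
indices 3..32) that exclude the error-prone lead-in and lead-out frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegenerateCovarianceError, MissingDataError,
                     ShortEventError, ConfigurationError)

#: retained raw samples, 1-based inclusive: the 3rd through the 32nd
WINDOW_FIRST_1BASED = 3
WINDOW_SIZE = 30
MIN_RAW_POINTS = 33

FEATURE_NAMES = ("x", "y", "z", "speed")

TRAJECTORY_CSV_COLUMNS = [
    "event_id", "t", "x", "y", "z", "vx", "vy", "vz", "speed", "stage",
]


def fuse_ranges(readings, valid, previous: float | None = None,
                ) -> tuple[float, bool]:
    """Fuse the three ultrasonic channels into one longitudinal range.

    Returns ``(fused_cm, held)``.  The fused value is the median of the
    valid readings; if any valid reading decreased relative to the
    previous fused value — the subject is approaching the module — only
    the decreasing readings enter the median (they are the principal
    signals).  With no valid reading the previous fused value is held.
    """
    readings = np.asarray(readings, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    usable = readings[valid]
    if usable.size == 0:
        if previous is None:
            raise MissingDataError("no valid ultrasonic reading and no history")
        return float(previous), True
    if previous is not None:
        approaching = usable[usable < previous]
        if approaching.size > 0:
            usable = approaching
    return float(np.median(usable)), False


def estimate_speeds(t, x, y, z) -> dict[str, np.ndarray]:
    """Per-point speeds: central differences interior, one-sided at ends.

    ``speed`` is the Euclidean norm of (vx, vy, vz).  Timestamps must be
    strictly increasing.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ShortEventError("need at least 2 points to estimate speeds")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("timestamps must be strictly increasing")
    vx = np.gradient(np.asarray(x, dtype=float), t)
    vy = np.gradient(np.asarray(y, dtype=float), t)
    vz = np.gradient(np.asarray(z, dtype=float), t)
    return {"vx": vx, "vy": vy, "vz": vz,
            "speed": np.sqrt(vx**2 + vy**2 + vz**2)}


def window_event(points: pd.DataFrame) -> pd.DataFrame:
    """Keep the 30 retained samples of a raw event trajectory.

    Selects 1-based raw indices 3..32 (a pure contiguous selection);
    raises ShortEventError below 33 raw points.
    """
    n = len(points)
    if n < MIN_RAW_POINTS:
        raise ShortEventError(f"event has {n} raw points; need >= {MIN_RAW_POINTS}")
    lo = WINDOW_FIRST_1BASED - 1
    return points.iloc[lo:lo + WINDOW_SIZE].reset_index(drop=True)


def _carry_centroid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Hold the last valid centroid through dropouts (backfill leading)."""
    if not valid.any():
        raise MissingDataError("face centroid never detected in this event")
    out = np.asarray(values, dtype=float).copy()
    idx = np.where(valid, np.arange(len(out)), -1)
    idx = np.maximum.accumulate(idx)
    first = int(np.flatnonzero(valid)[0])
    idx[idx < 0] = first
    return out[idx]


def event_trajectory(frames: pd.DataFrame) -> pd.DataFrame:
    """Build the raw (unwindowed) 3D trajectory of one event.

    Fuses ranges frame by frame with the hold rule, carries the face
    centroid through dropouts, and appends finite-difference speeds.
    """
    frames = frames.sort_values("frame_idx") if "frame_idx" in frames else frames
    t = frames["t"].to_numpy(dtype=float)
    face_valid = frames["face_valid"].to_numpy(dtype=bool)
    x = _carry_centroid(frames["u"].to_numpy(), face_valid)
    y = _carry_centroid(frames["v"].to_numpy(), face_valid)

    d = frames[["d1", "d2", "d3"]].to_numpy(dtype=float)
    rv = frames[["r1_valid", "r2_valid", "r3_valid"]].to_numpy(dtype=bool)
    if not rv.any():
        raise MissingDataError("no valid ultrasonic reading in this event")
    z = np.empty(len(frames))
    prev: float | None = None
    pending = 0  # leading frames with no valid reading, backfilled below
    for k in range(len(frames)):
        try:
            fused, _ = fuse_ranges(d[k], rv[k], prev)
        except MissingDataError:
            pending += 1
            continue
        z[k] = fused
        prev = fused
    if pending:
        z[:pending] = z[pending]

    speeds = estimate_speeds(t, x, y, z)
    out = pd.DataFrame({
        "event_id": frames["event_id"].to_numpy(),
        "t": t, "x": x, "y": y, "z": z,
        "vx": speeds["vx"], "vy": speeds["vy"], "vz": speeds["vz"],
        "speed": speeds["speed"],
    })
    if "stage" in frames:
        out["stage"] = frames["stage"].to_numpy()
    return out


def dataset_trajectories(frames: pd.DataFrame, window: bool = True,
                         ) -> list[pd.DataFrame]:
    """Per-event trajectories for a whole sensor frame table."""
    events = []
    for _, ev in frames.groupby("event_id", sort=True):
        traj = event_trajectory(ev)
        events.append(window_event(traj) if window else traj)
    return events


@dataclass
class NormalizationModel:
    """ZCA whitening of the (x, y, z, speed) feature space.

    Fitted on training points only; applying it to the training set
    yields per-feature mean 0 and identity covariance.  The transform is
    symmetric (C^{-1/2}) so decorrelated axes stay aligned with the
    original sensors as far as possible.
    """

    mean: np.ndarray
    transform: np.ndarray       # W = C^{-1/2}
    inverse: np.ndarray         # W^{-1} = C^{1/2}
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.mean) @ self.transform.T

    def invert(self, whitened: np.ndarray) -> np.ndarray:
        whitened = np.asarray(whitened, dtype=float)
        return whitened @ self.inverse.T + self.mean

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": "1.0",
            "kind": "normalization",
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "transform": {"shape": list(self.transform.shape),
                          "data": self.transform.ravel().tolist()},
        })

    @classmethod
    def from_json(cls, text: str) -> "NormalizationModel":
        d = json.loads(text)
        if d.get("kind") != "normalization" or d.get("schema_version", "").split(".")[0] != "1":
            raise ConfigurationError("not a compatible normalization model file")
        shape = tuple(d["transform"]["shape"])
        w = np.asarray(d["transform"]["data"], dtype=float).reshape(shape)
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   transform=w, inverse=np.linalg.inv(w),
                   feature_names=tuple(d["feature_names"]))


def fit_normalization(points: np.ndarray, shrinkage: float = 1e-9,
                      feature_names: tuple[str, ...] = FEATURE_NAMES,
                      ) -> NormalizationModel:
    """Fit ZCA whitening on training points.

    A small shrinkage (ridge on the covariance diagonal, scaled by the
    mean variance) keeps the transform finite on nearly collinear data;
    exactly coincident points remain degenerate and raise.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise DegenerateCovarianceError("need >= 2 training points")
    mean = points.mean(axis=0)
    centered = points - mean
    cov = centered.T @ centered / points.shape[0]
    total_var = float(np.trace(cov)) / cov.shape[0]
    if total_var <= 1e-24:
        raise DegenerateCovarianceError("all training points identical")
    cov = cov + shrinkage * total_var * np.eye(cov.shape[0])
    evals, evecs = np.linalg.eigh(cov)
    floor = 1e-12 * float(evals.max())
    if np.any(evals <= floor):
        evals = np.maximum(evals, max(floor, shrinkage * total_var))
    w = evecs @ np.diag(evals ** -0.5) @ evecs.T
    w_inv = evecs @ np.diag(evals ** 0.5) @ evecs.T
    return NormalizationModel(mean=mean, transform=w, inverse=w_inv,
                              feature_names=feature_names)


def feature_matrix(events: list[pd.DataFrame]) -> np.ndarray:
    """Stack (x, y, z, speed) rows from a list of event trajectories."""
    return np.concatenate(
        [ev[list(FEATURE_NAMES)].to_numpy(dtype=float) for ev in events], axis=0)
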