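"""Trajectory containers, tracking-file I/O, gap repair, and per-animal kinematics.

Positions are continuous centimetres with the image convention: origin at the
top-left of the arena, x rightward, y downward. Frame indices are 0-based and
frame ranges half-open. Each animal is represented by its body-center keypoint
(the only stable single-point summary of a multi-keypoint pose) plus an
optional nose keypoint used for heading.

Two on-disk dialects are supported:

* ``sleap_h5`` — an analysis-style HDF5 file with datasets ``tracks``
  (animals x coords x keypoints x frames), ``node_names`` and ``track_names``.
  Coordinates are stored in pixels; a ``pixels_per_cm`` scale (file attribute
  or argument) is required.
* ``csv`` — one row per frame x animal with columns
  ``frame, animal_id, sex, body_x, body_y, nose_x, nose_y``; units are cm and
  empty coordinate fields mark invalid detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "GroupRecording",
    "read_tracking",
    "write_tracking",
    "interpolate_gaps",
    "kinematics",
    "occupancy_map",
]

#: default node-name map from SLEAP skeleton names to the consumed keypoints
DEFAULT_NODE_MAP = {"body": ("center", "centroid", "body"), "nose": ("nose",)}

#: median-filter width (frames) applied to positions before the max-speed readout
SPIKE_FILTER_FRAMES = 5


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena geometry, cm. Origin top-left, x rightward, y downward."""

    width: float = 76.2
    length: float = 76.2

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("arena dimensions must be positive")


@dataclass
class Trajectory:
    """One animal's per-frame body-center (and optional nose) track.

    ``body`` is an (n_frames, 2) float array in cm; ``valid`` marks frames with
    a usable detection. Invalid frames may hold NaN coordinates.
    """

    animal_id: str
    body: np.ndarray
    valid: np.ndarray
    fps: float
    sex: str = "unknown"
    nose: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.body = np.asarray(self.body, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.body.ndim != 2 or self.body.shape[1] != 2:
            raise ValueError("body must be (n_frames, 2)")
        if self.valid.shape[0] != self.body.shape[0]:
            raise ValueError("body and valid must have equal length")
        if self.nose is not None:
            self.nose = np.asarray(self.nose, dtype=float)
            if self.nose.shape != self.body.shape:
                raise ValueError("nose must match body shape")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.body.shape[0]

    def copy(self) -> "Trajectory":
        return Trajectory(
            animal_id=self.animal_id,
            body=self.body.copy(),
            valid=self.valid.copy(),
            fps=self.fps,
            sex=self.sex,
            nose=None if self.nose is None else self.nose.copy(),
        )


@dataclass
class GroupRecording:
    """Four simultaneously tracked animals in one arena session."""

    trajectories: list[Trajectory]
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    condition: str = "unknown"
    recording_id: str = "rec"
    analyzed_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.trajectories) != 4:
            raise ValueError(f"expected exactly 4 animals, got {len(self.trajectories)}")
        n = {t.n_frames for t in self.trajectories}
        if len(n) != 1:
            raise ValueError("all trajectories must share frame count")
        fps = {t.fps for t in self.trajectories}
        if len(fps) != 1:
            raise ValueError("all trajectories must share fps")
        if self.analyzed_range is None:
            self.analyzed_range = (0, self.n_frames)
        lo, hi = self.analyzed_range
        if not (0 <= lo < hi <= self.n_frames):
            raise ValueError("analyzed_range outside data")

    @property
    def n_frames(self) -> int:
        return self.trajectories[0].n_frames

    @property
    def fps(self) -> float:
        return self.trajectories[0].fps

    def positions(self) -> np.ndarray:
        """Stacked body centers, shape (4, n_frames, 2)."""
        return np.stack([t.body for t in self.trajectories])

    def valid_matrix(self) -> np.ndarray:
        """Stacked validity, shape (4, n_frames)."""
        return np.stack([t.valid for t in self.trajectories])


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_node(names: list[str], wanted: tuple[str, ...]) -> int | None:
    lowered = [n.lower() for n in names]
    for w in wanted:
        if w in lowered:
            return lowered.index(w)
    return None


def read_tracking(
    path,
    dialect: str,
    *,
    fps: float = 30.0,
    pixels_per_cm: float | None = None,
    arena: ArenaSpec | None = None,
    condition: str = "unknown",
    node_map: dict | None = None,
    animal_order: list[str] | None = None,
) -> GroupRecording:
    """Read a 4-animal tracking file into a :class:`GroupRecording`.

    Missing detections become invalid frames; gap repair is a separate,
    explicit step (:func:`interpolate_gaps`).
    """
    if dialect == "sleap_h5":
        return _read_sleap_h5(path, fps, pixels_per_cm, arena, condition, node_map, animal_order)
    if dialect == "csv":
        return _read_csv(path, fps, arena, condition, animal_order)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sleap_h5(path, fps, pixels_per_cm, arena, condition, node_map, animal_order):
    node_map = node_map or DEFAULT_NODE_MAP
    with h5py.File(path, "r") as f:
        tracks = np.asarray(f["tracks"], dtype=float)  # (animals, 2, nodes, frames)
        node_names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["node_names"][:]]
        track_names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["track_names"][:]]
        scale = pixels_per_cm
        if scale is None and "pixels_per_cm" in f.attrs:
            scale = float(f.attrs["pixels_per_cm"])
        if "fps" in f.attrs:
            fps = float(f.attrs["fps"])
    if scale is None:
        raise ValueError("pixels_per_cm scale required (file attribute or argument)")
    if tracks.shape[0] != 4:
        raise ValueError(f"expected exactly 4 animals, got {tracks.shape[0]}")
    body_idx = _resolve_node(node_names, node_map["body"])
    if body_idx is None:
        raise ValueError(f"no body-center node among {node_names}")
    nose_idx = _resolve_node(node_names, node_map.get("nose", ()))

    order = animal_order or track_names
    trajs = []
    for name in order:
        a = track_names.index(name)
        body = (tracks[a, :, body_idx, :].T / scale).astype(float)  # (frames, 2)
        valid = np.isfinite(body).all(axis=1)
        nose = None
        if nose_idx is not None:
            nose = (tracks[a, :, nose_idx, :].T / scale).astype(float)
        trajs.append(Trajectory(animal_id=name, body=body, valid=valid, fps=fps, nose=nose))
    return GroupRecording(trajs, arena=arena or ArenaSpec(), condition=condition)


CSV_COLUMNS = ["frame", "animal_id", "sex", "body_x", "body_y", "nose_x", "nose_y"]


def _read_csv(path, fps, arena, condition, animal_order):
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"csv dialect missing columns {sorted(missing)}")
    ids = animal_order or sorted(df["animal_id"].unique().tolist())
    if len(ids) != 4:
        raise ValueError(f"expected exactly 4 animals, got {len(ids)}")
    n_frames = int(df["frame"].max()) + 1
    has_nose = "nose_x" in df.columns and "nose_y" in df.columns
    trajs = []
    for aid in ids:
        sub = df[df["animal_id"] == aid]
        body = np.full((n_frames, 2), np.nan)
        nose = np.full((n_frames, 2), np.nan) if has_nose else None
        idx = sub["frame"].to_numpy(dtype=int)
        body[idx, 0] = sub["body_x"].to_numpy(dtype=float)
        body[idx, 1] = sub["body_y"].to_numpy(dtype=float)
        if has_nose:
            nose[idx, 0] = sub["nose_x"].to_numpy(dtype=float)
            nose[idx, 1] = sub["nose_y"].to_numpy(dtype=float)
        valid = np.isfinite(body).all(axis=1)
        sexes = sub["sex"].dropna().unique()
        sex = str(sexes[0]) if len(sexes) else "unknown"
        trajs.append(Trajectory(animal_id=str(aid), body=body, valid=valid, fps=fps, sex=sex, nose=nose))
    return GroupRecording(trajs, arena=arena or ArenaSpec(), condition=condition)


def write_tracking(rec: GroupRecording, path, dialect: str, *, pixels_per_cm: float = 1.0) -> None:
    """Write a recording in either supported dialect (round-trip lossless)."""
    if dialect == "sleap_h5":
        n = rec.n_frames
        has_nose = all(t.nose is not None for t in rec.trajectories)
        nodes = ["center", "nose"] if has_nose else ["center"]
        tracks = np.full((4, 2, len(nodes), n), np.nan)
        for a, t in enumerate(rec.trajectories):
            body = np.where(t.valid[:, None], t.body, np.nan)
            tracks[a, :, 0, :] = (body * pixels_per_cm).T
            if has_nose:
                nose = np.where(t.valid[:, None], t.nose, np.nan)
                tracks[a, :, 1, :] = (nose * pixels_per_cm).T
        with h5py.File(path, "w") as f:
            f.create_dataset("tracks", data=tracks)
            f.create_dataset("node_names", data=np.array([s.encode() for s in nodes]))
            f.create_dataset(
                "track_names", data=np.array([t.animal_id.encode() for t in rec.trajectories])
            )
            f.attrs["pixels_per_cm"] = pixels_per_cm
            f.attrs["fps"] = rec.fps
    elif dialect == "csv":
        rows = []
        for t in rec.trajectories:
            for i in range(t.n_frames):
                if t.valid[i]:
                    bx, by = t.body[i]
                    nx, ny = t.nose[i] if t.nose is not None else (np.nan, np.nan)
                else:
                    bx = by = nx = ny = np.nan
                rows.append((i, t.animal_id, t.sex, bx, by, nx, ny))
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# repair and kinematics


def interpolate_gaps(traj: Trajectory, max_gap: int) -> Trajectory:
    """Linearly fill interior invalid runs of length <= ``max_gap`` frames.

    Edge runs and longer runs are left invalid; no extrapolation. Valid frames
    are never altered, so the valid count is non-decreasing.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = traj.copy()
    if max_gap == 0 or out.valid.all():
        return out
    valid = out.valid
    n = out.n_frames
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        if i > 0 and j < n and run <= max_gap:  # interior, short enough
            w = (np.arange(1, run + 1) / (run + 1))[:, None]
            out.body[i:j] = (1 - w) * out.body[i - 1] + w * out.body[j]
            if out.nose is not None:
                out.nose[i:j] = (1 - w) * out.nose[i - 1] + w * out.nose[j]
            out.valid[i:j] = True
        i = j
    return out


def _central_speed(body: np.ndarray, valid: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame speed (cm/s): central difference, one-sided at the ends.

    A frame's speed is invalid (NaN) if any frame entering its stencil is invalid.
    """
    n = body.shape[0]
    speed = np.full(n, np.nan)
    if n == 1:
        speed[0] = 0.0 if valid[0] else np.nan
        return speed
    d = body[2:] - body[:-2]
    speed[1:-1] = np.linalg.norm(d, axis=1) / 2.0 * fps
    speed[0] = np.linalg.norm(body[1] - body[0]) * fps
    speed[-1] = np.linalg.norm(body[-1] - body[-2]) * fps
    ok = valid.copy()
    ok[1:-1] &= valid[:-2] & valid[2:]
    ok[0] &= valid[1] if n > 1 else True
    ok[-1] &= valid[-2] if n > 1 else True
    speed[~ok] = np.nan
    return speed


def kinematics(traj: Trajectory, window: tuple[int, int] | None = None) -> dict:
    """Speed series, path length and spike-filtered maximum speed over a window.

    ``path_length`` sums step lengths between consecutive valid frames of the
    raw track (invariant under time reversal). ``max_speed`` is read from a
    5-frame median-filtered copy of the positions so single-frame tracking
    spikes do not dominate the maximum.
    """
    lo, hi = window if window is not None else (0, traj.n_frames)
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError("window outside data")
    body = traj.body[lo:hi]
    valid = traj.valid[lo:hi]
    if not valid.any():
        raise ValueError("all frames in window are invalid")

    speed = _central_speed(body, valid, traj.fps)

    steps = np.linalg.norm(np.diff(body, axis=0), axis=1)
    ok = valid[:-1] & valid[1:]
    path_length = float(steps[ok].sum()) if ok.any() else 0.0

    filt = body.copy()
    filt[valid] = median_filter(
        body[valid], size=(min(SPIKE_FILTER_FRAMES, int(valid.sum())), 1), mode="nearest"
    )
    fspeed = _central_speed(filt, valid, traj.fps)
    max_speed = float(np.nanmax(fspeed)) if np.isfinite(fspeed).any() else 0.0

    return {"speed": speed, "path_length": path_length, "max_speed": max_speed}


def occupancy_map(
    traj: Trajectory,
    bins: int,
    window: tuple[int, int] | None = None,
    arena: ArenaSpec | None = None,
) -> np.ndarray:
    """2-D histogram (counts) of valid body-center positions over a window."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    arena = arena or ArenaSpec()
    lo, hi = window if window is not None else (0, traj.n_frames)
    body = traj.body[lo:hi][traj.valid[lo:hi]]
    hist, _, _ = np.histogram2d(
        body[:, 0],
        body[:, 1],
        bins=bins,
        range=[[0, arena.width], [0, arena.length]],
    )
    return hist
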