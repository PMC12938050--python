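"""Dyadic distances, sustained-proximity events, and group huddling states.

Huddling is operationalized spatially and temporally: animals count as
huddling when a configuration-specific distance rule is satisfied for at
least a minimum duration (defaults: 5 cm, 60 s). Configurations:

* DYAD    — two animals within the distance threshold;
* TRIAD   — three animals whose mean pairwise distance (3 pairs within the
            triple) is below the threshold;
* QUARTET — four animals compact enough that the mean of the most separated
            pairs is below the threshold. "Most separated pairs" is read, per
            animal, as its largest distance to any other member (default
            ``quartet_rule="animal_max"``); the alternative reading — the mean
            of the 3 largest of the 6 pairwise distances — is available as
            ``quartet_rule="pair_top3"``.

All threshold comparisons are strict (<); a frame exactly at the threshold is
outside. Larger configurations shadow smaller ones, and candidate runs
shorter than the minimum duration are demoted to the largest smaller
configuration that does satisfy it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import ArenaSpec, GroupRecording

__all__ = [
    "HuddleCriteria",
    "ProximityEvent",
    "HuddleEvent",
    "RegionGrid",
    "min_dyadic_series",
    "bin_by_minute",
    "extract_events",
    "threshold_sweep",
    "classify_state_series",
    "huddling_fraction",
    "corner_enrichment",
]

PAIRS = list(itertools.combinations(range(4), 2))  # fixed order of the 6 dyads
TRIPLES = list(itertools.combinations(range(4), 3))
# pair indices (into PAIRS) internal to each triple / incident to each animal
_TRIPLE_PAIRS = [
    [i for i, p in enumerate(PAIRS) if set(p) <= set(tr)] for tr in TRIPLES
]
_ANIMAL_PAIRS = [[i for i, p in enumerate(PAIRS) if a in p] for a in range(4)]


@dataclass(frozen=True)
class HuddleCriteria:
    """Spatial and temporal criteria defining sustained huddles."""

    distance_threshold: float = 5.0  # cm
    min_duration: float = 60.0  # s
    entry_radius: float = 3.5  # cm, initiator/follower entry rule
    entry_min_inside: float = 1.0  # s
    quartet_rule: str = "animal_max"  # or "pair_top3"
    bridge_gap: float = 0.0  # s; 0 = no bridging of sub-threshold gaps

    def __post_init__(self) -> None:
        if min(self.distance_threshold, self.entry_radius, self.entry_min_inside) <= 0:
            raise ValueError("criteria must be positive")
        if self.min_duration < 0 or self.bridge_gap < 0:
            raise ValueError("durations must be nonnegative")
        if self.quartet_rule not in ("animal_max", "pair_top3"):
            raise ValueError("quartet_rule must be 'animal_max' or 'pair_top3'")


@dataclass
class ProximityEvent:
    """Maximal run of frames with the group min-dyadic distance below threshold."""

    start_frame: int
    end_frame: int  # half-open
    fps: float
    threshold: float

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps


@dataclass
class HuddleEvent:
    """A state-classified huddle with a stable member set."""

    event_id: int
    state: int  # 2 DYAD / 3 TRIAD / 4 QUARTET
    members: tuple[int, ...]
    start_frame: int
    end_frame: int  # half-open
    fps: float
    centroid: tuple[float, float]
    parent_id: int | None = None

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps


@dataclass(frozen=True)
class RegionGrid:
    """4x4 partition of the arena into 16 equal cells (4 corners, 8 edges, 4 centers).

    Cell intervals are half-open [low, high) except the last cell per axis,
    which is closed, so every in-arena point maps to exactly one cell.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)

    def cell(self, x: float, y: float) -> tuple[int, int]:
        cx = min(int(x / (self.arena.width / 4.0)), 3)
        cy = min(int(y / (self.arena.length / 4.0)), 3)
        return cx, cy

    def cell_class(self, x: float, y: float) -> str:
        cx, cy = self.cell(x, y)
        on_x, on_y = cx in (0, 3), cy in (0, 3)
        if on_x and on_y:
            return "corner"
        if on_x or on_y:
            return "edge"
        return "center"


# ---------------------------------------------------------------------------
# distance series and simple events


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """The 6 dyadic distances per frame, shape (6, n_frames).

    ``positions`` is (4, n_frames, 2).
    """
    i = np.array([p[0] for p in PAIRS])
    j = np.array([p[1] for p in PAIRS])
    d = positions[i] - positions[j]
    return np.sqrt((d**2).sum(axis=-1))


def min_dyadic_series(rec: GroupRecording) -> np.ndarray:
    """Per-frame minimum of the 6 pairwise body-center distances (cm).

    Frames with any invalid animal are NaN.
    """
    if len(rec.trajectories) != 4:
        raise ValueError("exactly 4 animals required")
    dmin = pairwise_distances(rec.positions()).min(axis=0)
    dmin[~rec.valid_matrix().all(axis=0)] = np.nan
    return dmin


def bin_by_minute(series: np.ndarray, fps: float) -> pd.DataFrame:
    """Mean and median of a per-frame series over 60 s bins.

    Bins with no valid (finite) frames are flagged ``empty``.
    """
    series = np.asarray(series, dtype=float)
    per_bin = int(round(60 * fps))
    n_bins = int(np.ceil(len(series) / per_bin))
    rows = []
    for b in range(n_bins):
        chunk = series[b * per_bin : (b + 1) * per_bin]
        finite = chunk[np.isfinite(chunk)]
        rows.append(
            {
                "minute": b,
                "mean": finite.mean() if finite.size else np.nan,
                "median": float(np.median(finite)) if finite.size else np.nan,
                "n_valid": finite.size,
                "empty": finite.size == 0,
            }
        )
    return pd.DataFrame(rows)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def extract_events(
    series: np.ndarray, threshold: float, min_duration: float, fps: float
) -> list[ProximityEvent]:
    """Maximal runs with value strictly below ``threshold``; NaN breaks runs.

    Events shorter than ``min_duration`` seconds are dropped when
    ``min_duration > 0``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    series = np.asarray(series, dtype=float)
    below = np.isfinite(series) & (series < threshold)
    min_frames = int(np.ceil(min_duration * fps)) if min_duration > 0 else 1
    return [
        ProximityEvent(s, e, fps, threshold)
        for s, e in _runs(below)
        if e - s >= min_frames
    ]


def threshold_sweep(
    series: np.ndarray, distance_grid, min_duration: float, fps: float
) -> pd.DataFrame:
    """Sustained-event counts across distance thresholds (nondecreasing)."""
    grid = list(distance_grid)
    if not grid:
        raise ValueError("distance grid must be nonempty")
    counts = [len(extract_events(series, thr, min_duration, fps)) for thr in grid]
    return pd.DataFrame({"threshold_cm": grid, "n_events": counts})


# ---------------------------------------------------------------------------
# state classification


def _candidate_masks(D: np.ndarray, valid: np.ndarray, criteria: HuddleCriteria):
    """Per-frame qualification masks and candidate members for each state."""
    thr = criteria.distance_threshold
    all_valid = valid.all(axis=0)

    if criteria.quartet_rule == "animal_max":
        per_animal_max = np.stack([D[idx].max(axis=0) for idx in _ANIMAL_PAIRS])
        quartet_metric = per_animal_max.mean(axis=0)
    else:  # pair_top3: mean of the 3 largest of the 6 pairwise distances
        quartet_metric = np.sort(D, axis=0)[3:, :].mean(axis=0)
    quartet_ok = all_valid & (quartet_metric < thr)

    triple_means = np.stack([D[idx].mean(axis=0) for idx in _TRIPLE_PAIRS])
    triple_valid = np.stack([valid[list(tr)].all(axis=0) for tr in TRIPLES])
    triple_q = triple_valid & (triple_means < thr)
    triad_ok = triple_q.any(axis=0)
    best_triple = np.where(triple_q, triple_means, np.inf).argmin(axis=0)

    pair_valid = np.stack([valid[[i, j]].all(axis=0) for i, j in PAIRS])
    pair_q = pair_valid & (D < thr)
    dyad_ok = pair_q.any(axis=0)
    best_pair = np.where(pair_q, D, np.inf).argmin(axis=0)

    return {
        4: (quartet_ok, None),
        3: (triad_ok, best_triple),
        2: (dyad_ok, best_pair),
    }, pair_q


def dyad_multiplicity_frames(pair_q: np.ndarray) -> np.ndarray:
    """Frames where two *disjoint* dyads qualify simultaneously.

    The 3 disjoint pair-pairings of 4 animals are (01,23), (02,13), (03,12),
    i.e. pair indices (0,5), (1,4), (2,3) in the fixed PAIRS order.
    """
    return (
        (pair_q[0] & pair_q[5]) | (pair_q[1] & pair_q[4]) | (pair_q[2] & pair_q[3])
    )


def classify_state_frames(
    positions: np.ndarray, valid: np.ndarray, criteria: HuddleCriteria, fps: float
) -> np.ndarray:
    """Per-frame group state in {0, 2, 3, 4} after duration gating.

    Applied top-down: quartet runs meeting the minimum duration are fixed
    first, then triad runs on the remaining frames, then dyad runs — so a
    short higher-state excursion inside a sustained lower state demotes to
    that lower state rather than fragmenting it.
    """
    D = pairwise_distances(positions)
    cand, _ = _candidate_masks(D, valid, criteria)
    min_frames = int(np.ceil(criteria.min_duration * fps)) if criteria.min_duration > 0 else 1
    assigned = np.zeros(D.shape[1], dtype=int)
    for state in (4, 3, 2):
        ok, _members = cand[state]
        mask = ok & (assigned == 0)
        for s, e in _runs(mask):
            if e - s >= min_frames:
                assigned[s:e] = state
    return assigned


def classify_state_series(
    rec: GroupRecording, criteria: HuddleCriteria | None = None
) -> tuple[np.ndarray, list[HuddleEvent]]:
    """Group state per frame plus member-resolved :class:`HuddleEvent` list.

    Within a constant-state run, frame membership follows the qualifying
    candidate (closest pair / tightest triple / all four), with hysteresis:
    the previous frame's member set is kept while it still qualifies, so
    jitter between near-tied candidates does not fragment events. A
    member-set change closes the event and opens a child event linked through
    ``parent_id``.
    """
    criteria = criteria or HuddleCriteria()
    if len(rec.trajectories) != 4:
        raise ValueError("exactly 4 animals required")
    positions = rec.positions()
    valid = rec.valid_matrix()
    fps = rec.fps
    D = pairwise_distances(positions)
    cand, _multiplicity = _candidate_masks(D, valid, criteria)
    assigned = classify_state_frames(positions, valid, criteria, fps)

    thr = criteria.distance_threshold
    events: list[HuddleEvent] = []
    next_id = 0
    for s, e in _runs(assigned > 0):
        state = int(assigned[s])
        prev_members: tuple[int, ...] | None = None
        seg_start = s
        parent: int | None = None

        def members_at(f: int, state: int, prev: tuple[int, ...] | None) -> tuple[int, ...]:
            if state == 4:
                return (0, 1, 2, 3)
            if state == 3:
                if prev is not None and len(prev) == 3:
                    k = TRIPLES.index(prev)
                    if D[_TRIPLE_PAIRS[k], f].mean() < thr:
                        return prev
                return TRIPLES[cand[3][1][f]]
            if prev is not None and len(prev) == 2:
                k = PAIRS.index(prev)
                if D[k, f] < thr:
                    return prev
            return PAIRS[cand[2][1][f]]

        def close_segment(seg_start: int, f_end: int, state: int, members: tuple[int, ...], parent):
            nonlocal next_id
            pts = positions[list(members), seg_start:f_end, :].mean(axis=0)
            centroid = tuple(np.round(pts.mean(axis=0), 6))
            ev = HuddleEvent(
                event_id=next_id,
                state=state,
                members=members,
                start_frame=seg_start,
                end_frame=f_end,
                fps=fps,
                centroid=centroid,
                parent_id=parent,
            )
            events.append(ev)
            next_id += 1
            return ev.event_id

        for f in range(s, e):
            st = int(assigned[f])
            m = members_at(f, st, prev_members if st == (len(prev_members or ())) else None)
            if prev_members is None:
                prev_members, seg_start = m, f
            elif m != prev_members or st != len(prev_members):
                parent = close_segment(seg_start, f, len(prev_members), prev_members, parent)
                prev_members, seg_start = m, f
        if prev_members is not None:
            close_segment(seg_start, e, len(prev_members), prev_members, parent)
    return assigned, events


def huddling_fraction(
    rec: GroupRecording, criteria: HuddleCriteria | None = None, states: np.ndarray | None = None
) -> float:
    """Fraction of the analyzed range spent in any huddling state.

    Invalid frames remain in the denominator (they count as non-huddling
    time), so the fraction is with respect to the full analyzed hour.
    """
    criteria = criteria or HuddleCriteria()
    lo, hi = rec.analyzed_range
    if hi <= lo:
        raise ValueError("analyzed_range is empty")
    if states is None:
        states = classify_state_frames(
            rec.positions()[:, lo:hi], rec.valid_matrix()[:, lo:hi], criteria, rec.fps
        )
    else:
        states = states[lo:hi]
    return float((states > 0).sum() / (hi - lo))


# ---------------------------------------------------------------------------
# spatial enrichment


def events_table(events: list[HuddleEvent], rec: GroupRecording, grid: RegionGrid | None = None) -> pd.DataFrame:
    """Tidy event table (one row per HuddleEvent) for export."""
    grid = grid or RegionGrid(rec.arena)
    rows = []
    for ev in events:
        rows.append(
            {
                "recording_id": rec.recording_id,
                "event_id": ev.event_id,
                "parent_id": ev.parent_id,
                "state": {2: "DYAD", 3: "TRIAD", 4: "QUARTET"}[ev.state],
                "members": "+".join(rec.trajectories[m].animal_id for m in ev.members),
                "start_s": ev.start_frame / ev.fps,
                "end_s": ev.end_frame / ev.fps,
                "duration_s": ev.duration,
                "centroid_x_cm": ev.centroid[0],
                "centroid_y_cm": ev.centroid[1],
                "region_class": grid.cell_class(*ev.centroid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "recording_id", "event_id", "parent_id", "state", "members",
            "start_s", "end_s", "duration_s", "centroid_x_cm", "centroid_y_cm",
            "region_class",
        ],
    )


def corner_enrichment(
    events_per_recording: dict[str, list[HuddleEvent]],
    grid: RegionGrid | None = None,
) -> dict:
    """Per-mouse corner proportions and a one-sample signed-rank test vs 0.25.

    A mouse's events are the huddle events whose member set contains it
    (pooled across its recording); mice with zero events are excluded and
    reported. The null median is 4/16 = 0.25, the corner share of a uniform
    spatial distribution over the 16-cell grid.
    """
    from .stats import signed_rank_one_sample

    grid = grid or RegionGrid()
    proportions: dict[tuple[str, int], float] = {}
    excluded: list[tuple[str, int]] = []
    for rec_id, events in events_per_recording.items():
        per_mouse: dict[int, list[bool]] = {a: [] for a in range(4)}
        for ev in events:
            in_corner = grid.cell_class(*ev.centroid) == "corner"
            for m in ev.members:
                per_mouse[m].append(in_corner)
        for a, flags in per_mouse.items():
            if flags:
                proportions[(rec_id, a)] = float(np.mean(flags))
            else:
                excluded.append((rec_id, a))
    values = np.array(list(proportions.values()))
    result = None
    if (values != 0.25).sum() >= 3:
        result = signed_rank_one_sample(values, 0.25)
    return {
        "proportions": proportions,
        "excluded": excluded,
        "test": result,
        "null_value": 0.25,
    }
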