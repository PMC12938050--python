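"""Synthetic multi-agent arena simulator with ground-truth huddle labels.

The simulator reproduces the *statistical structure* of group recordings of
four mice in a 76.2 x 76.2 cm arena at 30 frames/s, not any physical or social
mechanism. Two phenotypes are generated:

* ``control`` — four independent wanderers (heading-persistent random walk,
  truncated-normal speeds, reflecting walls). Paths cross occasionally, giving
  brief incidental proximity but no sustained huddles.
* ``impaired`` — the same wandering interrupted by scheduled huddles: events
  drawn as a Poisson process, sited with a configurable corner bias, whose
  members approach the site in a staggered growth order (dyad, then triad,
  then quartet) and station there with small positional jitter until the
  scheduled end.

Every simulation carries a frame-level :class:`GroundTruth` (per-agent regime,
per-frame group state, and the schedule itself) so downstream detectors can be
scored against known labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tracking import ArenaSpec, GroupRecording, Trajectory

__all__ = [
    "SimConfig",
    "HuddleSchedule",
    "ScheduleEntry",
    "GroundTruth",
    "make_schedule",
    "step_agent",
    "simulate_group",
]

STATE_NAMES = {0: "NONE", 2: "DYAD", 3: "TRIAD", 4: "QUARTET"}

#: cm the nose sits ahead of the body center along the instantaneous heading
NOSE_OFFSET_CM = 2.5

#: ring radius (cm) on which stationed members settle around the huddle site
HUDDLE_RING_CM = 1.8

#: AR(1) coefficient of stationed-position jitter: huddled animals are nearly
#: motionless frame to frame while keeping the configured positional spread
STATION_JITTER_RHO = 0.98

#: seconds of slack added to the computed travel time when scheduling approaches
APPROACH_MARGIN_S = 2.0

#: earliest allowed event start / minimum inter-event gap (s); leaves agents
#: time to reach (or disperse from) a site at the default approach speed
SCHEDULE_LEAD_S = 30.0
SCHEDULE_GAP_S = 30.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated group recording.

    Defaults are the recording conditions of the assay the package analyzes:
    4 mixed-sex mice, 76.2 cm square arena, 30 frames/s, 1 h analyzed.
    Locomotion and huddle-schedule defaults are calibrated qualitatively
    (see docs/methods.md): impaired groups huddle for minutes at a time,
    mostly in corners; controls never satisfy the 5 cm / 1 min criteria.
    """

    arena_side: float = 76.2
    fps: float = 30.0
    duration: float = 3600.0
    n_agents: int = 4
    phenotype: str = "control"  # or "impaired"
    wander_speed_mean: float = 6.0  # cm/s
    wander_speed_sd: float = 3.0  # cm/s
    turn_sd: float = 0.5  # rad/frame, wrapped-Gaussian turning angle
    approach_speed: float = 15.0  # cm/s
    station_jitter_sd: float = 0.3  # cm
    huddle_rate: float = 3.0  # events per simulated hour
    huddle_duration_range: tuple[float, float] = (240.0, 480.0)  # s, full span incl. growth
    huddle_size: int = 4  # members per scheduled huddle (2-4)
    member_stagger: float = 75.0  # s between growth-order arrivals (within the span)
    initiator_lead: float = 10.0  # s the first member stations alone before onset
    corner_bias: float = 0.8  # probability a site lies in a corner cell
    sex_effect: float = 0.0  # cosmetic; no dynamic effect at 0 (default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_side <= 0 or self.fps <= 0 or self.duration <= 0:
            raise ValueError("arena_side, fps and duration must be positive")
        if not 0 <= self.corner_bias <= 1:
            raise ValueError("corner_bias must be in [0, 1]")
        lo, hi = self.huddle_duration_range
        if hi < lo or lo <= 0:
            raise ValueError("huddle_duration_range must be positive nondecreasing")
        if not 2 <= self.huddle_size <= self.n_agents:
            raise ValueError("huddle_size must be between 2 and n_agents")
        if self.phenotype not in ("control", "impaired"):
            raise ValueError("phenotype must be 'control' or 'impaired'")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class ScheduleEntry:
    start: float  # s
    duration: float  # s
    members: tuple[int, ...]
    site: tuple[float, float]  # cm
    growth_order: tuple[int, ...]

    @property
    def end(self) -> float:
        return self.start + self.duration

    def member_start(self, agent: int, stagger: float, lead: float = 0.0) -> float:
        """When ``agent`` is scheduled to be stationed at the site (s).

        The first member in growth order (the scripted initiator) stations
        ``lead`` seconds before ``start``; the second arrives at ``start``,
        which is when the huddle exists (a dyad). Each later member joins
        ``stagger`` seconds after the previous one. Growth happens *inside*
        the scheduled span: all members remain until ``end = start + duration``.
        """
        k = self.growth_order.index(agent)
        if k == 0:
            return self.start - lead
        return self.start + (k - 1) * stagger


@dataclass
class HuddleSchedule:
    entries: list[ScheduleEntry] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.entries], indent=2)


@dataclass
class GroundTruth:
    """Frame-level labels: per-agent regime, group state, and the schedule."""

    regimes: np.ndarray  # (n_agents, n_frames) of {"wander","approach","station"}
    group_state: np.ndarray  # (n_frames,) of {0, 2, 3, 4}
    schedule: HuddleSchedule

    def to_frame(self) -> pd.DataFrame:
        n_agents, n_frames = self.regimes.shape
        return pd.DataFrame(
            {
                "frame": np.tile(np.arange(n_frames), n_agents),
                "agent_id": np.repeat(np.arange(n_agents), n_frames),
                "regime": self.regimes.ravel(),
                "group_state": np.tile(self.group_state, n_agents),
            }
        )


# ---------------------------------------------------------------------------
# scheduling


def _corner_cells(side: float) -> list[tuple[float, float, float, float]]:
    c = side / 4.0
    return [
        (0, c, 0, c),
        (3 * c, side, 0, c),
        (0, c, 3 * c, side),
        (3 * c, side, 3 * c, side),
    ]


def _draw_site(config: SimConfig, rng: np.random.Generator) -> tuple[float, float]:
    side = config.arena_side
    margin = 4.0  # keep the stationed ring + jitter inside the arena
    if rng.random() < config.corner_bias:
        x0, x1, y0, y1 = _corner_cells(side)[rng.integers(4)]
        x = rng.uniform(max(x0, margin), min(x1, side - margin))
        y = rng.uniform(max(y0, margin), min(y1, side - margin))
    else:
        x = rng.uniform(margin, side - margin)
        y = rng.uniform(margin, side - margin)
    return (float(x), float(y))


def make_schedule(config: SimConfig, rng: np.random.Generator) -> HuddleSchedule:
    """Draw the huddle schedule for one simulation.

    Control phenotype: no scheduled huddles. Impaired phenotype: the event
    count is Poisson at ``huddle_rate`` per hour; starts are uniform over the
    feasible span and then packed sequentially (an event whose start would
    collide with the previous event is pushed after it; events that no longer
    fit before the end of the recording are dropped, which is rare at the
    default rate).
    """
    if config.phenotype == "control":
        return HuddleSchedule()
    lo, hi = config.huddle_duration_range
    growth_span = (config.huddle_size - 2) * config.member_stagger
    if lo <= growth_span:
        raise ValueError(
            "huddle durations must exceed the growth span "
            f"({growth_span:.0f} s at size {config.huddle_size}, stagger {config.member_stagger:.0f} s)"
        )
    latest = config.duration - hi - SCHEDULE_LEAD_S
    if latest <= SCHEDULE_LEAD_S:
        raise ValueError("huddle_duration_range does not fit in the simulation length")
    n_events = rng.poisson(config.huddle_rate * config.duration / 3600.0)
    starts = np.sort(rng.uniform(SCHEDULE_LEAD_S, latest, size=n_events))
    entries: list[ScheduleEntry] = []
    t_free = SCHEDULE_LEAD_S
    for s in starts:
        start = max(float(s), t_free)
        duration = float(rng.uniform(lo, hi))
        if start + duration > config.duration - 1.0:
            continue  # does not fit; dropped (rare at the default rate)
        members = tuple(int(a) for a in rng.choice(config.n_agents, size=config.huddle_size, replace=False))
        order = tuple(int(a) for a in rng.permutation(members))
        entries.append(
            ScheduleEntry(
                start=start,
                duration=duration,
                members=members,
                site=_draw_site(config, rng),
                growth_order=order,
            )
        )
        t_free = start + duration + SCHEDULE_GAP_S
    return HuddleSchedule(entries)


# ---------------------------------------------------------------------------
# stepping


def _reflect(p: np.ndarray, side: float) -> np.ndarray:
    """Fold a coordinate pair back into [0, side] (reflecting walls)."""
    p = np.mod(p, 2 * side)
    return np.where(p > side, 2 * side - p, p)


def _truncated_speed(config: SimConfig, rng: np.random.Generator, size=None) -> np.ndarray:
    """Speeds ~ Normal(mean, sd) truncated at 0, by resampling."""
    s = rng.normal(config.wander_speed_mean, config.wander_speed_sd, size=size)
    bad = s < 0
    while np.any(bad):
        s = np.where(bad, rng.normal(config.wander_speed_mean, config.wander_speed_sd, size=size), s)
        bad = s < 0
    return s


def step_agent(
    pos: np.ndarray,
    regime: str,
    target: np.ndarray | None,
    config: SimConfig,
    rng: np.random.Generator,
    heading: float | None = None,
) -> tuple[np.ndarray, float]:
    """Advance one agent one frame; returns (new position, new heading).

    wander   — heading-persistent step: heading += wrapped-Gaussian turn,
               step length = truncated-normal speed / fps, walls reflect.
    approach — step of length approach_speed/fps straight toward ``target``
               (landing on it when closer than one step).
    station  — Gaussian jitter (sd = station_jitter_sd) about ``target``,
               clipped to the arena.
    """
    pos = np.asarray(pos, dtype=float)
    side = config.arena_side
    if regime == "wander":
        h = float(rng.uniform(0, 2 * np.pi)) if heading is None else heading
        h = h + float(rng.normal(0.0, config.turn_sd))
        step = float(_truncated_speed(config, rng)) / config.fps
        new = pos + step * np.array([np.cos(h), np.sin(h)])
        folded = _reflect(new, side)
        # reflect the heading on a bounce so persistence survives the wall
        if new[0] != folded[0]:
            h = np.pi - h
        if new[1] != folded[1]:
            h = -h
        return folded, h
    if regime == "approach":
        tgt = np.asarray(target, dtype=float)
        delta = tgt - pos
        dist = float(np.linalg.norm(delta))
        step = config.approach_speed / config.fps
        if dist <= step or dist == 0.0:
            new = tgt
        else:
            new = pos + delta / dist * step
        h = float(np.arctan2(delta[1], delta[0])) if dist > 0 else (heading or 0.0)
        return np.clip(new, 0.0, side), h
    if regime == "station":
        tgt = np.asarray(target, dtype=float)
        new = tgt + rng.normal(0.0, config.station_jitter_sd, size=2)
        delta = new - pos
        if np.linalg.norm(delta) > 0:
            heading = float(np.arctan2(delta[1], delta[0]))
        return np.clip(new, 0.0, side), heading if heading is not None else 0.0
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# whole-group simulation


def _wander_paths_vectorized(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """All-wander trajectories for every agent, shape (n_agents, n_frames, 2).

    Headings accumulate wrapped-Gaussian turns and unbounded displacements are
    folded into the arena (equivalent to reflecting walls), which keeps the
    control phenotype fully vectorized.
    """
    n, T = config.n_agents, config.n_frames
    turns = rng.normal(0.0, config.turn_sd, size=(n, T))
    turns[:, 0] = rng.uniform(0, 2 * np.pi, size=n)
    headings = np.cumsum(turns, axis=1)
    speeds = _truncated_speed(config, rng, size=(n, T)) / config.fps
    steps = np.stack([speeds * np.cos(headings), speeds * np.sin(headings)], axis=-1)
    start = rng.uniform(0, config.arena_side, size=(n, 1, 2))
    raw = start + np.cumsum(steps, axis=1)
    raw[:, 0, :] = start[:, 0, :]  # frame 0 is the start position
    side = config.arena_side
    folded = np.mod(raw, 2 * side)
    return np.where(folded > side, 2 * side - folded, folded)


def _headings_from_path(path: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Instantaneous heading per frame from finite differences (for the nose)."""
    d = np.diff(path, axis=0)
    h = np.arctan2(d[:, 1], d[:, 0])
    h = np.concatenate([h[:1], h])
    still = np.concatenate([[False], np.linalg.norm(d, axis=1) < 1e-9])
    # hold the previous heading through stationary frames
    for i in np.flatnonzero(still):
        h[i] = h[i - 1] if i > 0 else rng.uniform(0, 2 * np.pi)
    return h


def simulate_group(config: SimConfig) -> tuple[GroupRecording, GroundTruth]:
    """Simulate one group recording; deterministic given ``config.seed``.

    Raises ``RuntimeError`` if an agent cannot reach a scheduled site before
    its scheduled station start at the configured approach speed.
    """
    rng = np.random.default_rng(config.seed)
    schedule = make_schedule(config, rng)
    n, T, fps, side = config.n_agents, config.n_frames, config.fps, config.arena_side

    regimes = np.full((n, T), "wander", dtype=object)
    group_state = np.zeros(T, dtype=int)

    if not schedule.entries:
        pos = _wander_paths_vectorized(config, rng)
    else:
        # noise pre-drawn per agent (deterministic sub-streams); the frame loop
        # then only routes each agent between wander / approach / station
        turns = rng.normal(0.0, config.turn_sd, size=(n, T))
        speeds = _truncated_speed(config, rng, size=(n, T)) / fps
        jitter = rng.normal(0.0, config.station_jitter_sd, size=(n, T, 2))
        jstate = np.zeros((n, 2))  # AR(1) jitter state per agent
        j_innov = np.sqrt(1.0 - STATION_JITTER_RHO**2)
        pos = np.empty((n, T, 2))
        pos[:, 0, :] = rng.uniform(0, side, size=(n, 2))
        headings = rng.uniform(0, 2 * np.pi, size=n)

        # per-agent sorted station spans: (station_start_s, end_s, site_xy)
        spans: list[list[tuple[float, float, np.ndarray]]] = [[] for _ in range(n)]
        for e in schedule.entries:
            for a in e.members:
                k = e.growth_order.index(a)
                ring = 2 * np.pi * k / len(e.members)
                site = np.array(
                    [e.site[0] + HUDDLE_RING_CM * np.cos(ring), e.site[1] + HUDDLE_RING_CM * np.sin(ring)]
                )
                spans[a].append((e.member_start(a, config.member_stagger, config.initiator_lead), e.end, site))
        for s in spans:
            s.sort(key=lambda x: x[0])
        next_span = [0] * n
        step_len = config.approach_speed / fps
        cos, sin, hypot, atan2 = np.cos, np.sin, np.hypot, np.arctan2

        for f in range(1, T):
            t = f / fps
            for a in range(n):
                x, y = pos[a, f - 1]
                sp = spans[a]
                j = next_span[a]
                if j < len(sp) and t > sp[j][1]:
                    j = next_span[a] = j + 1
                site = sp[j][2] if j < len(sp) else None
                if site is not None:
                    s_start = sp[j][0]
                    dx, dy = site[0] - x, site[1] - y
                    dist = hypot(dx, dy)
                    if t >= s_start - 1.0 / fps:
                        if dist > 2.0:
                            raise RuntimeError(
                                f"agent {a} cannot reach site ({site[0]:.1f}, {site[1]:.1f}) "
                                f"by t={s_start:.1f}s (schedule infeasible at configured speeds)"
                            )
                        regime = "station"
                    elif (s_start - t) <= dist / config.approach_speed + APPROACH_MARGIN_S:
                        regime = "station" if dist <= 1.0 else "approach"
                    else:
                        regime = "wander"
                else:
                    regime = "wander"

                if regime == "wander":
                    h = headings[a] + turns[a, f]
                    nx = x + speeds[a, f] * cos(h)
                    ny = y + speeds[a, f] * sin(h)
                    if nx < 0 or nx > side:
                        nx = -nx if nx < 0 else 2 * side - nx
                        h = np.pi - h
                    if ny < 0 or ny > side:
                        ny = -ny if ny < 0 else 2 * side - ny
                        h = -h
                    headings[a] = h
                elif regime == "approach":
                    if dist <= step_len:
                        nx, ny = site[0], site[1]
                    else:
                        nx = x + dx / dist * step_len
                        ny = y + dy / dist * step_len
                    headings[a] = atan2(dy, dx)
                else:  # station
                    jstate[a, 0] = STATION_JITTER_RHO * jstate[a, 0] + j_innov * jitter[a, f, 0]
                    jstate[a, 1] = STATION_JITTER_RHO * jstate[a, 1] + j_innov * jitter[a, f, 1]
                    nx = min(max(site[0] + jstate[a, 0], 0.0), side)
                    ny = min(max(site[1] + jstate[a, 1], 0.0), side)
                pos[a, f, 0] = nx
                pos[a, f, 1] = ny
                regimes[a, f] = regime

    # ground-truth group state straight from the schedule
    frame_t = np.arange(T) / fps
    for e in schedule.entries:
        present = np.zeros(T, dtype=int)
        for a in e.members:
            ms = e.member_start(a, config.member_stagger, config.initiator_lead)
            present += ((frame_t >= ms) & (frame_t < e.end)).astype(int)
        in_event = present >= 2
        group_state[in_event] = np.maximum(group_state[in_event], present[in_event])

    trajs = []
    sexes = ["M", "M", "F", "F"]
    for a in range(n):
        h = _headings_from_path(pos[a], np.random.default_rng(config.seed + 7 * a + 1))
        nose = pos[a] + NOSE_OFFSET_CM * np.stack([np.cos(h), np.sin(h)], axis=-1)
        trajs.append(
            Trajectory(
                animal_id=f"mouse{a}",
                body=pos[a].copy(),
                valid=np.ones(T, dtype=bool),
                fps=fps,
                sex=sexes[a % 4],
                nose=np.clip(nose, 0.0, side),
            )
        )
    rec = GroupRecording(
        trajs,
        arena=ArenaSpec(side, side),
        condition=config.phenotype,
        recording_id=f"sim-{config.phenotype}-{config.seed}",
    )
    return rec, GroundTruth(regimes=regimes, group_state=group_state, schedule=schedule)


def scheduled_span_recovery(gt: GroundTruth, detected_states: np.ndarray, fps: float) -> list[float]:
    """Jaccard overlap of each scheduled huddle span with its best detected bout.

    Detected bouts are maximal contiguous runs of non-NONE group state; each
    scheduled entry is scored against the bout overlapping it most.
    """
    det = np.asarray(detected_states) > 0
    padded = np.concatenate([[False], det, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    bouts = list(zip(edges[::2], edges[1::2]))
    out = []
    for e in gt.schedule.entries:
        s, t = int(round(e.start * fps)), int(round(e.end * fps))
        best = 0.0
        for bs, bt in bouts:
            inter = max(0, min(t, bt) - max(s, bs))
            if inter == 0:
                continue
            union = max(t, bt) - min(s, bs)
            best = max(best, inter / union)
        out.append(best)
    return out


def write_ground_truth(gt: GroundTruth, csv_path, json_path) -> None:
    """Persist labels as CSV (frame, agent, regime, group state) + JSON schedule."""
    gt.to_frame().to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        fh.write(gt.schedule.to_json())
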