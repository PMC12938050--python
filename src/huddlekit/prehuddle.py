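"""Initiator/follower dynamics before dyadic huddles and their latent states.

For each dyadic huddle the two members are ordered by when they *entered* the
huddle: the entry time is the first moment an animal's body center comes
within ``entry_radius`` (default 3.5 cm) of the huddle center and stays there
continuously for at least ``entry_min_inside`` (default 1 s). First in =
initiator, second = follower.

The five seconds (150 frames at 30 fps) preceding huddle onset are summarized
per animal by instantaneous speed, distance to the huddle center, and the
cosine of the angle between the head direction (nose - body center) and the
direction to the center. Gaussian-emission hidden Markov models with 2-4
latent states are fitted to the pooled (speed, distance) sequences; the
selected model's states are labeled post hoc — the faster state is
"approaching", the slower "stationing" — and temporal stability is summarized
by stationary-weighted persistence

    wPersistence = sum_s  pi_s * P_ss,

the self-transition probabilities weighted by the stationary distribution pi
of the transition matrix P. Animal-level dependence is probed with a
clustered bootstrap that resamples whole animals with all their sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .proximity import HuddleCriteria, HuddleEvent
from .tracking import GroupRecording, _central_speed

__all__ = [
    "RoleAssignment",
    "PreHuddleWindow",
    "HmmFit",
    "BootstrapResult",
    "assign_roles",
    "pre_window_features",
    "fit_hmm_select",
    "wpersistence",
    "stationary_distribution",
    "clustered_bootstrap",
    "approach_station_ratio",
]

WINDOW_S = 5.0
VARIANCE_FLOOR = 1e-4  # in standardized units
CENTER_ANCHOR_S = 10.0  # center = member centroid averaged over onset+10 s


@dataclass
class RoleAssignment:
    event_id: int
    initiator: int
    follower: int
    entry_time: dict[int, float]  # s, per animal index
    huddle_center: tuple[float, float]


@dataclass
class PreHuddleWindow:
    event_id: int
    animal: int
    role: str  # "initiator" | "follower"
    speed: np.ndarray  # cm/s, length = window frames
    dist_to_center: np.ndarray  # cm
    heading_cos: np.ndarray  # [-1, 1]; NaN without a nose keypoint
    short: bool = False  # window truncated at the recording start
    recording_id: str = "rec"

    @property
    def n_frames(self) -> int:
        return len(self.speed)


@dataclass
class HmmFit:
    K: int
    means: np.ndarray  # (K, n_features), original units
    variances: np.ndarray  # (K, n_features), original units
    P: np.ndarray  # (K, K)
    pi: np.ndarray  # stationary distribution of P
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int
    state_labels: dict[str, int]  # {"approaching": idx, "stationing": idx}
    wpersistence: float
    converged: bool
    aic_by_k: dict[int, float] = field(default_factory=dict)
    bic_by_k: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False
    model: GaussianHMM | None = None
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd) of features


@dataclass
class BootstrapResult:
    replicates: np.ndarray
    B: int
    median: float
    ci95: tuple[float, float]
    seed: int
    n_resampled: int = 0  # replicates redrawn for having < 2 sequences


# ---------------------------------------------------------------------------
# roles


def _sustained_entry(dist: np.ndarray, radius: float, min_frames: int, onset: int, fps: float) -> float | None:
    """Start time (s) of the sustained inside-run in effect at huddle onset.

    "Inside" means dist <= radius; only runs lasting >= min_frames count as
    sustained (a brief dip inside does not). The entry is the start of the
    sustained run containing the onset frame (a resident's run may reach back
    to the recording start); if the animal is outside at onset, the first
    sustained run beginning after onset (the animal settling into the huddle)
    is used instead.
    """
    inside = dist <= radius
    if not inside.any():
        return None
    padded = np.concatenate([[False], inside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    after = None
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s < min_frames:
            continue
        if s <= onset < e:
            return s / fps
        if s > onset and after is None:
            after = s / fps
    return after


def assign_roles(
    rec: GroupRecording, event: HuddleEvent, criteria: HuddleCriteria | None = None
) -> RoleAssignment | None:
    """Order the two members of a dyadic huddle by sustained entry time.

    The huddle center is the members' body-center centroid averaged over the
    first 10 s after onset (held fixed). Entry search runs from the analyzed
    start through the event end. Ties at the same entry frame break toward
    the animal closer to the center at that frame. Returns ``None`` (the
    event is excluded from role analysis) if a member never satisfies the
    entry rule.
    """
    criteria = criteria or HuddleCriteria()
    if event.state != 2:
        raise ValueError("role assignment is defined for dyadic events only")
    fps = rec.fps
    a, b = event.members
    lo, _ = rec.analyzed_range
    anchor_end = min(event.start_frame + int(CENTER_ANCHOR_S * fps), event.end_frame)
    pos = rec.positions()
    center = pos[[a, b], event.start_frame : anchor_end, :].mean(axis=(0, 1))

    min_frames = int(np.ceil(criteria.entry_min_inside * fps))
    entry: dict[int, float] = {}
    for m in (a, b):
        dist = np.linalg.norm(pos[m, lo : event.end_frame] - center, axis=1)
        t = _sustained_entry(dist, criteria.entry_radius, min_frames, event.start_frame - lo, fps)
        if t is None:
            return None
        entry[m] = t + lo / fps
    if entry[a] < entry[b]:
        first, second = a, b
    elif entry[b] < entry[a]:
        first, second = b, a
    else:  # same frame: closer animal at that frame is the initiator
        f = int(round(entry[a] * fps))
        da, db = (np.linalg.norm(pos[m, f] - center) for m in (a, b))
        first, second = (a, b) if da <= db else (b, a)
    return RoleAssignment(
        event_id=event.event_id,
        initiator=first,
        follower=second,
        entry_time=entry,
        huddle_center=(float(center[0]), float(center[1])),
    )


# ---------------------------------------------------------------------------
# features


def pre_window_features(
    rec: GroupRecording, assignment: RoleAssignment, event: HuddleEvent, window_s: float = WINDOW_S
) -> list[PreHuddleWindow]:
    """Per-role kinematic windows over the ``window_s`` seconds before onset.

    Windows whose start precedes the analyzed range are truncated and flagged
    ``short``. The displacement scalar (start-to-end position change) is
    available via :func:`window_displacement`.
    """
    fps = rec.fps
    n_frames = int(round(window_s * fps))
    onset = event.start_frame
    lo, _ = rec.analyzed_range
    start = onset - n_frames
    short = start < lo
    start = max(start, lo)
    center = np.asarray(assignment.huddle_center)

    out = []
    for animal, role in ((assignment.initiator, "initiator"), (assignment.follower, "follower")):
        traj = rec.trajectories[animal]
        body = traj.body[start:onset]
        valid = traj.valid[start:onset]
        speed = _central_speed(body, valid, fps)
        dist = np.linalg.norm(body - center, axis=1)
        if traj.nose is not None:
            head = traj.nose[start:onset] - body
            to_center = center - body
            num = (head * to_center).sum(axis=1)
            den = np.linalg.norm(head, axis=1) * np.linalg.norm(to_center, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                hcos = np.where(den > 0, num / den, np.nan)
        else:
            hcos = np.full(onset - start, np.nan)
        out.append(
            PreHuddleWindow(
                event_id=event.event_id,
                animal=animal,
                role=role,
                speed=speed,
                dist_to_center=dist,
                heading_cos=hcos,
                short=short,
                recording_id=rec.recording_id,
            )
        )
    return out


def window_displacement(rec: GroupRecording, window: PreHuddleWindow, event: HuddleEvent,
                        window_s: float = WINDOW_S) -> float:
    """Euclidean start-to-end displacement (cm) over the pre-onset window."""
    fps = rec.fps
    onset = event.start_frame
    start = max(onset - int(round(window_s * fps)), rec.analyzed_range[0])
    body = rec.trajectories[window.animal].body
    return float(np.linalg.norm(body[onset - 1] - body[start]))


def windows_table(windows: list[PreHuddleWindow], states: dict[tuple[int, int], np.ndarray] | None = None) -> pd.DataFrame:
    """Tidy per-frame feature table (one row per window frame)."""
    rows = []
    for w in windows:
        st = states.get((w.event_id, w.animal)) if states else None
        for f in range(w.n_frames):
            rows.append(
                {
                    "recording_id": w.recording_id,
                    "event_id": w.event_id,
                    "animal_id": w.animal,
                    "role": w.role,
                    "frame_offset": f,
                    "speed_cmps": w.speed[f],
                    "dist_to_center_cm": w.dist_to_center[f],
                    "heading_cos": w.heading_cos[f],
                    "hmm_state": int(st[f]) if st is not None else pd.NA,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HMM


def _window_matrix(windows: list[PreHuddleWindow]) -> tuple[np.ndarray, list[int]]:
    """Stack (speed, distance) per window; NaN speeds filled by interpolation."""
    seqs = []
    for w in windows:
        x = np.column_stack([w.speed, w.dist_to_center])
        for col in range(x.shape[1]):
            bad = ~np.isfinite(x[:, col])
            if bad.any():
                good = np.flatnonzero(~bad)
                if good.size == 0:
                    raise ValueError("window with no finite feature values")
                x[bad, col] = np.interp(np.flatnonzero(bad), good, x[good, col])
        seqs.append(x)
    X = np.concatenate(seqs)
    lengths = [len(s) for s in seqs]
    return X, lengths


def _n_params(K: int, d: int) -> int:
    # startprob (K-1) + transitions K(K-1) + diagonal Gaussian means/variances
    return (K - 1) + K * (K - 1) + 2 * K * d


def stationary_distribution(P: np.ndarray) -> tuple[np.ndarray, bool]:
    """Left fixed point of a row-stochastic matrix; (pi, used_eigen_flag).

    Falls back to the normalized diagonal of P^1000 row-average (empirical
    occupancy of a long run) when no real unit eigenvalue is found.
    """
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(w - 1.0))
    if abs(w[idx] - 1.0) < 1e-8:
        pi = np.real(v[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum(), True
    occ = np.linalg.matrix_power(P, 1000).mean(axis=0)
    return occ / occ.sum(), False


def wpersistence(P: np.ndarray) -> float:
    """Stationary-weighted persistence sum_s pi_s * P_ss of a stochastic matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < -1e-12) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be row-stochastic")
    pi, _ = stationary_distribution(P)
    return float(np.dot(pi, np.diag(P)))


def _fit_single_k(
    X: np.ndarray, lengths: list[int], K: int, n_restarts: int, rng: np.random.Generator
) -> tuple[GaussianHMM, float, bool]:
    best, best_ll, conv = None, -np.inf, False
    for _ in range(max(1, n_restarts)):
        model = GaussianHMM(
            n_components=K,
            covariance_type="diag",
            n_iter=500,
            tol=1e-6,
            min_covar=VARIANCE_FLOOR,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X, lengths)
                ll = model.score(X, lengths)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if ll > best_ll:
            best, best_ll = model, ll
            conv = bool(model.monitor_.converged)
    if best is None:
        raise RuntimeError(f"all EM restarts failed for K={K}")
    return best, best_ll, conv


def fit_hmm_select(
    windows: list[PreHuddleWindow],
    K_range=(2, 3, 4),
    n_restarts: int = 10,
    seed: int = 0,
) -> HmmFit:
    """Fit Gaussian HMMs over pooled (speed, distance) sequences and select K.

    Features are z-scored over the pooled dataset before EM (diagonal
    covariance, variance floor 1e-4 standardized). Each event x role window is
    one sequence. BIC selects K (AIC reported; BIC breaks disagreements).
    States of the selected model are relabeled so the higher-mean-speed state
    is "approaching" and the lower "stationing".
    """
    if len(windows) < 2:
        raise ValueError("at least 2 sequences required")
    X_raw, lengths = _window_matrix(windows)
    mu, sd = X_raw.mean(axis=0), X_raw.std(axis=0)
    degenerate = bool(np.any(sd < 1e-12))
    sd = np.where(sd < 1e-12, 1.0, sd)
    X = (X_raw - mu) / sd
    n, d = X.shape

    rng = np.random.default_rng(seed)
    fits: dict[int, tuple[GaussianHMM, float, bool]] = {}
    aic_by_k, bic_by_k = {}, {}
    for K in K_range:
        model, ll, conv = _fit_single_k(X, lengths, K, n_restarts, rng)
        k_free = _n_params(K, d)
        aic_by_k[K] = 2 * k_free - 2 * ll
        bic_by_k[K] = k_free * np.log(n) - 2 * ll
        fits[K] = (model, ll, conv)
    K_sel = min(bic_by_k, key=bic_by_k.get)
    model, ll, conv = fits[K_sel]

    means = model.means_ * sd + mu  # back to original units
    covars = model.covars_  # hmmlearn exposes full matrices even for diag
    diag = np.diagonal(covars, axis1=1, axis2=2) if covars.ndim == 3 else covars
    variances = diag * sd**2
    speed_order = np.argsort(-means[:, 0])
    labels = {"approaching": int(speed_order[0]), "stationing": int(speed_order[-1])}
    pi, _ = stationary_distribution(model.transmat_)
    return HmmFit(
        K=K_sel,
        means=means,
        variances=np.asarray(variances),
        P=model.transmat_.copy(),
        pi=pi,
        log_likelihood=float(ll),
        aic=float(aic_by_k[K_sel]),
        bic=float(bic_by_k[K_sel]),
        n_obs=n,
        state_labels=labels,
        wpersistence=wpersistence(model.transmat_),
        converged=conv,
        aic_by_k={k: float(v) for k, v in aic_by_k.items()},
        bic_by_k={k: float(v) for k, v in bic_by_k.items()},
        degenerate=degenerate,
        model=model,
        scaler=(mu, sd),
    )


def decode_windows(fit: HmmFit, windows: list[PreHuddleWindow]) -> dict[tuple[int, int], np.ndarray]:
    """Viterbi state path per (event, animal) window under the fitted model."""
    if fit.model is None or fit.scaler is None:
        raise ValueError("fit carries no model to decode with")
    mu, sd = fit.scaler
    out = {}
    for w in windows:
        X, _ = _window_matrix([w])
        _, path = fit.model.decode((X - mu) / sd)
        out[(w.event_id, w.animal)] = path
    return out


# ---------------------------------------------------------------------------
# bootstrap and ratios


def clustered_bootstrap(
    windows_by_animal: dict, B: int = 1000, seed: int = 0, n_restarts: int = 3
) -> BootstrapResult:
    """Animal-level clustered bootstrap of the 2-state HMM's wPersistence.

    Each replicate resamples animals with replacement (same count as the
    number of distinct animals) and refits the K=2 model to all sequences of
    the sampled animals as a unit. Replicates landing on fewer than 2
    sequences are redrawn (counted in ``n_resampled``).
    """
    if not windows_by_animal:
        raise ValueError("animal -> windows map is empty")
    animals = sorted(windows_by_animal)
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            chosen = rng.choice(len(animals), size=len(animals), replace=True)
            ws = [w for i in chosen for w in windows_by_animal[animals[i]]]
            if len(ws) >= 2:
                break
            redrawn += 1
        fit = fit_hmm_select(ws, K_range=(2,), n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        reps[b] = fit.wpersistence
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(
        replicates=reps,
        B=B,
        median=float(np.median(reps)),
        ci95=(float(lo), float(hi)),
        seed=seed,
        n_resampled=redrawn,
    )


def approach_station_ratio(
    states: dict[tuple[int, int], np.ndarray],
    fit: HmmFit,
    windows: list[PreHuddleWindow],
) -> pd.DataFrame:
    """Log ratio of time approaching vs stationing per animal-event window.

    log((frames approaching + 1) / (frames stationing + 1)); the one-frame
    pseudocount avoids division by zero for windows spent wholly in one state.
    """
    app = fit.state_labels["approaching"]
    rows = []
    for w in windows:
        path = states[(w.event_id, w.animal)]
        a = int((path == app).sum())
        s = len(path) - a
        rows.append(
            {
                "recording_id": w.recording_id,
                "animal_id": w.animal,
                "event_id": w.event_id,
                "role": w.role,
                "frames_approaching": a,
                "frames_stationing": s,
                "log_ratio": float(np.log((a + 1) / (s + 1))),
            }
        )
    return pd.DataFrame(rows)
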