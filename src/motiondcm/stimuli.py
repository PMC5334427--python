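"""Ball-trajectory stimulus simulator for the motion-predictability paradigm.

A white ball moves at constant speed inside a rectangular frame under three
reflection regimes of decreasing predictability:

* ``PREDICTABLE`` — specular (billiard) reflection at the frame walls; the
  emergent angle equals the angle of incidence, so the whole trajectory is
  deterministic given the initial state.
* ``RANDOM`` — the ball still changes direction only at the walls, but the
  emergent angle is drawn uniformly over the inward-pointing directions.
* ``ARBITRARY`` — as ``RANDOM``, plus additional direction changes in the
  middle of the frame arriving as a Poisson process with a configurable
  hazard rate.

Trajectories are simulated with *exact* event times (closed-form
time-to-boundary between direction changes) and only discretized for export.
A session is a pseudo-randomized, counterbalanced sequence of 30 blocks
(10 per condition) separated by baselines of 10 s mean duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "FrameGeometry",
    "Block",
    "SessionDesign",
    "Trajectory",
    "EventStream",
    "ScheduleConfig",
    "simulate_block",
    "simulate_session",
    "build_session",
    "count_changes",
    "calibrate_hazard",
    "events_to_frame",
    "schedule_to_frame",
    "DEFAULT_HAZARD_RATE",
]


class Condition(str, Enum):
    PREDICTABLE = "PREDICTABLE"
    RANDOM = "RANDOM"
    ARBITRARY = "ARBITRARY"


#: Midfield hazard rate (events/s) for the ARBITRARY condition, set by
#: :func:`calibrate_hazard` (bisection on simulated sessions) so that
#: ARBITRARY blocks contain ~1.6x the direction changes of PREDICTABLE
#: blocks under the default geometry and schedule.
DEFAULT_HAZARD_RATE = 0.2139

_GRAZING_DEG = 5.0  # emergent angles within 5 deg of a wall are excluded


@dataclass(frozen=True)
class FrameGeometry:
    """Frame and ball geometry in degrees of visual angle.

    The ball's *center* is confined to the effective play area
    ``(width - ball_diameter) x (height - ball_diameter)``.
    """

    width: float = 24.0
    height: float = 16.0
    ball_diameter: float = 2.0
    speed: float = 6.0

    def __post_init__(self) -> None:
        if not (self.width > self.height > self.ball_diameter > 0):
            raise ValueError("require width > height > ball_diameter > 0")
        if self.speed <= 0:
            raise ValueError("speed must be positive")

    @property
    def play_width(self) -> float:
        return self.width - self.ball_diameter

    @property
    def play_height(self) -> float:
        return self.height - self.ball_diameter

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) for the ball center."""
        r = self.ball_diameter / 2.0
        return (r, self.width - r, r, self.height - r)

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)

    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        xmin, xmax, ymin, ymax = self.bounds
        return (xmin - tol <= x <= xmax + tol) and (ymin - tol <= y <= ymax + tol)


@dataclass
class Block:
    condition: Condition
    duration: float
    jitter: float
    onset: float


@dataclass
class SessionDesign:
    """Temporal skeleton of one run: 30 condition blocks with baselines.

    ``baseline_durations[i]`` is the stationary baseline *preceding* block
    ``i`` (the run opens with a baseline as well).
    """

    blocks: list[Block]
    baseline_durations: list[float]

    def __post_init__(self) -> None:
        onsets = [b.onset for b in self.blocks]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")

    @property
    def total_duration(self) -> float:
        last = self.blocks[-1]
        return last.onset + last.duration

    def condition_counts(self) -> dict[Condition, int]:
        out: dict[Condition, int] = {}
        for b in self.blocks:
            out[b.condition] = out.get(b.condition, 0) + 1
        return out


@dataclass
class Trajectory:
    times: np.ndarray  # (N,) s, block-relative
    positions: np.ndarray  # (N, 2) deg
    velocities: np.ndarray  # (N, 2) deg/s

    @property
    def final_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions[-1].copy(), self.velocities[-1].copy()


@dataclass
class EventStream:
    """Direction-change events of one block (times block-relative, sorted)."""

    change_times: np.ndarray  # (K,) s
    change_kinds: list[str]  # "WALL" | "MIDFIELD"

    def __len__(self) -> int:
        return len(self.change_times)


def _time_to_wall(
    p: np.ndarray, v: np.ndarray, bounds: tuple[float, float, float, float]
) -> tuple[float, list[int]]:
    """Exact time until the ball center reaches a wall, and the axis index
    (0 = vertical wall, 1 = horizontal wall) of every wall reached at that
    time (two axes for a corner hit)."""
    xmin, xmax, ymin, ymax = bounds
    ts = [math.inf, math.inf]
    if v[0] > 1e-12:
        ts[0] = (xmax - p[0]) / v[0]
    elif v[0] < -1e-12:
        ts[0] = (xmin - p[0]) / v[0]
    if v[1] > 1e-12:
        ts[1] = (ymax - p[1]) / v[1]
    elif v[1] < -1e-12:
        ts[1] = (ymin - p[1]) / v[1]
    t = min(ts)
    walls = [ax for ax in (0, 1) if ts[ax] - t <= 1e-12 * max(1.0, abs(t))]
    return t, walls


def _random_emergent(
    p: np.ndarray,
    walls: list[int],
    bounds: tuple[float, float, float, float],
    speed: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform emergent direction over the inward directions at a wall (or
    corner), excluding grazing angles within ``_GRAZING_DEG`` of any hit
    wall. Rejection sampling keeps the draw exactly uniform on the allowed
    arc."""
    xmin, xmax, ymin, ymax = bounds
    sin_margin = math.sin(math.radians(_GRAZING_DEG))
    for _ in range(10_000):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        d = np.array([math.cos(phi), math.sin(phi)])
        ok = True
        for ax in walls:
            inward = 1.0 if (p[ax] - (xmin if ax == 0 else ymin)) < 1e-9 else -1.0
            if inward * d[ax] < sin_margin:
                ok = False
                break
        if ok:
            return speed * d
    raise RuntimeError("emergent-angle rejection sampling failed")  # pragma: no cover


def simulate_block(
    condition: Condition | str,
    duration: float,
    geometry: FrameGeometry = FrameGeometry(),
    initial_state: tuple[Sequence[float], Sequence[float]] | None = None,
    hazard_rate: float = DEFAULT_HAZARD_RATE,
    rng: np.random.Generator | None = None,
    sample_hz: float = 100.0,
) -> tuple[Trajectory, EventStream]:
    """Simulate one block of ball motion with exact direction-change times.

    Parameters
    ----------
    condition
        Reflection regime; the hazard rate is used only for ``ARBITRARY``.
    initial_state
        ``(position, velocity)`` of the ball center; defaults to the frame
        center moving in a random direction. The speed of the supplied
        velocity is normalized to ``geometry.speed``.
    sample_hz
        Export rate of the (piecewise-linear) trajectory; event times stay
        exact regardless.
    """
    condition = Condition(condition)
    rng = np.random.default_rng() if rng is None else rng
    if hazard_rate < 0:
        raise ValueError("hazard_rate must be >= 0")
    bounds = geometry.bounds

    if initial_state is None:
        p = np.array(geometry.center, dtype=float)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        v = geometry.speed * np.array([math.cos(phi), math.sin(phi)])
    else:
        p = np.asarray(initial_state[0], dtype=float).copy()
        v = np.asarray(initial_state[1], dtype=float).copy()
        nv = float(np.hypot(*v))
        if nv == 0:
            raise ValueError("initial velocity must be nonzero")
        v *= geometry.speed / nv
    if not geometry.contains(p[0], p[1]):
        raise ValueError(f"initial position {p} outside the play area")

    if duration == 0:
        traj = Trajectory(np.array([0.0]), p[None, :].copy(), v[None, :].copy())
        return traj, EventStream(np.empty(0), [])
    if duration < 0:
        raise ValueError("duration must be >= 0")

    # breakpoints of the piecewise-linear path
    bp_t: list[float] = [0.0]
    bp_p: list[np.ndarray] = [p.copy()]
    bp_v: list[np.ndarray] = [v.copy()]
    ev_t: list[float] = []
    ev_k: list[str] = []

    t = 0.0
    use_hazard = condition is Condition.ARBITRARY and hazard_rate > 0
    while True:
        t_wall, walls = _time_to_wall(p, v, bounds)
        t_mid = rng.exponential(1.0 / hazard_rate) if use_hazard else math.inf
        t_step = min(t_wall, t_mid)
        if t + t_step >= duration:
            p = p + v * (duration - t)
            bp_t.append(duration)
            bp_p.append(p.copy())
            bp_v.append(v.copy())
            break
        t += t_step
        p = p + v * t_step
        if t_mid < t_wall:
            ev_k.append("MIDFIELD")
            phi = rng.uniform(0.0, 2.0 * math.pi)
            v = geometry.speed * np.array([math.cos(phi), math.sin(phi)])
        else:
            ev_k.append("WALL")
            if condition is Condition.PREDICTABLE:
                for ax in walls:
                    v[ax] = -v[ax]
            else:
                v = _random_emergent(p, walls, bounds, geometry.speed, rng)
        ev_t.append(t)
        bp_t.append(t)
        bp_p.append(p.copy())
        bp_v.append(v.copy())

    traj = _sample_path(np.array(bp_t), np.array(bp_p), np.array(bp_v), duration, sample_hz)
    return traj, EventStream(np.array(ev_t), ev_k)


def _sample_path(
    bp_t: np.ndarray, bp_p: np.ndarray, bp_v: np.ndarray, duration: float, sample_hz: float
) -> Trajectory:
    n = int(math.floor(duration * sample_hz)) + 1
    times = np.arange(n) / sample_hz
    if times[-1] < duration - 1e-12:
        times = np.append(times, duration)
    seg = np.clip(np.searchsorted(bp_t, times, side="right") - 1, 0, len(bp_t) - 2)
    dt = times - bp_t[seg]
    pos = bp_p[seg] + bp_v[seg] * dt[:, None]
    return Trajectory(times, pos, bp_v[seg].copy())


# ---------------------------------------------------------------------------
# session schedule


@dataclass(frozen=True)
class ScheduleConfig:
    """Counterbalanced block schedule of one run."""

    n_blocks: int = 30
    durations: tuple[float, ...] = (20.0, 20.5, 21.5)
    jitters: tuple[float, ...] = (0.0, 0.5, 1.5)
    baselines: tuple[float, ...] = (8.5, 10.0, 11.5)  # mean exactly 10 s


def _counterbalanced_multiset(
    values: tuple[float, ...], n_per_cond: int, rotation: int
) -> list[float]:
    """Deal `n_per_cond` draws over `values`; the remainder (when the count
    does not divide evenly) is assigned cyclically, rotated per condition so
    no level is systematically favored."""
    k = len(values)
    base, rem = divmod(n_per_cond, k)
    counts = [base] * k
    for j in range(rem):
        counts[(j + rotation) % k] += 1
    out: list[float] = []
    for val, c in zip(values, counts):
        out.extend([val] * c)
    return out


def build_session(
    config: ScheduleConfig = ScheduleConfig(), rng: np.random.Generator | None = None
) -> SessionDesign:
    """Build a pseudo-randomized, counterbalanced session.

    Exactly ``n_blocks/3`` blocks per condition; durations, jitters and
    baselines are counterbalanced within condition (identical multisets up
    to the cyclic rotation that distributes the remainder of 10 over 3
    levels); the condition order is a seeded permutation.
    """
    rng = np.random.default_rng() if rng is None else rng
    conds = list(Condition)
    if config.n_blocks % len(conds) != 0:
        raise ValueError("n_blocks must be divisible by the number of conditions")
    npc = config.n_blocks // len(conds)

    order = np.array([i for i in range(len(conds)) for _ in range(npc)])
    rng.shuffle(order)

    per_cond: dict[int, dict[str, list[float]]] = {}
    for ci in range(len(conds)):
        d = _counterbalanced_multiset(config.durations, npc, ci)
        j = _counterbalanced_multiset(config.jitters, npc, ci)
        b = _counterbalanced_multiset(config.baselines, npc, ci)
        rng.shuffle(d), rng.shuffle(j), rng.shuffle(b)
        per_cond[ci] = {"dur": d, "jit": j, "base": b}

    blocks: list[Block] = []
    baselines: list[float] = []
    taken = {ci: 0 for ci in range(len(conds))}
    t = 0.0
    for ci in order:
        ci = int(ci)
        k = taken[ci]
        taken[ci] += 1
        dur = per_cond[ci]["dur"][k]
        jit = per_cond[ci]["jit"][k]
        base = per_cond[ci]["base"][k]
        t += base + jit
        blocks.append(Block(conds[ci], dur, jit, onset=t))
        baselines.append(base)
        t += dur
    return SessionDesign(blocks, baselines)


def simulate_session(
    design: SessionDesign,
    geometry: FrameGeometry = FrameGeometry(),
    hazard_rate: float = DEFAULT_HAZARD_RATE,
    rng: np.random.Generator | None = None,
    sample_hz: float = 100.0,
) -> pd.DataFrame:
    """Simulate the ball through a whole session, chaining the state across
    blocks (during baselines the ball rests at its last position).

    Returns a tidy event table with columns ``onset_s`` (session time),
    ``kind`` and ``condition``.
    """
    rng = np.random.default_rng() if rng is None else rng
    p = np.array(geometry.center, dtype=float)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    v = geometry.speed * np.array([math.cos(phi), math.sin(phi)])
    rows: list[tuple[float, str, str]] = []
    for block in design.blocks:
        traj, events = simulate_block(
            block.condition,
            block.duration,
            geometry,
            initial_state=(p, v),
            hazard_rate=hazard_rate,
            rng=rng,
            sample_hz=sample_hz,
        )
        p, v = traj.final_state
        for t, kind in zip(events.change_times, events.change_kinds):
            rows.append((block.onset + t, kind, block.condition.value))
    return pd.DataFrame(rows, columns=["onset_s", "kind", "condition"])


def count_changes(events: pd.DataFrame, design: SessionDesign) -> pd.DataFrame:
    """Per-condition totals and per-block mean/SD of direction changes.

    ``events`` is the tidy table from :func:`simulate_session`.
    """
    n_per_cond: dict[str, int] = {}
    for b in design.blocks:
        n_per_cond[b.condition.value] = n_per_cond.get(b.condition.value, 0) + 1
    # per-block counts, including blocks with zero events
    per_block: dict[str, list[int]] = {c: [] for c in n_per_cond}
    for b in design.blocks:
        lo, hi = b.onset, b.onset + b.duration
        m = ((events["onset_s"] >= lo - 1e-9) & (events["onset_s"] <= hi + 1e-9)).sum()
        per_block[b.condition.value].append(int(m))
    rows = []
    for cond in [c.value for c in Condition]:
        counts = np.array(per_block.get(cond, [0]))
        rows.append(
            {
                "condition": cond,
                "total": int(counts.sum()),
                "mean_per_block": float(counts.mean()),
                "sd_per_block": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def _session_change_ratio(
    hazard: float,
    n_sessions: int,
    geometry: FrameGeometry,
    config: ScheduleConfig,
    seed: int,
) -> float:
    """ARBITRARY / PREDICTABLE total direction changes over seeded sessions."""
    arb = pred = 0
    for s in range(n_sessions):
        rng = np.random.default_rng((seed, s))
        design = build_session(config, rng)
        events = simulate_session(design, geometry, hazard_rate=hazard, rng=rng)
        tab = count_changes(events, design)
        arb += tab.loc["ARBITRARY", "total"]
        pred += tab.loc["PREDICTABLE", "total"]
    return arb / pred


def calibrate_hazard(
    target_ratio: float = 1.6,
    geometry: FrameGeometry = FrameGeometry(),
    config: ScheduleConfig = ScheduleConfig(),
    n_sessions: int = 20,
    seed: int = 0,
    lo: float = 0.0,
    hi: float = 2.0,
    n_iter: int = 14,
) -> float:
    """Find the midfield hazard rate that makes ARBITRARY blocks contain
    ``target_ratio`` times the direction changes of PREDICTABLE blocks.

    Bisection on the (monotone in hazard) simulated change ratio, using
    common random numbers across evaluations so the objective is
    deterministic given ``seed``.
    """
    f_lo = _session_change_ratio(lo, n_sessions, geometry, config, seed) - target_ratio
    f_hi = _session_change_ratio(hi, n_sessions, geometry, config, seed) - target_ratio
    if f_lo > 0 or f_hi < 0:
        raise ValueError("target ratio not bracketed by [lo, hi]")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _session_change_ratio(mid, n_sessions, geometry, config, seed) - target_ratio
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# export


def events_to_frame(events: pd.DataFrame) -> pd.DataFrame:
    """3-column direction-change event table (onset_s, kind, condition)."""
    return events[["onset_s", "kind", "condition"]].sort_values("onset_s").reset_index(drop=True)


def schedule_to_frame(design: SessionDesign) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type) of the blocks."""
    return pd.DataFrame(
        {
            "onset": [b.onset for b in design.blocks],
            "duration": [b.duration for b in design.blocks],
            "trial_type": [b.condition.value for b in design.blocks],
        }
    )
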