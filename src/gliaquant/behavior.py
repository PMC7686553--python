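"""Trajectory-derived behavioural metrics.

Covers binned path length, epoch velocity, rotation counting for
stereotypy, and Y-maze spontaneous alternation scoring with the
field-standard rules: an arm entry requires the central body point to pass
20% of the arm length, repeated passages from the centre into the same arm
collapse to a single exploration, and animals with fewer than 20
alternations are flagged for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "YMazeGeometry",
    "CircularArena",
    "ArmEntry",
    "binned_distance",
    "epoch_velocity",
    "count_rotations",
    "extract_arm_entries",
    "score_alternations",
    "AlternationScore",
]


@dataclass
class CircularArena:
    radius_cm: float = 20.0

    def contains(self, x: float, y: float, tol: float = 1e-6) -> bool:
        return math.hypot(x, y) <= self.radius_cm + tol


@dataclass
class YMazeGeometry:
    """Three arms of equal length at 120 degrees, joined at the origin."""

    arm_length_cm: float = 30.0
    arm_width_cm: float = 7.0
    arm_labels: tuple[str, str, str] = ("A", "B", "C")

    def arm_direction(self, label: str) -> np.ndarray:
        idx = self.arm_labels.index(label)
        ang = math.radians(90.0 + 120.0 * idx)
        return np.array([math.cos(ang), math.sin(ang)])

    def arm_and_depth(self, x: float, y: float) -> tuple[str | None, float]:
        """Arm containing the point and penetration depth as a fraction of
        the arm length (0 at the junction); ``(None, 0)`` in the centre."""
        best: tuple[str | None, float] = (None, 0.0)
        p = np.array([x, y])
        for label in self.arm_labels:
            u = self.arm_direction(label)
            proj = float(p @ u)
            perp = abs(float(p[0] * u[1] - p[1] * u[0]))
            if 0.0 < proj <= self.arm_length_cm + 1e-6 and perp <= self.arm_width_cm / 2:
                if proj > best[1] * self.arm_length_cm:
                    best = (label, proj / self.arm_length_cm)
        return best

    def contains(self, x: float, y: float, tol: float = 1e-6) -> bool:
        if math.hypot(x, y) <= self.arm_width_cm + tol:  # junction
            return True
        arm, _ = self.arm_and_depth(x, y)
        return arm is not None


@dataclass
class Trajectory:
    """Timestamped planar path of one animal's central body point (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate_hz: float
    arena: CircularArena | YMazeGeometry | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))


def binned_distance(traj: Trajectory, bin_s: float = 600.0) -> pd.DataFrame:
    """Path length per time bin (default 10 min bins from the first sample).

    Each step contributes to the bin containing its start time, making the
    binned distances exactly additive over concatenated windows.  A single
    sample yields one zero bin flagged partial.
    """
    if len(traj.t) < 2:
        return pd.DataFrame(
            {"bin_start_s": [traj.t[0] if len(traj.t) else 0.0],
             "distance_cm": [0.0], "partial": [True]}
        )
    t0 = traj.t[0]
    steps = traj.step_lengths()
    idx = np.floor((traj.t[:-1] - t0) / bin_s).astype(int)
    n_bins = idx.max() + 1
    dist = np.zeros(n_bins)
    np.add.at(dist, idx, steps)
    starts = t0 + np.arange(n_bins) * bin_s
    partial = starts + bin_s > traj.t[-1] + 1e-9
    return pd.DataFrame({"bin_start_s": starts, "distance_cm": dist, "partial": partial})


def epoch_velocity(
    traj: Trajectory, epochs: Sequence[tuple[float, float]]
) -> pd.DataFrame:
    """Mean speed (cm/s) over each ``(t_start, t_end)`` epoch."""
    rows = []
    steps = traj.step_lengths()
    for t0, t1 in epochs:
        if t1 <= t0:
            raise ValueError("epoch end must exceed start")
        in_ep = (traj.t[:-1] >= t0) & (traj.t[:-1] < t1)
        rows.append(
            {"t_start_s": t0, "t_end_s": t1,
             "velocity_cm_s": float(steps[in_ep].sum()) / (t1 - t0)}
        )
    return pd.DataFrame(rows)


def count_rotations(
    traj: Trajectory, min_radius_cm: float = 2.0, noise_floor_cm: float = 0.5
) -> int:
    """Count full-circle rotations from unwrapped heading change.

    One rotation is scored for every accumulated 360 deg of heading change
    in a consistent direction; a heading reversal exceeding 90 deg resets
    the accumulator, and a completed circle only counts when the loop's
    spatial extent reaches ``min_radius_cm``.  Rotations are unsigned, so a
    figure-eight scores two.  Displacements below ``noise_floor_cm`` are
    skipped when computing headings.
    """
    pts = np.c_[traj.x, traj.y]
    kept = [pts[0]]
    for p in pts[1:]:
        if np.hypot(*(p - kept[-1])) >= noise_floor_cm:
            kept.append(p)
    if len(kept) < 3:
        return 0
    kept_arr = np.array(kept)
    d = np.diff(kept_arr, axis=0)
    headings = np.arctan2(d[:, 1], d[:, 0])
    dth = np.diff(headings)
    # closed path: include the turning across the closure point, so a
    # circle traversed k times accumulates exactly k * 360 degrees
    if np.hypot(*(pts[-1] - pts[0])) <= noise_floor_cm:
        dth = np.append(dth, headings[0] - headings[-1])
    dth = (dth + math.pi) % (2 * math.pi) - math.pi
    acc = 0.0
    reversal = 0.0
    count = 0
    loop_start = 0
    for i, step in enumerate(dth):
        if acc != 0.0 and np.sign(step) != 0 and np.sign(step) != np.sign(acc):
            reversal += abs(step)
            if reversal > math.pi / 2:
                # direction flip: restart accumulation with the turning
                # already made in the new direction
                acc = np.sign(step) * reversal
                reversal = 0.0
                loop_start = i + 1
            continue
        reversal = 0.0
        acc += step
        if abs(acc) >= 2 * math.pi - 1e-9:
            loop = kept_arr[loop_start : i + 3]
            radius = np.max(np.hypot(*(loop - loop.mean(axis=0)).T))
            if radius >= min_radius_cm:
                count += 1
            acc -= np.sign(acc) * 2 * math.pi
            loop_start = i + 1
    return count


@dataclass
class ArmEntry:
    arm: str
    t_entry_s: float
    max_depth: float


def extract_arm_entries(
    traj: Trajectory,
    maze: YMazeGeometry | None = None,
    depth_rule: float = 0.2,
    exit_depth: float = 0.05,
) -> list[ArmEntry]:
    """Registered arm entries under the depth and same-arm-collapse rules.

    An entry is registered when penetration first reaches ``depth_rule`` of
    the arm length; returning to the same arm without an intervening entry
    into a different arm counts as the same single-arm exploration.
    """
    maze = maze or (traj.arena if isinstance(traj.arena, YMazeGeometry) else YMazeGeometry())
    entries: list[ArmEntry] = []
    in_arm: str | None = None  # arm currently occupied beyond exit_depth
    for t, x, y in zip(traj.t, traj.x, traj.y):
        arm, depth = maze.arm_and_depth(x, y)
        if in_arm is not None and (arm != in_arm or depth < exit_depth):
            in_arm = None
        if arm is not None and depth >= depth_rule and in_arm != arm:
            in_arm = arm
            if entries and entries[-1].arm == arm:
                entries[-1].max_depth = max(entries[-1].max_depth, depth)
            else:
                entries.append(ArmEntry(arm=arm, t_entry_s=float(t), max_depth=depth))
        elif in_arm is not None and arm == in_arm and entries:
            entries[-1].max_depth = max(entries[-1].max_depth, depth)
    return entries


@dataclass
class AlternationScore:
    total_entries: int
    total_alternations: int  # arm changes
    successful_alternations: int  # sliding triplets with 3 distinct arms
    alternation_pct: float | None
    excluded: bool


def score_alternations(
    entries: Sequence[ArmEntry] | Sequence[str], min_alternations: int = 20
) -> AlternationScore:
    """Spontaneous alternation score from an ordered arm-entry sequence.

    ``successful_alternations`` counts sliding windows of three consecutive
    entries visiting three distinct arms; the percentage is taken over the
    ``n_entries - 2`` available windows and is undefined (None) for fewer
    than three entries.  Animals below ``min_alternations`` arm changes are
    flagged ``excluded``.
    """
    arms = [e.arm if isinstance(e, ArmEntry) else str(e) for e in entries]
    n = len(arms)
    changes = sum(1 for a, b in zip(arms[:-1], arms[1:]) if a != b)
    triplets = sum(
        1 for i in range(n - 2) if len({arms[i], arms[i + 1], arms[i + 2]}) == 3
    )
    pct = 100.0 * triplets / (n - 2) if n >= 3 else None
    return AlternationScore(
        total_entries=n,
        total_alternations=changes,
        successful_alternations=triplets if n >= 3 else 0,
        alternation_pct=pct,
        excluded=changes < min_alternations,
    )
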