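"""Microglial binarization, skeletonization and non-isolated 2D Sholl.

Cortical microglia tile the tissue as an interlocking network whose
individual arbors cannot be cleanly isolated in thin slices, so the Sholl
analysis here runs on the skeleton of the *whole* network: circles around a
soma keep gaining branches from neighbouring cells, making the crossing
count grow roughly linearly with radius.  Subtracting the identity line
y = x exposes deviations from that linear growth, and zone statistics
compare the single-cell territory (0-20 um by default) with the
inter-cellular territory (20-40 um) between groups.

A "crossing" at radius r is a maximal connected run of skeleton-foreground
pixels along the discretized circle of radius r: the midpoint-circle pixel
ring, traversed in angular order, with runs wrapping the 0/2pi seam merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from skimage.morphology import skeletonize as _sk_skeletonize

from .stats_report import compare_two

__all__ = [
    "Skeleton",
    "ShollProfile",
    "binarize",
    "skeletonize",
    "ramification_metrics",
    "midpoint_ring",
    "sholl_2d",
    "identity_baseline",
    "zone_statistics",
]


@dataclass
class Skeleton:
    """One-pixel-wide binary ramification network."""

    pixels: np.ndarray  # bool (Y, X)
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, bool)
        if self.pixels.ndim != 2:
            raise ValueError("skeleton must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class ShollProfile:
    center_um: tuple[float, float]
    radii_um: np.ndarray
    crossings: np.ndarray  # nonnegative ints per radius
    dim: str = "2D"
    partial: np.ndarray | None = None  # True where the circle left the image
    baseline_adjusted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, float)
        self.crossings = np.asarray(self.crossings)
        if np.any(np.diff(self.radii_um) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.crossings < 0):
            raise ValueError("crossing counts must be nonnegative")


def binarize(
    image: np.ndarray, method: str = "otsu", manual_level: float | None = None
) -> tuple[np.ndarray, float]:
    """Threshold a single-channel image; returns (mask, level used)."""
    from skimage.filters import threshold_otsu

    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("binarize expects a single-channel 2D image")
    if manual_level is not None:
        return image > manual_level, float(manual_level)
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    if image.max() == image.min():
        raise ValueError("flat image: Otsu undefined, supply manual_level")
    level = float(threshold_otsu(image))
    return image > level, level


def skeletonize(mask: np.ndarray, pixel_size_um: float = 1.0) -> Skeleton:
    """Topology-preserving thinning to a 1-pixel-wide medial skeleton."""
    mask = np.asarray(mask, bool)
    return Skeleton(pixels=_sk_skeletonize(mask), pixel_size_um=pixel_size_um)


def ramification_metrics(
    image: np.ndarray, mask: np.ndarray, skeleton: Skeleton
) -> dict[str, float]:
    """Field-level ramification summary: percentage of pixels occupied by
    the skeleton, by the thresholded mask, and the whole-field mean gray."""
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    if image.shape != mask.shape or image.shape != skeleton.pixels.shape:
        raise ValueError("image, mask and skeleton must share one grid")
    n = image.size
    return {
        "skeleton_area_pct": 100.0 * skeleton.pixels.sum() / n,
        "threshold_area_pct": 100.0 * mask.sum() / n,
        "mean_gray": float(image.mean()),
    }


@lru_cache(maxsize=512)
def midpoint_ring(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Angle-ordered (dx, dy) offsets of the midpoint circle of integer
    radius; the ring is an 8-connected closed curve."""
    if radius_px < 1:
        raise ValueError("radius must be >= 1 pixel")
    pts: set[tuple[int, int]] = set()
    x, y, d = radius_px, 0, 1 - radius_px
    while x >= y:
        pts.update(
            [(x, y), (y, x), (-x, y), (-y, x), (x, -y), (y, -x), (-x, -y), (-y, -x)]
        )
        y += 1
        if d < 0:
            d += 2 * y + 1
        else:
            x -= 1
            d += 2 * (y - x) + 1
    arr = np.array(sorted(pts, key=lambda p: math.atan2(p[1], p[0])))
    return arr[:, 0].copy(), arr[:, 1].copy()


def _ring_runs(flags: np.ndarray) -> int:
    """Maximal runs of True along a cyclic sequence (seam merged)."""
    if not flags.any():
        return 0
    if flags.all():
        return 1
    return int(np.count_nonzero(flags & ~np.roll(flags, 1)))


def sholl_2d(
    skeleton: Skeleton,
    center_um: tuple[float, float],
    r_max_um: float = 40.0,
    dr_um: float = 1.0,
) -> ShollProfile:
    """Crossings of the skeleton with concentric discretized circles.

    For each radius on the ``dr`` grid the midpoint-circle pixel ring is
    traversed in angular order and maximal foreground runs are counted;
    ring pixels outside the image are treated as background and flag the
    radius as partial (the count then covers the in-bounds arc only).
    """
    if dr_um <= 0 or r_max_um < dr_um:
        raise ValueError("need r_max >= dr > 0")
    p = skeleton.pixel_size_um
    ny, nx = skeleton.pixels.shape
    cx = int(round(center_um[0] / p - 0.5))
    cy = int(round(center_um[1] / p - 0.5))
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError("Sholl center lies outside the image")
    radii = np.arange(dr_um, r_max_um + dr_um / 2, dr_um)
    crossings = np.zeros(len(radii), dtype=int)
    partial = np.zeros(len(radii), dtype=bool)
    for i, r in enumerate(radii):
        r_px = int(round(r / p))
        if r_px < 1:
            continue
        dxs, dys = midpoint_ring(r_px)
        xs, ys = cx + dxs, cy + dys
        inb = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny)
        flags = np.zeros(len(xs), dtype=bool)
        flags[inb] = skeleton.pixels[ys[inb], xs[inb]]
        crossings[i] = _ring_runs(flags)
        partial[i] = not inb.all()
    return ShollProfile(
        center_um=tuple(center_um), radii_um=radii, crossings=crossings, partial=partial
    )


def identity_baseline(profile: ShollProfile) -> ShollProfile:
    """Attach the identity-adjusted curve: crossings(r) - r (r in um).

    Pure transformation: crossings are untouched and adding the radius
    back recovers them exactly.
    """
    if profile.dim != "2D":
        raise ValueError("identity baseline applies to 2D profiles")
    return replace(profile, baseline_adjusted=profile.crossings - profile.radii_um)


@dataclass
class ZoneSummary:
    group: str
    zone_um: tuple[float, float]
    per_center_mean: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_center_mean = np.asarray(self.per_center_mean, float)
        self.mean = float(self.per_center_mean.mean())


def zone_statistics(
    profiles_by_group: dict[str, list[ShollProfile]],
    zones: tuple[tuple[float, float], ...] = ((0.0, 20.0), (20.0, 40.0)),
) -> tuple[list[ZoneSummary], pd.DataFrame]:
    """Per-centre zone means and a two-group rank test per radial zone.

    Zones are half-open ``[lo, hi)`` in um and must be ordered and
    non-overlapping.  Exactly two groups are compared with a two-sided
    Mann-Whitney U test (exact for <= 8 centres per group without ties,
    tie-corrected normal approximation otherwise).
    """
    for (a_lo, a_hi), (b_lo, b_hi) in zip(zones[:-1], zones[1:]):
        if a_hi > b_lo:
            raise ValueError("zones must be ordered and non-overlapping")
    if len(profiles_by_group) != 2:
        raise ValueError("zone statistics compare exactly two groups")
    for g, profs in profiles_by_group.items():
        if len(profs) < 2:
            raise ValueError(f"group {g!r} needs >= 2 centers")
    summaries: list[ZoneSummary] = []
    rows = []
    (ga, profs_a), (gb, profs_b) = profiles_by_group.items()
    for zone in zones:
        per_group = {}
        for g, profs in ((ga, profs_a), (gb, profs_b)):
            means = np.array([_zone_mean(p, zone) for p in profs])
            per_group[g] = means
            summaries.append(ZoneSummary(group=g, zone_um=zone, per_center_mean=means))
        u, pval = compare_two(per_group[ga], per_group[gb], test="mannwhitney")
        rows.append(
            {"zone_lo_um": zone[0], "zone_hi_um": zone[1], "U": u, "p": pval,
             f"mean_{ga}": per_group[ga].mean(), f"mean_{gb}": per_group[gb].mean()}
        )
    return summaries, pd.DataFrame(rows)


def _zone_mean(profile: ShollProfile, zone: tuple[float, float]) -> float:
    lo, hi = zone
    sel = (profile.radii_um >= lo) & (profile.radii_um < hi)
    if not sel.any():
        raise ValueError("zone contains no profile radii")
    return float(profile.crossings[sel].mean())
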