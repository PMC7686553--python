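"""Synthetic cortical image stacks, trajectories and release series.

Every generator draws from a single integer seed.  Internally the seed is
split into named substreams (nuclei, somata, arbors, intercellular segments,
attraction segments, noise) so that two runs differing in one parameter
share all draws for the unaffected components: cohorts that "differ only in
inter-cellular branch density" then really do differ only there.

The imaging generator renders three channels:

``neun``
    every neuronal nucleus, at a fixed marker intensity;
``cfos``
    activated nuclei only (classes ``cfos_plus`` / ``cfos_plusplus``), each
    as a flat-top ellipse at its drawn immunointensity;
``microglia``
    somata plus branching arbors of a ramified network, with a separately
    controllable density of inter-cellular segments in the 20-40 um annulus
    around each soma.

Nuclei are rendered with a constant fill intensity inside the ellipse so
that the thresholded-object measurements made downstream (projected area in
um^2, mean gray over the object mask) reproduce the generator's own draws
exactly at zero noise.  Ground-truth activation labels are assigned from the
*rendered* object (pixel-count area, fill intensity) under the standard
dual threshold (area > 200 um^2 and mean gray > 400), so the labels are
sound by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line

from .core import CortexLayout, ImageStack
from .behavior import Trajectory, YMazeGeometry, CircularArena
from .release import ReleaseSeries

__all__ = [
    "SimParams",
    "GroundTruth",
    "NucleusTruth",
    "generate_cortex_stack",
    "generate_trajectory",
    "ymaze_visit_waypoints",
    "generate_release_series",
]

ACTIVATION_CLASSES = ("negative", "cfos_plus", "cfos_plusplus")

# dual threshold used to certify generated labels (area um^2, mean gray)
LABEL_AREA_UM2 = 200.0
LABEL_INTENSITY = 400.0


@dataclass
class SimParams:
    """Knobs of the cortical field generator.

    Class intensity means must be ordered negative < cfos_plus <
    cfos_plusplus; the defaults put the two activated classes on either
    side of the 400 mean-gray cut, with areas straddling 200 um^2 so the
    dual threshold separates them.
    """

    nucleus_count: dict[str, int] = field(
        default_factory=lambda: {"negative": 20, "cfos_plus": 20, "cfos_plusplus": 20}
    )
    intensity_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "negative": (80.0, 15.0),
            "cfos_plus": (300.0, 35.0),
            "cfos_plusplus": (560.0, 55.0),
        }
    )
    area_mean_sd_um2: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "negative": (180.0, 25.0),
            "cfos_plus": (265.0, 35.0),
            "cfos_plusplus": (300.0, 35.0),
        }
    )
    soma_density_per_mm2: float = 235.0  # ~65 um quasi-regular spacing
    single_cell_radius_um: float = 20.0
    intercell_branch_density: float = 1.0
    n_intercell_base: int = 6  # segments per soma at density 1.0
    n_primary_branches: int = 4
    branch_prob: float = 0.35
    segment_length_um: float = 6.0
    tortuosity_deg: float = 22.0
    activation_attraction: int = 0  # extra segments per activated nucleus
    attraction_radius_um: float = 8.0
    noise_sd: float = 25.0
    # immunopositive nuclei are rendered no dimmer than this, keeping them
    # above the auto-threshold the background/foreground mix produces
    min_render_intensity: float = 240.0
    neun_intensity: float = 350.0
    branch_intensity: float = 500.0
    soma_intensity: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.nucleus_count.values()):
            raise ValueError("nucleus counts must be >= 0")
        if self.soma_density_per_mm2 < 0 or self.intercell_branch_density < 0:
            raise ValueError("densities must be >= 0")
        m = self.intensity_mean_sd
        if not (m["negative"][0] < m["cfos_plus"][0] < m["cfos_plusplus"][0]):
            raise ValueError("class intensity means must be ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class NucleusTruth:
    center_um: tuple[float, ...]
    area_um2: float  # rendered (pixel-count) projected area
    mean_intensity: float
    peak_intensity: float
    activation_class: str
    layer: str
    attracted: bool = False


@dataclass
class GroundTruth:
    nuclei: list[NucleusTruth]
    somata_um: np.ndarray  # (N, ndim)
    branch_segments_um: list[np.ndarray]  # each (2, ndim) endpoint pairs
    rng_seed: int


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


# ---------------------------------------------------------------------------
# cortical stack


def _place_nuclei(rng, params: SimParams, layout: CortexLayout, nz: int):
    """Rejection-sample non-overlapping nucleus centres inside the layers."""
    px = layout.voxel_size_um[0]
    x_lo = layout.midline_offset_um + 5.0
    x_hi = layout.midline_offset_um + layout.total_width_um - 5.0
    y_lo, y_hi = 5.0, layout.field_size_um[1] - 5.0
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ValueError("field too small to place nuclei")
    placed: list[tuple[np.ndarray, float, str, float, float]] = []
    order = [c for c in ACTIVATION_CLASSES for _ in range(params.nucleus_count.get(c, 0))]
    for cls in order:
        a_mu, a_sd = params.area_mean_sd_um2[cls]
        i_mu, i_sd = params.intensity_mean_sd[cls]
        for _attempt in range(4000):
            area = max(30.0, rng.normal(a_mu, a_sd))
            inten = max(5.0, rng.normal(i_mu, i_sd))
            # activated classes must land on their side of the dual cut
            if cls != "negative" and inten < params.min_render_intensity:
                continue
            if cls == "cfos_plusplus" and not (
                area > LABEL_AREA_UM2 + 4 * px**2 and inten > LABEL_INTENSITY + 1
            ):
                continue
            if cls == "cfos_plus" and (
                area > LABEL_AREA_UM2 - 4 * px**2 and inten > LABEL_INTENSITY - 1
            ):
                continue
            r_um = math.sqrt(area / math.pi) * 1.15  # eccentric major axis
            c = np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)])
            if all(
                np.hypot(*(c - p[0])) > r_um + p[1] + 2.0 for p in placed
            ):
                placed.append((c, r_um, cls, area, inten))
                break
        else:
            raise ValueError(
                "field too small for requested nucleus counts (placement failed)"
            )
    return placed


def _render_ellipse(channel: np.ndarray, center_um, area_um2, theta, px, nz_slices):
    """Flat-top ellipse; returns the pixel mask indices and rendered area."""
    r_eq = math.sqrt(area_um2 / math.pi)
    a_px = r_eq * 1.12 / px
    b_px = r_eq / 1.12 / px
    rr, cc = _draw_ellipse(
        center_um[1] / px - 0.5,
        center_um[0] / px - 0.5,
        a_px,
        b_px,
        shape=channel.shape[-2:],
        rotation=theta,
    )
    return rr, cc


def generate_cortex_stack(
    params: SimParams, layout: CortexLayout, nz: int | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render a 3-channel synthetic cortical field with full ground truth.

    Returns a stack with channels ``("neun", "cfos", "microglia")`` of
    shape ``(3, nz, ny, nx)`` (``nz`` from the layout z-extent unless
    given) and the exact list of rendered objects.  Identical
    ``(params, layout)`` produce bit-identical output.
    """
    dx, dy, dz = layout.voxel_size_um
    if abs(dx - dy) > 1e-9:
        raise ValueError("in-plane voxel size must be square")
    px = dx
    nx = int(round(layout.field_size_um[0] / dx))
    ny = int(round(layout.field_size_um[1] / dy))
    if nz is None:
        nz = max(1, int(round(layout.field_size_um[2] / dz)))
    if nx < 8 or ny < 8:
        raise ValueError("field too small")

    rngs = _substreams(
        params.seed, ["nuclei", "somata", "arbors", "intercell", "attraction", "noise"]
    )
    data = np.zeros((3, nz, ny, nx), dtype=np.float64)
    neun, cfos, micro = data

    # --- nuclei -----------------------------------------------------------
    truths: list[NucleusTruth] = []
    total_nuclei = sum(params.nucleus_count.values())
    if total_nuclei:
        placed = _place_nuclei(rngs["nuclei"], params, layout, nz)
        z_slices = _nucleus_z_slices(nz)
        for c, r_um, cls, area, inten in placed:
            theta = rngs["nuclei"].uniform(0, math.pi)
            rr, cc = _render_ellipse(neun, c, area, theta, px, nz)
            if rr.size == 0:
                raise ValueError("nucleus rendered outside the field")
            for z in z_slices:
                neun[z, rr, cc] = np.maximum(neun[z, rr, cc], params.neun_intensity)
            rendered_area = rr.size * px * px
            if cls != "negative":
                for z in z_slices:
                    cfos[z, rr, cc] = np.maximum(cfos[z, rr, cc], inten)
                label = (
                    "cfos_plusplus"
                    if rendered_area > LABEL_AREA_UM2 and inten > LABEL_INTENSITY
                    else "cfos_plus"
                )
            else:
                label = "negative"
            zc = (z_slices[len(z_slices) // 2] + 0.5) * dz
            center = (float(c[0]), float(c[1])) if nz == 1 else (float(c[0]), float(c[1]), zc)
            truths.append(
                NucleusTruth(
                    center_um=center,
                    area_um2=rendered_area,
                    mean_intensity=float(inten) if cls != "negative" else 0.0,
                    peak_intensity=float(inten) if cls != "negative" else 0.0,
                    activation_class=label,
                    layer=layout.layer_of(float(c[0])),
                )
            )

    # --- microglial network ----------------------------------------------
    somata = _soma_grid(rngs["somata"], params, layout)
    segments: list[np.ndarray] = []
    for s in somata:
        segments.extend(
            _grow_arbor(
                rngs["arbors"],
                s,
                params.n_primary_branches,
                params.segment_length_um,
                params.branch_prob,
                math.radians(params.tortuosity_deg),
                params.single_cell_radius_um,
            )
        )
    n_inter = int(round(params.n_intercell_base * params.intercell_branch_density))
    for s in somata:
        segments.extend(
            _intercell_segments(
                rngs["intercell"],
                s,
                n_inter,
                params.single_cell_radius_um,
                2 * params.single_cell_radius_um,
                params.segment_length_um,
            )
        )
    if params.activation_attraction > 0:
        for t in truths:
            if t.activation_class != "negative":
                t.attracted = True
                segments.extend(
                    _attraction_segments(
                        rngs["attraction"],
                        np.asarray(t.center_um[:2]),
                        params.activation_attraction,
                        params.attraction_radius_um,
                    )
                )
    _render_segments(micro, segments, px, nz, params.branch_intensity)
    for s in somata:
        rr, cc = _draw_disk((s[1] / px - 0.5, s[0] / px - 0.5), 4.0 / px, shape=(ny, nx))
        for z in _nucleus_z_slices(nz):
            micro[z, rr, cc] = params.soma_intensity

    # --- noise ------------------------------------------------------------
    if params.noise_sd > 0:
        data += rngs["noise"].normal(0.0, params.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    if nz == 1:
        stack = ImageStack(data[:, 0], (dy, dx), ("neun", "cfos", "microglia"))
    else:
        stack = ImageStack(data, (dz, dy, dx), ("neun", "cfos", "microglia"))
    somata_um = (
        somata
        if somata.size == 0 or nz == 1
        else np.c_[somata, np.full(len(somata), (nz / 2) * dz)]
    )
    return stack, GroundTruth(
        nuclei=truths,
        somata_um=somata_um,
        branch_segments_um=segments,
        rng_seed=params.seed,
    )


def _nucleus_z_slices(nz: int) -> list[int]:
    if nz == 1:
        return [0]
    mid = nz // 2
    return [z for z in (mid - 1, mid, mid + 1) if 0 <= z < nz]


def _soma_grid(rng, params: SimParams, layout: CortexLayout) -> np.ndarray:
    """Quasi-regular soma positions: jittered square grid at the target
    density, kept one cell-radius away from the field border."""
    if params.soma_density_per_mm2 <= 0:
        return np.empty((0, 2))
    spacing = 1000.0 / math.sqrt(params.soma_density_per_mm2)
    margin = params.single_cell_radius_um
    fx, fy = layout.field_size_um[0], layout.field_size_um[1]
    xs = np.arange(margin + spacing / 2, fx - margin, spacing)
    ys = np.arange(margin + spacing / 2, fy - margin, spacing)
    out = []
    for y in ys:
        for x in xs:
            jit = rng.uniform(-0.12 * spacing, 0.12 * spacing, 2)
            out.append([x + jit[0], y + jit[1]])
    return np.array(out) if out else np.empty((0, 2))


def _grow_arbor(rng, soma, n_primary, seg_len, branch_prob, tort, max_radius):
    """Random binary tree confined to a disc around the soma."""
    segs = []
    stack = [
        (np.asarray(soma, float), 2 * math.pi * k / n_primary + rng.uniform(-0.3, 0.3))
        for k in range(n_primary)
    ]
    guard = 0
    while stack and guard < 10000:
        guard += 1
        pos, ang = stack.pop()
        ang += rng.normal(0.0, tort)
        new = pos + seg_len * _unit(ang)
        r = np.hypot(*(new - soma))
        if r > max_radius:  # clip the last step to the cell territory edge
            lo = np.hypot(*(pos - soma))
            if lo >= max_radius - 1e-6:
                continue
            frac = (max_radius - lo) / (r - lo)
            new = pos + (new - pos) * frac
            segs.append(np.stack([pos, new]))
            continue
        segs.append(np.stack([pos, new]))
        stack.append((new, ang))
        if rng.random() < branch_prob:
            stack.append((new, ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)))
    return segs


def _intercell_segments(rng, soma, count, r_in, r_out, seg_len):
    """Near-radial segments confined to the [r_in, r_out] annulus."""
    segs = []
    soma = np.asarray(soma, float)
    for _ in range(count):
        phi = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(0.7, 1.3) * seg_len * 1.5
        r0 = rng.uniform(r_in + 0.5, max(r_in + 1.0, r_out - length - 0.5))
        p0 = soma + r0 * _unit(phi)
        p1 = soma + min(r0 + length, r_out - 0.2) * _unit(phi + rng.normal(0, 0.08))
        segs.append(np.stack([p0, p1]))
    return segs


def _attraction_segments(rng, center, count, radius):
    """Short spokes fully inside the attraction radius of a nucleus."""
    segs = []
    for _ in range(count):
        phi = rng.uniform(0, 2 * math.pi)
        r0 = rng.uniform(0.5, radius * 0.4)
        r1 = rng.uniform(radius * 0.6, radius - 0.2)
        segs.append(np.stack([center + r0 * _unit(phi), center + r1 * _unit(phi)]))
    return segs


def _render_segments(channel3d, segments, px, nz, intensity):
    nz_, ny, nx = channel3d.shape
    zs = _nucleus_z_slices(nz)
    for seg in segments:
        r0, c0 = int(round(seg[0][1] / px - 0.5)), int(round(seg[0][0] / px - 0.5))
        r1, c1 = int(round(seg[1][1] / px - 0.5)), int(round(seg[1][0] / px - 0.5))
        rr, cc = _draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        rr, cc = rr[keep], cc[keep]
        # draw through the central slices so projections see the full arbor
        for z in zs:
            channel3d[z, rr, cc] = np.maximum(channel3d[z, rr, cc], intensity)


# ---------------------------------------------------------------------------
# trajectories


def generate_trajectory(
    kind: Literal["open_field", "cylinder", "ymaze"],
    *,
    waypoints: Sequence[tuple[float, float, float]] | None = None,
    duration_s: float = 600.0,
    speed_cm_s: float = 5.0,
    frame_rate_hz: float = 25.0,
    arena_radius_cm: float = 20.0,
    seed: int = 0,
) -> Trajectory:
    """Scripted (waypoint-interpolated) or random-walk trajectory.

    Scripted mode: ``waypoints`` is a list of ``(t, x, y)``; samples are the
    waypoints themselves plus linear interpolation at the frame rate, so the
    path reproduces the waypoints exactly.  Random mode: a bounded
    correlated random walk at ``speed_cm_s``.
    """
    if kind == "ymaze":
        arena = YMazeGeometry()
    elif kind in ("open_field", "cylinder"):
        arena = CircularArena(radius_cm=arena_radius_cm)
    else:
        raise ValueError(f"unknown arena kind {kind!r}")

    if waypoints is not None:
        wp = np.asarray(waypoints, float)
        if wp.ndim != 2 or wp.shape[1] != 3:
            raise ValueError("waypoints must be (t, x, y) triples")
        if np.any(np.diff(wp[:, 0]) <= 0):
            raise ValueError("waypoint times must be strictly increasing")
        for _, x, y in wp:
            if not arena.contains(x, y):
                raise ValueError(f"waypoint ({x:.1f}, {y:.1f}) outside arena")
        ts = [wp[0, 0]]
        for (t0, *_), (t1, *_) in zip(wp[:-1], wp[1:]):
            n = max(1, int(math.floor((t1 - t0) * frame_rate_hz)))
            ts.extend(np.linspace(t0, t1, n + 1)[1:])
        t = np.array(ts)
        x = np.interp(t, wp[:, 0], wp[:, 1])
        y = np.interp(t, wp[:, 0], wp[:, 2])
        return Trajectory(t=t, x=x, y=y, frame_rate_hz=frame_rate_hz, arena=arena)

    rng = np.random.default_rng(seed)
    n = int(duration_s * frame_rate_hz)
    dt = 1.0 / frame_rate_hz
    pos = np.zeros(2)
    ang = rng.uniform(0, 2 * math.pi)
    xs, ys = [0.0], [0.0]
    for _ in range(n):
        ang += rng.normal(0, 0.4)
        step = speed_cm_s * dt
        cand = pos + step * _unit(ang)
        tries = 0
        while not arena.contains(*cand) and tries < 50:
            ang = rng.uniform(0, 2 * math.pi)
            cand = pos + step * _unit(ang)
            tries += 1
        pos = cand if arena.contains(*cand) else pos
        xs.append(pos[0])
        ys.append(pos[1])
    t = np.arange(n + 1) * dt
    return Trajectory(
        t=t, x=np.array(xs), y=np.array(ys), frame_rate_hz=frame_rate_hz, arena=arena
    )


def ymaze_visit_waypoints(
    visits: Sequence[tuple[str, float]],
    dwell_s: float = 4.0,
    maze: YMazeGeometry | None = None,
) -> list[tuple[float, float, float]]:
    """Waypoints for a scripted sequence of arm visits.

    ``visits`` is a list of ``(arm_label, depth_fraction)``; the animal
    starts at the centre, walks to ``depth * arm_length`` along each arm in
    turn, and returns to the centre between visits.
    """
    maze = maze or YMazeGeometry()
    t = 0.0
    wps: list[tuple[float, float, float]] = [(t, 0.0, 0.0)]
    for arm, depth in visits:
        u = maze.arm_direction(arm)
        tip = u * (depth * maze.arm_length_cm)
        t += dwell_s
        wps.append((t, tip[0], tip[1]))
        t += dwell_s
        wps.append((t, 0.0, 0.0))
    return wps


# ---------------------------------------------------------------------------
# superfusion release


def generate_release_series(
    basal_fraction: float,
    stim_gain: float,
    n_samples: int,
    stim_sample_index: int,
    tissue_initial_bq: float,
    tissue_mass_g: float = 0.01,
    sample_duration_s: float = 180.0,
) -> ReleaseSeries:
    """First-order washout of a radiolabelled pool with a stimulus bump.

    Each sample releases a constant fraction ``basal_fraction`` (percent) of
    the pool remaining at its start; the stimulated sample releases
    ``stim_gain`` times that fraction.  Radioactivity is conserved exactly:
    released amounts plus the final tissue content sum to the initial load.
    """
    if not (0.0 < basal_fraction < 100.0):
        raise ValueError("basal_fraction must be in (0, 100)")
    if not (0 <= stim_sample_index < n_samples):
        raise ValueError("stim index must fall within the series")
    h = basal_fraction / 100.0
    if stim_gain < 0 or h * stim_gain > 1.0:
        raise ValueError("stimulated release fraction exceeds the pool")
    pool = float(tissue_initial_bq)
    released = np.empty(n_samples)
    for k in range(n_samples):
        frac = h * stim_gain if k == stim_sample_index else h
        released[k] = pool * frac
        pool -= released[k]
    return ReleaseSeries(
        released_bq=released,
        tissue_after_bq=pool,
        tissue_mass_g=tissue_mass_g,
        stim_sample_index=stim_sample_index,
        sample_duration_s=sample_duration_s,
    )


def params_to_dict(params: SimParams) -> dict:
    return asdict(params)
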