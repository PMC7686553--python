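"""Microglial branch recruitment around neuronal nuclei.

Three complementary measurements of neuron-microglia apposition:

* neuron-centred 2D Sholl profiles on the network skeleton, grouped by
  activation status (c-Fos+ versus NeuN+/c-Fos-);
* neuron-centred 3D Sholl on the thresholded membrane volume, counting
  distinct 26-connected clusters per spherical shell (anisotropic voxels
  are respected by computing shell membership in physical micrometres);
* the fraction of activated nuclei whose mask, expanded by a small contact
  margin, touches a microglial soma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .microglia import Skeleton, ShollProfile, sholl_2d
from .stats_report import compare_two

__all__ = [
    "NeuronCenterSet",
    "ShellCount",
    "neuron_sholl_2d",
    "compare_status_profiles",
    "sholl_3d",
    "soma_contact_fraction",
]

STATUSES = ("activated", "inactive")


@dataclass
class NeuronCenterSet:
    """Neuron centres (um) with activation status per centre."""

    centers_um: np.ndarray  # (N, 2) or (N, 3): (x, y[, z])
    status: list[str]

    def __post_init__(self) -> None:
        self.centers_um = np.atleast_2d(np.asarray(self.centers_um, float))
        if len(self.status) != len(self.centers_um):
            raise ValueError("one status per center required")
        bad = set(self.status) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown statuses {bad}; expected {STATUSES}")

    def by_status(self, status: str) -> np.ndarray:
        sel = [i for i, s in enumerate(self.status) if s == status]
        return self.centers_um[sel]


@dataclass
class ShellCount:
    radius_um: float
    components: int
    partial: bool = False

    def __post_init__(self) -> None:
        if self.components < 0:
            raise ValueError("component count must be >= 0")


def neuron_sholl_2d(
    skeleton: Skeleton,
    centers: NeuronCenterSet,
    r_max_um: float = 15.0,
    dr_um: float = 1.0,
) -> dict[str, list[ShollProfile]]:
    """One skeleton Sholl profile per neuron centre, grouped by status."""
    out: dict[str, list[ShollProfile]] = {s: [] for s in STATUSES}
    for center, status in zip(centers.centers_um, centers.status):
        out[status].append(sholl_2d(skeleton, tuple(center[:2]), r_max_um, dr_um))
    return out


def compare_status_profiles(
    groups: dict[str, list[ShollProfile]]
) -> pd.DataFrame:
    """Per-radius activated-vs-inactive comparison (Mann-Whitney).

    Returns mean, sem and n per status and radius plus the two-sided
    p-value, i.e. the status x radius layout flattened by radius.
    """
    act, ina = groups["activated"], groups["inactive"]
    if len(act) < 2 or len(ina) < 2:
        raise ValueError("need >= 2 centers per status group")
    radii = act[0].radii_um
    rows = []
    for i, r in enumerate(radii):
        a = np.array([p.crossings[i] for p in act], float)
        b = np.array([p.crossings[i] for p in ina], float)
        try:
            _, pval = compare_two(a, b, test="mannwhitney")
        except ValueError:
            pval = np.nan
        rows.append(
            {
                "radius_um": r,
                "mean_activated": a.mean(),
                "sem_activated": a.std(ddof=1) / np.sqrt(len(a)),
                "n_activated": len(a),
                "mean_inactive": b.mean(),
                "sem_inactive": b.std(ddof=1) / np.sqrt(len(b)),
                "n_inactive": len(b),
                "p": pval,
            }
        )
    return pd.DataFrame(rows)


def _shell_distances(shape, center_um, voxel_size_um):
    nz, ny, nx = shape
    dx, dy, dz = voxel_size_um
    zc = (np.arange(nz) + 0.5) * dz - center_um[2]
    yc = (np.arange(ny) + 0.5) * dy - center_um[1]
    xc = (np.arange(nx) + 0.5) * dx - center_um[0]
    return np.sqrt(
        zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
    )


def sholl_3d(
    mask3d: np.ndarray,
    center_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 1.0),
    r_max_um: float = 15.0,
    dr_um: float = 1.0,
    allow_thin: bool = False,
) -> list[ShellCount]:
    """Foreground clusters per spherical shell around a neuron centre.

    Shell k spans ``[k*dr - dr/2, k*dr + dr/2)`` of Euclidean distance in
    micrometres, so every voxel between ``dr/2`` and ``r_max + dr/2`` lands
    in exactly one shell (the sub-``dr/2`` core around the centre - the
    nucleus itself - belongs to none); the count is the number
    of 26-connected clusters of foreground voxels in the shell.  Volumes
    thinner than ``2 * r_max`` along z are refused unless ``allow_thin``;
    shells truncated by any border are flagged partial.
    """
    mask3d = np.asarray(mask3d, bool)
    if mask3d.ndim != 3:
        raise ValueError("sholl_3d expects a 3D volume")
    dx, dy, dz = voxel_size_um
    nz, ny, nx = mask3d.shape
    extent = (nx * dx, ny * dy, nz * dz)
    if not all(0 <= c <= e for c, e in zip(center_um, extent)):
        raise ValueError("center lies outside the volume")
    if extent[2] < 2 * r_max_um and not allow_thin:
        raise ValueError(
            f"z-extent {extent[2]:g} um is thinner than 2 x r_max; "
            "pass allow_thin=True to accept border-truncated shells"
        )
    dist = _shell_distances(mask3d.shape, center_um, voxel_size_um)
    radii = np.arange(dr_um, r_max_um + dr_um / 2, dr_um)
    structure = np.ones((3, 3, 3), dtype=int)
    border_margin = min(
        center_um[0], extent[0] - center_um[0],
        center_um[1], extent[1] - center_um[1],
        center_um[2], extent[2] - center_um[2],
    )
    out = []
    for r in radii:
        lo = r - dr_um / 2
        hi = r + dr_um / 2
        shell = (dist >= lo) & (dist < hi) & mask3d
        _, n = ndimage.label(shell, structure=structure)
        out.append(ShellCount(radius_um=float(r), components=int(n),
                              partial=hi > border_margin))
    return out


def soma_contact_fraction(
    nucleus_labels: np.ndarray,
    activated_ids: list[int],
    soma_mask: np.ndarray,
    contact_margin_um: float = 0.5,
    voxel_size_um: tuple[float, ...] = (0.5, 0.5),
) -> float:
    """Fraction of activated nuclei in contact with a microglial soma.

    A nucleus counts as contacting when any voxel of its mask lies within
    ``contact_margin_um`` (Euclidean, physical units) of the soma mask -
    equivalent to dilating the nucleus by the margin and testing overlap.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    soma_mask = np.asarray(soma_mask, bool)
    if nucleus_labels.shape != soma_mask.shape:
        raise ValueError("nucleus labels and soma mask must share one grid")
    if not activated_ids:
        raise ValueError("empty activated set: contact fraction undefined")
    if not soma_mask.any():
        return 0.0
    # distance from every voxel to the nearest soma voxel, in um
    sampling = tuple(reversed(voxel_size_um)) if len(voxel_size_um) == nucleus_labels.ndim else None
    if sampling is None:
        raise ValueError("voxel_size_um must match the mask dimensionality")
    dist = ndimage.distance_transform_edt(~soma_mask, sampling=sampling)
    contacted = 0
    for nid in activated_ids:
        sel = nucleus_labels == nid
        if not sel.any():
            raise ValueError(f"nucleus id {nid} absent from the label image")
        if dist[sel].min() <= contact_margin_um + 1e-9:
            contacted += 1
    return contacted / len(activated_ids)
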