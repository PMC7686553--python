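"""Shared containers: multichannel image stacks and cortical layer layouts.

Physical coordinates are always expressed in micrometres, as ``(x, y)`` or
``(x, y, z)`` tuples, where x runs along the medial-distal axis (image
columns), y along rows and z along the optical axis.  Voxel arrays are
indexed ``[z, y, x]`` (3D) or ``[y, x]`` (2D); pixel indices are 0-based and
the physical coordinate of pixel ``i`` is its centre, ``(i + 0.5) * pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ImageStack", "CortexLayout", "default_mpfc_layout"]


@dataclass
class ImageStack:
    """A multi-channel 2D image or 3D z-stack with physical voxel size.

    Parameters
    ----------
    data:
        Array of shape ``(C, Z, Y, X)`` (3D) or ``(C, Y, X)`` (2D).
    voxel_size_um:
        ``(dz, dy, dx)`` for 3D data, ``(dy, dx)`` for 2D, in micrometres.
    channel_names:
        One name per channel, e.g. ``("neun", "cfos", "microglia")``.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, ...]
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, Y, X) or (C, Z, Y, X)")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")
        if len(self.voxel_size_um) != self.data.ndim - 1:
            raise ValueError("voxel_size_um must match spatial dimensionality")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def pixel_size_um(self) -> float:
        """In-plane pitch; requires square in-plane pixels."""
        dy, dx = self.voxel_size_um[-2], self.voxel_size_um[-1]
        if abs(dy - dx) > 1e-9:
            raise ValueError("in-plane pixels are not square")
        return float(dx)

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError as exc:
            raise KeyError(f"no channel named {name!r}") from exc
        return self.data[i]


@dataclass
class CortexLayout:
    """Consecutive cortical layer bands measured from the pial/midline edge.

    ``layer_widths`` is an ordered list of ``(name, width_um)``; bands are
    half-open ``[start, start + width)`` along the medial-distal (x) axis,
    starting at ``midline_offset_um``.
    """

    layer_widths: Sequence[tuple[str, float]]
    field_size_um: tuple[float, float, float]
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 1.0)  # (dx, dy, dz)
    midline_offset_um: float = 0.0

    def __post_init__(self) -> None:
        self.layer_widths = [(str(n), float(w)) for n, w in self.layer_widths]
        if not self.layer_widths:
            raise ValueError("at least one layer required")
        if any(w <= 0 for _, w in self.layer_widths):
            raise ValueError("layer widths must be strictly positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if self.midline_offset_um + self.total_width_um > self.field_size_um[0] + 1e-9:
            raise ValueError("layers do not fit inside the field x-extent")

    @property
    def total_width_um(self) -> float:
        return float(sum(w for _, w in self.layer_widths))

    @property
    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layer_widths]

    @property
    def beyond_label(self) -> str:
        return f"beyond_{self.layer_widths[-1][0]}"

    def boundaries_um(self) -> list[tuple[str, float, float]]:
        """(name, start, end) for each band, in absolute x micrometres."""
        out = []
        start = self.midline_offset_um
        for name, w in self.layer_widths:
            out.append((name, start, start + w))
            start += w
        return out

    def layer_of(self, x_um: float) -> str:
        """Band containing ``x_um``; positions past the last band get the
        ``beyond_*`` sentinel, positions before the first band fold into it."""
        for name, start, end in self.boundaries_um():
            if x_um < end:
                return name
        return self.beyond_label


def default_mpfc_layout(
    field_y_um: float = 400.0, field_z_um: float = 10.0
) -> CortexLayout:
    """Prefrontal layer bands: I, II/III, V, VI.

    Where a band width is reported as a range in the anatomical literature
    (layer I 120-140 um, layer V 320-350 um), the midpoint is used.
    """
    widths = [("I", 130.0), ("II/III", 80.0), ("V", 335.0), ("VI", 280.0)]
    total = sum(w for _, w in widths)
    return CortexLayout(
        layer_widths=widths,
        field_size_um=(total, field_y_um, field_z_um),
    )
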