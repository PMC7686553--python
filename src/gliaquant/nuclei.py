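"""Nucleus detection, dual-threshold activation classes and layer profiles.

The counting workflow mirrors the standard immunofluorescence macro: a
z-stack is flattened (maximum projection for fluorescence, sum of slices
for DAB), the activation channel is auto-thresholded, connected objects
above an area floor are kept, and the mean gray value of each object is
measured on the *original* (unthresholded) image over the object mask.
Strongly activated nuclei (c-Fos++) are those whose projected area and
mean gray value both strictly exceed a configured threshold pair; detected
nuclei failing either arm are c-Fos+.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_li, threshold_otsu, threshold_triangle
from skimage.measure import regionprops

from .core import CortexLayout, ImageStack

__all__ = [
    "DetectedNucleus",
    "ThresholdPair",
    "LayerProfile",
    "project_stack",
    "detect_nuclei",
    "classify_activation",
    "assign_layers",
    "layer_counts",
    "longitudinal_profile",
]

_AUTO_THRESHOLDS = {
    "otsu": threshold_otsu,
    "li": threshold_li,
    "triangle": threshold_triangle,
}


@dataclass(frozen=True)
class ThresholdPair:
    """Dual cut separating c-Fos++ from c-Fos+ (strict > on both arms)."""

    min_area_um2: float = 200.0
    min_intensity: float = 400.0

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0 or self.min_intensity <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class DetectedNucleus:
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    mean_gray: float
    activation_class: str | None = None
    layer: str | None = None
    label_id: int = 0


@dataclass
class LayerProfile:
    distance_um: np.ndarray  # monotone pixel-pitch grid along medial-distal axis
    mean_intensity: np.ndarray
    layer_means: dict[str, float] | None = None


def project_stack(stack: ImageStack, mode: str = "max") -> ImageStack:
    """Flatten a 3D stack to 2D: per-pixel ``max`` or ``sum`` over z."""
    if not stack.is_3d:
        raise ValueError("stack is already 2D; nothing to project")
    if mode == "max":
        flat = stack.data.max(axis=1)
    elif mode == "sum":
        flat = stack.data.sum(axis=1)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return ImageStack(flat, stack.voxel_size_um[1:], stack.channel_names)


def detect_nuclei(
    image: np.ndarray,
    pixel_size_um: float,
    method: str = "otsu",
    min_area_um2: float = 20.0,
    manual_level: float | None = None,
) -> list[DetectedNucleus]:
    """Auto-threshold the projected channel and measure connected objects.

    Components use 8-connectivity; areas are pixel counts converted to
    um^2; the mean gray value is taken from ``image`` itself over each
    object mask.  A flat (or empty) image yields an empty list.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("detect_nuclei expects a 2D image")
    if image.max() == image.min():
        return []
    if manual_level is not None:
        level = manual_level
    else:
        try:
            level = _AUTO_THRESHOLDS[method](image)
        except KeyError as exc:
            raise ValueError(f"unknown auto-threshold method {method!r}") from exc
    mask = image > level
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out: list[DetectedNucleus] = []
    px2 = pixel_size_um * pixel_size_um
    for prop in regionprops(labels, intensity_image=image):
        area = prop.area * px2
        if area < min_area_um2:
            continue
        cy, cx = prop.centroid
        out.append(
            DetectedNucleus(
                centroid_um=((cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um),
                area_um2=float(area),
                mean_gray=float(prop.intensity_mean),
                label_id=int(prop.label),
            )
        )
    return out


def classify_activation(
    nuclei: list[DetectedNucleus], thresholds: ThresholdPair
) -> list[DetectedNucleus]:
    """Set ``cfos_plusplus`` iff area AND mean gray strictly exceed the
    threshold pair; every other detected nucleus is ``cfos_plus``."""
    out = []
    for nuc in nuclei:
        strong = (
            nuc.area_um2 > thresholds.min_area_um2
            and nuc.mean_gray > thresholds.min_intensity
        )
        out.append(replace(nuc, activation_class="cfos_plusplus" if strong else "cfos_plus"))
    return out


def assign_layers(
    nuclei: list[DetectedNucleus], layout: CortexLayout
) -> list[DetectedNucleus]:
    """Assign each nucleus to the half-open layer band containing its
    centroid's medial-distal coordinate; nuclei past the deepest band get
    the ``beyond_*`` sentinel rather than being dropped."""
    return [replace(n, layer=layout.layer_of(n.centroid_um[0])) for n in nuclei]


def layer_counts(
    nuclei: list[DetectedNucleus],
    layout: CortexLayout,
    class_filter: str | None = None,
) -> pd.DataFrame:
    """Count and areal density (objects/mm^2) per layer band.

    The band area is ``width x field y-extent``; counts over all rows
    (including the beyond sentinel) sum to the number of input nuclei
    passing ``class_filter``.
    """
    field_y = layout.field_size_um[1]
    rows = []
    kept = [
        n
        for n in nuclei
        if class_filter is None or n.activation_class == class_filter
    ]
    for n in kept:
        if n.layer is None:
            raise ValueError("layers not assigned; call assign_layers first")
    for name, start, end in layout.boundaries_um():
        band_mm2 = (end - start) * field_y / 1e6
        if band_mm2 <= 0:
            raise ValueError(f"zero-area band {name!r}")
        count = sum(1 for n in kept if n.layer == name)
        rows.append({"layer": name, "count": count, "density_per_mm2": count / band_mm2})
    beyond = sum(1 for n in kept if n.layer == layout.beyond_label)
    if beyond:
        rows.append(
            {"layer": layout.beyond_label, "count": beyond, "density_per_mm2": np.nan}
        )
    return pd.DataFrame(rows)


def longitudinal_profile(
    image: np.ndarray,
    pixel_size_um: float,
    layout: CortexLayout | None = None,
) -> LayerProfile:
    """Mean signal per medial-distal position (column means of the image).

    The distance grid steps at the pixel pitch with pixel-centre
    coordinates.  With a layout, profile values are also grouped into
    per-layer means; the layout must not extend past the image.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("longitudinal_profile expects a 2D image")
    nx = image.shape[1]
    distance = (np.arange(nx) + 0.5) * pixel_size_um
    profile = image.mean(axis=0)
    layer_means = None
    if layout is not None:
        extent = layout.midline_offset_um + layout.total_width_um
        if extent > nx * pixel_size_um + 1e-9:
            raise ValueError("layout is wider than the image")
        layer_means = {}
        for name, start, end in layout.boundaries_um():
            sel = (distance >= start) & (distance < end)
            layer_means[name] = float(profile[sel].mean()) if sel.any() else float("nan")
    return LayerProfile(distance_um=distance, mean_intensity=profile, layer_means=layer_means)
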