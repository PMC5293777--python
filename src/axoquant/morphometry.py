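"""Retinal morphometry: layer thickness and CTB+/DAPI+ soma counts.

Boundary curves are inputs (annotation polylines or generator truth); the
study measured them manually, so automatic layer segmentation is out of
scope here.  Thickness is the mean perpendicular distance between curves at
``n_locations`` equally spaced horizontal positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .nuclear_localization import segment_nuclei

# expected boundary order, superficial to deep
BOUNDARY_ORDER = ("NFL", "INL_top", "INL_bottom", "ONL_top", "ONL_bottom", "RPE")


@dataclass
class MorphometryResult:
    retinal_thickness_um: float | None = None
    inl_thickness_um: float | None = None
    onl_thickness_um: float | None = None
    n_locations: int | None = None
    rgc_count: int | None = None
    gcl_area_um2: float | None = None

    @property
    def rgc_density(self) -> float | None:
        if self.rgc_count is None or not self.gcl_area_um2:
            return None
        return self.rgc_count / self.gcl_area_um2


def _as_curve(boundary, x_um: np.ndarray) -> np.ndarray:
    """Evaluate a boundary at horizontal positions ``x_um``.

    Accepts a scalar depth, an ``(offset, slope)`` line, or an (N, 2)
    polyline of (x_um, depth_um) vertices.
    """
    b = np.asarray(boundary, dtype=float)
    if b.ndim == 0:
        return np.full_like(x_um, float(b))
    if b.shape == (2,):
        offset, slope = b
        return offset + slope * x_um
    if b.ndim == 2 and b.shape[1] == 2:
        return np.interp(x_um, b[:, 0], b[:, 1])
    raise ValueError("boundary must be scalar, (offset, slope) or (N, 2) polyline")


def measure_layer_thickness(
    boundaries: Mapping[str, object],
    *,
    n_locations: int = 5,
    x_extent_um: tuple[float, float] = (0.0, 100.0),
) -> MorphometryResult:
    """Mean perpendicular NFL->RPE, INL and ONL thickness over
    ``n_locations`` equally spaced horizontal positions.

    ``boundaries`` maps the six names in :data:`BOUNDARY_ORDER` to depth
    curves in um.  Crossing boundaries are rejected.
    """
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    missing = [k for k in BOUNDARY_ORDER if k not in boundaries]
    if missing:
        raise ValueError(f"missing boundaries: {missing}")
    x = np.linspace(*x_extent_um, n_locations)
    depths = np.stack([_as_curve(boundaries[k], x) for k in BOUNDARY_ORDER])
    if np.any(np.diff(depths, axis=0) <= 0):
        raise ValueError("boundaries cross or touch within the sampled extent")

    # local slope from a small horizontal step; perpendicular = vertical * cos
    dx = max((x_extent_um[1] - x_extent_um[0]) * 1e-3, 1e-6)
    depths_dx = np.stack([_as_curve(boundaries[k], x + dx) for k in BOUNDARY_ORDER])
    slopes = (depths_dx - depths) / dx

    def perp(i_top: int, i_bot: int) -> float:
        dy = depths[i_bot] - depths[i_top]
        m = 0.5 * (slopes[i_top] + slopes[i_bot])
        return float(np.mean(dy / np.sqrt(1.0 + m**2)))

    return MorphometryResult(
        retinal_thickness_um=perp(0, 5),
        inl_thickness_um=perp(1, 2),
        onl_thickness_um=perp(3, 4),
        n_locations=n_locations,
    )


def count_rgc_density(
    ctb_channel: np.ndarray,
    dapi_channel: np.ndarray,
    gcl_roi: np.ndarray,
    pixel_size: float,
    *,
    ctb_threshold: float = 0.5,
    dapi_threshold: float = 0.5,
    min_area: int = 8,
) -> MorphometryResult:
    """Count somas positive in BOTH channels inside the GCL ROI.

    Objects are detected on DAPI (the nuclear gate) and deemed CTB+ when the
    mean CTB intensity over the object exceeds ``ctb_threshold``; the count
    is invariant to intensity rescaling above the thresholds.  Density is
    count / ROI area in um^2.
    """
    gcl_roi = np.asarray(gcl_roi, dtype=bool)
    if not gcl_roi.any():
        raise ValueError("GCL ROI is empty")
    ctb = np.asarray(ctb_channel, dtype=float)
    dapi = np.where(gcl_roi, np.asarray(dapi_channel, dtype=float), 0.0)
    labels = segment_nuclei(dapi, min_area=min_area, threshold=dapi_threshold)
    count = 0
    for nid in range(1, labels.max() + 1):
        obj = labels == nid
        if not obj.any():
            continue
        # require the object substantially inside the ROI
        if (obj & gcl_roi).sum() < 0.5 * obj.sum():
            continue
        if float(ctb[obj].mean()) > ctb_threshold:
            count += 1
    area_um2 = float(gcl_roi.sum()) * pixel_size**2
    return MorphometryResult(rgc_count=count, gcl_area_um2=area_um2)


def average_per_animal(
    per_image_results: Sequence[MorphometryResult], min_images: int = 8
) -> MorphometryResult:
    """Per-animal mean over per-image results; warns below the study's
    minimum of eight images per animal."""
    if not per_image_results:
        raise ValueError("no images to average")
    if len(per_image_results) < min_images:
        warnings.warn(
            f"only {len(per_image_results)} images for this animal "
            f"(minimum {min_images} expected)",
            stacklevel=2,
        )

    def mean_of(attr: str):
        vals = [getattr(r, attr) for r in per_image_results if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    counts = [r.rgc_count for r in per_image_results if r.rgc_count is not None]
    return MorphometryResult(
        retinal_thickness_um=mean_of("retinal_thickness_um"),
        inl_thickness_um=mean_of("inl_thickness_um"),
        onl_thickness_um=mean_of("onl_thickness_um"),
        n_locations=per_image_results[0].n_locations,
        rgc_count=int(round(np.mean(counts))) if counts else None,
        gcl_area_um2=mean_of("gcl_area_um2"),
    )
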