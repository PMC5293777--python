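"""Retinotopic transport-map reconstruction and percent-intact statistic.

The flattened map convention is row 0 = rostral, column 0 = medial.  Each SC
section contributes one mediolateral profile of background-normalized CTB
intensity; profiles are stacked rostrocaudally, interpolated onto a fixed
grid, normalized to the map's reference maximum, and thresholded (default
70% of maximum, inclusive) to yield the percent of the map with intact
transport.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .synthetic_data import SectionImage

try:  # skimage only needed for the automatic background estimate
    from skimage.filters import threshold_otsu
except ImportError:  # pragma: no cover
    threshold_otsu = None


@dataclass
class RetinotopicMap:
    """Normalized CTB density over the flattened SC surface."""

    density: np.ndarray  # 2D, in [0, 1] where valid
    valid_mask: np.ndarray  # 2D bool
    max_signal: float  # reference maximum used for normalization
    grid_resolution: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.density.shape != self.valid_mask.shape:
            raise ValueError("density and valid_mask shapes differ")
        v = self.density[self.valid_mask]
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1.0 + 1e-9):
            raise ValueError("valid density values must lie in [0, 1]")


@dataclass
class TransportResult:
    percent_intact: float  # [0, 100]
    threshold: float
    n_sections: int
    map: RetinotopicMap

    def to_dict(self) -> dict:
        return {
            "percent_intact": self.percent_intact,
            "threshold": self.threshold,
            "n_sections": self.n_sections,
            "grid_resolution": self.map.grid_resolution,
            "max_signal": self.map.max_signal,
        }


def normalize_background(
    image: SectionImage,
    background_region: np.ndarray | str = "auto",
    channel: str = "CTB",
) -> SectionImage:
    """Subtract the background estimate from the CTB channel, clipping at 0.

    ``background_region`` is a boolean mask of tissue-free pixels, or
    ``"auto"`` to estimate it as the pixels below the Otsu split (falling
    back to the global minimum for near-constant images).  The estimate is
    recorded in the output metadata.
    """
    raw = image.channel(channel)
    if isinstance(background_region, str):
        if background_region != "auto":
            raise ValueError(f"unknown background mode {background_region!r}")
        if np.ptp(raw) < 1e-12 or threshold_otsu is None:
            estimate = float(raw.min())
        else:
            split = threshold_otsu(raw)
            below = raw[raw < split]
            estimate = float(below.mean()) if below.size else float(raw.min())
    else:
        mask = np.asarray(background_region, dtype=bool)
        if mask.shape != raw.shape:
            raise ValueError("background mask shape mismatch")
        if not mask.any():
            raise ValueError("background region is empty")
        if mask.all():
            raise ValueError("background region covers the entire image")
        estimate = float(raw[mask].mean())
    out = np.clip(raw - estimate, 0.0, None)
    channels = dict(image.channels)
    channels[channel] = out
    meta = dict(image.metadata)
    meta["background_estimate"] = estimate
    return SectionImage(
        channels=channels,
        pixel_size=image.pixel_size,
        tissue=image.tissue,
        eye=image.eye,
        animal_id=image.animal_id,
        section_index=image.section_index,
        metadata=meta,
    )


def extract_section_profile(
    image: SectionImage,
    sc_mask: np.ndarray,
    n_samples: int = 100,
    channel: str = "CTB",
) -> np.ndarray:
    """Mediolateral intensity profile: bin ``j`` holds the mean masked CTB
    intensity of columns in the j-th of ``n_samples`` equal-width bins across
    the image; bins with no masked pixels are NaN (invalid)."""
    sc_mask = np.asarray(sc_mask, dtype=bool)
    if sc_mask.shape != image.shape:
        raise ValueError("sc_mask shape mismatch")
    if not sc_mask.any():
        raise ValueError("empty SC mask: cannot identify the section")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    values = image.channel(channel)
    w = image.shape[1]
    edges = np.linspace(0, w, n_samples + 1)
    col_bin = np.clip(np.searchsorted(edges, np.arange(w), side="right") - 1, 0, n_samples - 1)
    profile = np.full(n_samples, np.nan)
    masked = np.where(sc_mask, values, np.nan)
    for j in range(n_samples):
        cols = col_bin == j
        block = masked[:, cols]
        if np.isfinite(block).any():
            profile[j] = np.nanmean(block)
    return profile


def _interp_rows(arr: np.ndarray, n_target: int) -> np.ndarray:
    """Linear interpolation along axis 0; a target row is NaN when either
    contributing source row is NaN (validity does not bleed across gaps)."""
    n_src = arr.shape[0]
    if n_src == n_target:
        return arr.copy()
    pos = np.linspace(0, n_src - 1, n_target)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_src - 1)
    t = (pos - lo)[:, None]
    return (1 - t) * arr[lo] + t * arr[hi]


def assemble_retinotopic_map(
    profiles: Sequence[np.ndarray],
    grid_resolution: int = 100,
    reference: str = "percentile99",
) -> RetinotopicMap:
    """Stack section profiles rostral->caudal, interpolate to the grid, and
    normalize so the reference maximum maps to density 1.0.

    ``reference`` is ``"percentile99"`` (robust to hot pixels, default) or
    ``"max"`` (exact maximum).  Densities above the reference are clipped to
    1.0, so at least one valid cell attains 1.0 by construction.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent profile lengths: {sorted(lengths)}")
    stack = np.asarray([np.asarray(p, dtype=float) for p in profiles])
    if len(profiles) > 1:
        stack = _interp_rows(stack, grid_resolution)
    stack = _interp_rows(stack.T, grid_resolution).T

    valid = np.isfinite(stack)
    if not valid.any():
        raise ValueError("no valid cells in assembled map")
    vals = stack[valid]
    if reference == "percentile99":
        ref = float(np.percentile(vals, 99))
    elif reference == "max":
        ref = float(vals.max())
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if ref <= 0:
        ref = max(float(vals.max()), 1e-12)
    density = np.where(valid, np.clip(stack / ref, 0.0, 1.0), 0.0)
    return RetinotopicMap(
        density=density,
        valid_mask=valid,
        max_signal=ref,
        grid_resolution=grid_resolution,
    )


def percent_intact_transport(
    rmap: RetinotopicMap, threshold: float = 0.70
) -> TransportResult:
    """Percent of valid map cells at or above ``threshold`` of the reference
    maximum (the >= is inclusive)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    valid = rmap.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("map has no valid cells")
    intact = int(np.count_nonzero(rmap.density[valid] >= threshold))
    return TransportResult(
        percent_intact=100.0 * intact / n_valid,
        threshold=threshold,
        n_sections=rmap.density.shape[0],
        map=rmap,
    )


def transport_from_sections(
    sections: Sequence[SectionImage],
    masks: Sequence[np.ndarray] | None = None,
    *,
    n_samples: int = 100,
    grid_resolution: int = 100,
    threshold: float = 0.70,
    reference: str = "percentile99",
    background: np.ndarray | str = "auto",
) -> TransportResult:
    """Full per-eye pipeline: normalize -> profile per section -> map ->
    percent intact.  ``masks`` defaults to each section's ``sc_mask``
    metadata (generator- or annotation-provided)."""
    if masks is None:
        masks = [s.metadata["sc_mask"] for s in sections]
    order = np.argsort([s.section_index for s in sections])
    profiles = []
    for i in order:
        norm = normalize_background(sections[i], background)
        profiles.append(extract_section_profile(norm, masks[i], n_samples))
    rmap = assemble_retinotopic_map(profiles, grid_resolution, reference)
    result = percent_intact_transport(rmap, threshold)
    return dataclasses.replace(result, n_sections=len(sections))


def save_map_tiff(rmap: RetinotopicMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, rmap.density.astype(np.float32))
    return path


def save_map_png(rmap: RetinotopicMap, path: str | Path) -> Path:
    """Heat map with the blue (0) -> green (50%) -> red (100%) convention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    shown = np.ma.masked_where(~rmap.valid_mask, rmap.density)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(shown, cmap="jet", vmin=0.0, vmax=1.0)
    ax.set_xlabel("mediolateral (medial at 0)")
    ax.set_ylabel("rostrocaudal (rostral at 0)")
    fig.colorbar(im, ax=ax, label="normalized CTB density")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
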