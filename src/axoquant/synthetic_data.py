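"""Synthetic image and tonometry generators with exact ground truth.

Every generator is driven by a single :class:`SyntheticSpec` seed through
independent sub-streams, so any individual artifact is reproducible without
re-running the whole cohort.  Ground truth is always bookkept from what was
actually rendered (pixel counts, placed objects), never from the requested
parameter alone, so recovery tests can compare against an exact reference.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


class Tissue(str, Enum):
    SC = "SC"
    ONH = "ONH"
    RETINA = "RETINA"


class Eye(str, Enum):
    SALINE = "SALINE"
    MICROBEAD = "MICROBEAD"


@dataclass
class SectionImage:
    """One 2D multi-channel field plus acquisition metadata.

    ``channels`` maps channel name (e.g. ``"CTB"``, ``"DAPI"``, ``"NFKB"``)
    to a 2D float array.  All channels must share shape; intensities are
    finite and non-negative.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    tissue: Tissue = Tissue.SC
    eye: Eye = Eye.SALINE
    animal_id: str = "A0"
    section_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SectionImage requires at least one channel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.section_index < 0:
            raise ValueError("section_index must be >= 0")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
        self.tissue = Tissue(self.tissue)
        self.eye = Eye(self.eye)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests; fields unused by a given
    generator stay ``None``."""

    deficit_fraction: float | None = None
    positive_area_fraction: float | None = None
    nuclear_fraction_per_cell: list[float] | None = None
    layer_boundaries: list[float] | None = None  # depths in um, increasing
    rgc_count: int | None = None
    baseline_iop_mmHg: float | None = None
    elevation_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.layer_boundaries is not None:
            b = np.asarray(self.layer_boundaries, dtype=float)
            if b.ndim != 1 or len(b) < 2 or not np.all(np.diff(b) > 0):
                raise ValueError("layer_boundaries must be strictly increasing depths")
        if self.rgc_count is not None and self.rgc_count < 0:
            raise ValueError("rgc_count must be >= 0")

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}


@dataclass
class SyntheticSpec:
    """Knobs shared by all generators.

    The paper reports no per-image intensity statistics, so noise defaults
    are free parameters chosen to be small relative to the signal contrast.
    """

    image_size: tuple[int, int] = (96, 160)  # rows, cols
    n_sections: int = 10
    pixel_size: float = 5.0  # um / pixel
    background: float = 0.10  # constant offset
    noise_sd: float = 0.02  # additive Gaussian sd
    signal: float = 1.0  # bright CTB level above background
    dim_level: float = 0.3  # deficit intensity as fraction of signal
    wedge_center_deg: float = 0.0  # deficit sector orientation in map coords
    positive_level: float = 0.8  # IHC positive-label intensity
    negative_level: float = 0.2  # IHC background-label intensity
    label_threshold: float = 0.5  # generator-known positivity threshold
    cell_radius: int = 6  # nucleus radius, pixels
    annulus_width: int = 3  # perinuclear annulus, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if min(self.image_size) < 8:
            raise ValueError("image_size too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for sub-stream ``stream`` of this spec's seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# stream ids; stable so individual artifacts are reproducible in isolation
_STREAM_SC = 1
_STREAM_IHC = 2
_STREAM_NUCLEI = 3
_STREAM_RETINA = 4
_STREAM_IOP = 5


def _add_noise(arr: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd > 0:
        arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
    return np.clip(arr, 0.0, None)


# ---------------------------------------------------------------------------
# superior colliculus series
# ---------------------------------------------------------------------------

def generate_sc_series(
    spec: SyntheticSpec,
    deficit_fraction: float,
    *,
    eye: Eye = Eye.MICROBEAD,
    animal_id: str = "A0",
) -> tuple[list[SectionImage], GroundTruth]:
    """Render serial SC sections whose CTB channel is dim inside an angular
    sector of the flattened retinotopic domain (unit disk).

    Section ``i`` samples the disk at rostrocaudal coordinate ``v_i``; its SC
    mask is a horizontal band whose mediolateral extent equals the disk chord
    at ``v_i``.  A sector of angle ``2*pi*deficit_fraction`` (contiguous, full
    radial extent — deficits fill complete sectors) is rendered at
    ``dim_level * signal``; the rest at ``signal``.  Truth is the exact pixel
    count of dim SC pixels over all sections.
    """
    if not 0.0 <= deficit_fraction <= 1.0:
        raise ValueError(f"deficit_fraction must be in [0, 1], got {deficit_fraction}")
    rng = spec.rng(_STREAM_SC)
    h, w = spec.image_size
    n = spec.n_sections
    band_h = max(h // 2, 4)
    row0 = (h - band_h) // 2
    radius_px = 0.45 * w
    cx = (w - 1) / 2.0
    half_angle = np.pi * deficit_fraction
    center = np.deg2rad(spec.wedge_center_deg)

    sections: list[SectionImage] = []
    dim_total = 0
    sc_total = 0
    for i in range(n):
        v = -1.0 + (2 * i + 1) / n  # midpoint rostrocaudal sample in (-1, 1)
        chord = np.sqrt(max(0.0, 1.0 - v * v))
        u = (np.arange(w) - cx) / radius_px  # mediolateral coord, disk units
        in_chord = np.abs(u) <= chord
        sc_mask = np.zeros((h, w), dtype=bool)
        sc_mask[row0 : row0 + band_h, :] = in_chord[None, :]

        theta = np.arctan2(v, u)  # angle of each column's retinotopic point
        dtheta = np.angle(np.exp(1j * (theta - center)))
        in_wedge_col = (np.abs(dtheta) <= half_angle) & in_chord
        if deficit_fraction == 0.0:
            in_wedge_col[:] = False
        dim_mask = np.zeros((h, w), dtype=bool)
        dim_mask[row0 : row0 + band_h, :] = in_wedge_col[None, :]

        ctb = np.full((h, w), spec.background, dtype=float)
        ctb[sc_mask] += spec.signal
        ctb[dim_mask] -= spec.signal * (1.0 - spec.dim_level)
        ctb = _add_noise(ctb, spec, rng)

        dim_total += int(dim_mask.sum())
        sc_total += int(sc_mask.sum())
        sections.append(
            SectionImage(
                channels={"CTB": ctb},
                pixel_size=spec.pixel_size,
                tissue=Tissue.SC,
                eye=eye,
                animal_id=animal_id,
                section_index=i,
                metadata={
                    "sc_mask": sc_mask,
                    "background_level": spec.background,
                    "rostrocaudal_coord": v,
                },
            )
        )
    truth = GroundTruth(deficit_fraction=dim_total / sc_total if sc_total else 0.0)
    return sections, truth


# ---------------------------------------------------------------------------
# immunolabel fields
# ---------------------------------------------------------------------------

def generate_ihc_image(
    spec: SyntheticSpec,
    positive_area_fraction: float,
    *,
    tissue: Tissue = Tissue.SC,
    eye: Eye = Eye.SALINE,
    animal_id: str = "A0",
    marker: str = "BDNF",
) -> tuple[SectionImage, GroundTruth]:
    """Render a label channel where exactly ``round(f * n_roi)`` pixels sit at
    ``positive_level`` (above ``label_threshold``) and the rest at
    ``negative_level``; noise is added on top.  Truth is the exact count
    fraction before noise."""
    if not 0.0 <= positive_area_fraction <= 1.0:
        raise ValueError(
            f"positive_area_fraction must be in [0, 1], got {positive_area_fraction}"
        )
    rng = spec.rng(_STREAM_IHC)
    h, w = spec.image_size
    n_pix = h * w
    n_pos = int(round(positive_area_fraction * n_pix))
    flat = np.full(n_pix, spec.negative_level, dtype=float)
    pos_idx = rng.choice(n_pix, size=n_pos, replace=False)
    flat[pos_idx] = spec.positive_level
    img = _add_noise(flat.reshape(h, w), spec, rng)
    roi = np.ones((h, w), dtype=bool)
    truth = GroundTruth(positive_area_fraction=n_pos / n_pix)
    section = SectionImage(
        channels={marker: img},
        pixel_size=spec.pixel_size,
        tissue=tissue,
        eye=eye,
        animal_id=animal_id,
        metadata={"roi_mask": roi, "label_threshold": spec.label_threshold},
    )
    return section, truth


# ---------------------------------------------------------------------------
# nuclei fields
# ---------------------------------------------------------------------------

def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius: int,
    clearance: int,
    max_tries_per_disk: int = 2000,
) -> list[tuple[int, int]]:
    """Rejection-sample ``n`` non-overlapping disk centers with the given
    center-to-center clearance; raises if placement is infeasible."""
    h, w = shape
    margin = radius + clearance // 2 + 1
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        if n > 0:
            raise ValueError("image too small to place any cell")
    centers: list[tuple[int, int]] = []
    min_d2 = float(clearance) ** 2
    tries = 0
    budget = max(max_tries_per_disk * max(n, 1), 1)
    while len(centers) < n:
        if tries >= budget:
            raise ValueError(
                f"could not place {n} non-overlapping cells in {shape} "
                f"(placed {len(centers)})"
            )
        tries += 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_nuclei_image(
    spec: SyntheticSpec,
    n_cells: int,
    nuclear_fraction: float,
    *,
    signal_name: str = "NFKB",
    tissue: Tissue = Tissue.SC,
    eye: Eye = Eye.SALINE,
    animal_id: str = "A0",
) -> tuple[SectionImage, GroundTruth]:
    """Render DAPI disks plus a signal channel whose intensity is split
    between nucleus and perinuclear annulus so the per-cell nuclear fraction
    (nuclear mean over nuclear + annulus mean) equals ``nuclear_fraction``.

    Placement keeps annuli of distinct cells disjoint so masked-mean
    recovery is unambiguous.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0.0 <= nuclear_fraction <= 1.0:
        raise ValueError(f"nuclear_fraction must be in [0, 1], got {nuclear_fraction}")
    rng = spec.rng(_STREAM_NUCLEI)
    h, w = spec.image_size
    r = spec.cell_radius
    clearance = 2 * (r + spec.annulus_width) + 3
    centers = _place_disks(rng, (h, w), n_cells, r, clearance)

    dapi = np.zeros((h, w), dtype=float)
    signal = np.zeros((h, w), dtype=float)
    fractions: list[float] = []
    for (rr, cc) in centers:
        nuc = disk_mask((h, w), (rr, cc), r)
        annulus = disk_mask((h, w), (rr, cc), r + spec.annulus_width) & ~nuc
        dapi[nuc] = 1.0
        signal[nuc] = nuclear_fraction
        signal[annulus] = 1.0 - nuclear_fraction
        fractions.append(nuclear_fraction)
    dapi = _add_noise(dapi, spec, rng)
    # signal noise kept an order smaller than contrast; no offset (a constant
    # offset would bias every fraction toward 0.5)
    if spec.noise_sd > 0:
        signal = np.clip(signal + rng.normal(0, spec.noise_sd / 2, signal.shape), 0, None)
    truth = GroundTruth(nuclear_fraction_per_cell=fractions)
    section = SectionImage(
        channels={"DAPI": dapi, signal_name: signal},
        pixel_size=spec.pixel_size,
        tissue=tissue,
        eye=eye,
        animal_id=animal_id,
        metadata={
            "centers": centers,
            "cell_radius": r,
            "annulus_width": spec.annulus_width,
        },
    )
    return section, truth


# ---------------------------------------------------------------------------
# retinal cross-sections
# ---------------------------------------------------------------------------

def generate_retina_section(
    spec: SyntheticSpec,
    thickness_um: float,
    inl_um: float,
    onl_um: float,
    rgc_count: int,
    *,
    n_dapi_distractors: int = 0,
    n_ctb_distractors: int = 0,
    tilt_deg: float = 0.0,
    eye: Eye = Eye.SALINE,
    animal_id: str = "A0",
) -> tuple[SectionImage, GroundTruth]:
    """Render a layered vertical retinal section.

    Boundary lines (NFL, INL top/bottom, ONL top/bottom, RPE) run across the
    image with slope ``tan(tilt_deg)``; at tilt 0 the NFL-to-RPE vertical
    separation is exactly ``thickness_um``.  ``rgc_count`` CTB+/DAPI+ somas
    are placed in the ganglion cell layer, plus optional single-channel
    distractors recorded in the truth.
    """
    if thickness_um <= 0 or inl_um <= 0 or onl_um <= 0:
        raise ValueError("layer thicknesses must be > 0")
    if inl_um + onl_um >= thickness_um:
        raise ValueError("inl_um + onl_um must be < thickness_um")
    if rgc_count < 0:
        raise ValueError("rgc_count must be >= 0")
    rng = spec.rng(_STREAM_RETINA)
    px = spec.pixel_size
    h, w = spec.image_size
    slope = np.tan(np.deg2rad(tilt_deg))
    margin = 10.0 * px  # um above NFL at x = 0

    # distribute the non-nuclear-layer remainder: GCL zone, IPL gap, outer gap
    rem = thickness_um - inl_um - onl_um
    b_nfl = margin
    b_inl_top = b_nfl + 0.40 * rem
    b_inl_bot = b_inl_top + inl_um
    b_onl_top = b_inl_bot + 0.30 * rem
    b_onl_bot = b_onl_top + onl_um
    b_rpe = b_nfl + thickness_um
    boundaries = [b_nfl, b_inl_top, b_inl_bot, b_onl_top, b_onl_bot, b_rpe]

    yy, xx = np.mgrid[0:h, 0:w]
    # perpendicular depth from the tilted line family: stated thicknesses are
    # boundary-to-boundary perpendicular distances regardless of tilt
    cos_t = float(np.cos(np.deg2rad(tilt_deg)))
    depth_um = (yy * px - slope * (xx * px)) * cos_t

    def band(top: float, bot: float) -> np.ndarray:
        return (depth_um >= top) & (depth_um < bot)

    dapi = np.full((h, w), 0.05, dtype=float)
    ctb = np.full((h, w), 0.02, dtype=float)
    dapi[band(b_inl_top, b_inl_bot)] = 0.9
    dapi[band(b_onl_top, b_onl_bot)] = 0.9

    # somas in the GCL zone (between NFL and INL top)
    gcl_mask = band(b_nfl + 2 * px, b_inl_top - 2 * px)
    soma_r = max(3, spec.cell_radius // 2)
    n_total = rgc_count + n_dapi_distractors + n_ctb_distractors
    rows_ok = np.where(gcl_mask.any(axis=1))[0]
    if n_total > 0 and len(rows_ok) < 2 * soma_r + 2:
        raise ValueError("GCL band too thin for requested somas")
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_total:
        if tries > 5000 * max(n_total, 1):
            raise ValueError("could not place somas without overlap")
        tries += 1
        r0 = int(rng.choice(rows_ok))
        c0 = int(rng.integers(soma_r + 1, w - soma_r - 1))
        if not gcl_mask[max(r0 - soma_r, 0) : r0 + soma_r + 1, c0].all():
            continue
        if all((r0 - a) ** 2 + (c0 - b) ** 2 >= (2 * soma_r + 2) ** 2 for a, b in centers):
            centers.append((r0, c0))
    for k, (r0, c0) in enumerate(centers):
        m = disk_mask((h, w), (r0, c0), soma_r)
        if k < rgc_count:  # double positive
            dapi[m] = 1.0
            ctb[m] = 1.0
        elif k < rgc_count + n_dapi_distractors:
            dapi[m] = 1.0
        else:
            ctb[m] = 1.0
    dapi = _add_noise(dapi, spec, rng)
    ctb = _add_noise(ctb, spec, rng)

    truth = GroundTruth(layer_boundaries=boundaries, rgc_count=rgc_count)
    section = SectionImage(
        channels={"DAPI": dapi, "CTB": ctb},
        pixel_size=px,
        tissue=Tissue.RETINA,
        eye=eye,
        animal_id=animal_id,
        metadata={
            # vertical intercepts at x = 0 (um); pair with slope tan(tilt)
            "boundaries_um": {
                "NFL": b_nfl / cos_t,
                "INL_top": b_inl_top / cos_t,
                "INL_bottom": b_inl_bot / cos_t,
                "ONL_top": b_onl_top / cos_t,
                "ONL_bottom": b_onl_bot / cos_t,
                "RPE": b_rpe / cos_t,
            },
            "tilt_deg": tilt_deg,
            "gcl_mask": gcl_mask,
            "soma_centers": centers,
            "soma_radius": soma_r,
            "n_dapi_distractors": n_dapi_distractors,
            "n_ctb_distractors": n_ctb_distractors,
        },
    )
    return section, truth


# ---------------------------------------------------------------------------
# tonometry series
# ---------------------------------------------------------------------------

def generate_iop_series(
    spec: SyntheticSpec,
    baseline_mmHg: float = 20.12,
    elevation_fraction: float = 0.327,
    n_days: int = 28,
    *,
    n_pre_days: int = 3,
    iop_noise_sd: float = 2.6,
    animal_id: str = "A0",
) -> pd.DataFrame:
    """Daily bilateral tonometry readings: both eyes fluctuate about the
    baseline pre-injection (days <= 0); from day 1 the microbead eye reads
    about ``baseline * (1 + elevation_fraction)``.

    Defaults are calibrated to the reported cohort (~20 mmHg baseline, ~30%
    unilateral elevation sustained for 28 days).
    """
    if baseline_mmHg <= 0:
        raise ValueError("baseline_mmHg must be > 0")
    if elevation_fraction < 0:
        raise ValueError("elevation_fraction must be >= 0")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 2 <= n_pre_days <= 3:
        warnings.warn(f"{n_pre_days} pre-injection days (expected 2-3)", stacklevel=2)
    rng = spec.rng(_STREAM_IOP)
    rows = []
    days = list(range(-(n_pre_days - 1), 1)) + list(range(1, n_days + 1))
    elevated = baseline_mmHg * (1.0 + elevation_fraction)
    for day in days:
        for eye in (Eye.SALINE, Eye.MICROBEAD):
            mean = baseline_mmHg if (day <= 0 or eye is Eye.SALINE) else elevated
            iop = mean + (rng.normal(0.0, iop_noise_sd) if iop_noise_sd > 0 else 0.0)
            rows.append(
                {
                    "animal_id": animal_id,
                    "eye": eye.value,
                    "day": day,
                    "iop_mmHg": max(iop, 0.1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk I/O: TIFF + JSON sidecar, IOP CSV
# ---------------------------------------------------------------------------

def write_section(image: SectionImage, path: str | Path) -> Path:
    """Write channels as float32 TIFF pages plus a JSON sidecar with metadata;
    boolean mask arrays in metadata go to ``<stem>.masks.tif``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = sorted(image.channels)
    stack = np.stack([image.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, stack)
    masks = {
        k: np.asarray(v)
        for k, v in image.metadata.items()
        if isinstance(v, np.ndarray) and v.dtype == bool
    }
    sidecar = {
        "channel_names": names,
        "pixel_size": image.pixel_size,
        "tissue": image.tissue.value,
        "eye": image.eye.value,
        "animal_id": image.animal_id,
        "section_index": image.section_index,
        "metadata": _jsonable(
            {k: v for k, v in image.metadata.items() if k not in masks}
        ),
        "mask_names": sorted(masks),
    }
    if masks:
        mask_stack = np.stack([masks[k].astype(np.uint8) for k in sorted(masks)])
        tifffile.imwrite(path.with_suffix(".masks.tif"), mask_stack)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_section(path: str | Path) -> SectionImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {
        name: stack[i].astype(float) for i, name in enumerate(sidecar["channel_names"])
    }
    metadata = dict(sidecar.get("metadata", {}))
    mask_names = sidecar.get("mask_names", [])
    if mask_names:
        mask_stack = tifffile.imread(path.with_suffix(".masks.tif"))
        if mask_stack.ndim == 2:
            mask_stack = mask_stack[None]
        for i, name in enumerate(mask_names):
            metadata[name] = mask_stack[i].astype(bool)
    return SectionImage(
        channels=channels,
        pixel_size=sidecar["pixel_size"],
        tissue=Tissue(sidecar["tissue"]),
        eye=Eye(sidecar["eye"]),
        animal_id=sidecar["animal_id"],
        section_index=sidecar["section_index"],
        metadata=metadata,
    )


def write_iop_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ("animal_id", "group", "eye", "day", "iop_mmHg") if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.6g")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Enum):
        return obj.value
    return obj
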