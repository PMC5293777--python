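"""Percent-area immunolabel quantification and microbead:saline ratios.

Averaging order follows the study design: images -> per-animal value ->
per-animal microbead/saline ratio -> group mean +/- SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic_data import SectionImage, Tissue

try:
    from skimage.filters import threshold_otsu
except ImportError:  # pragma: no cover
    threshold_otsu = None


@dataclass
class LabelQuantResult:
    marker: str
    tissue: Tissue
    percent_area: float  # [0, 100]
    threshold_used: float
    roi_area_um2: float


@dataclass
class RatioRecord:
    animal_id: str
    marker: str
    tissue: Tissue
    microbead_value: float
    saline_value: float

    @property
    def ratio(self) -> float:
        return self.microbead_value / self.saline_value


@dataclass
class GroupRatioSummary:
    group: str
    n: int
    mean_ratio: float
    sem: float


def threshold_positive_label(
    image: SectionImage,
    channel: str,
    roi: np.ndarray,
    method: str = "fixed",
    threshold: float | None = None,
    pool_with: SectionImage | None = None,
) -> tuple[np.ndarray, float]:
    """Binary positive-label mask within the ROI.

    ``fixed`` uses the configured intensity threshold.  ``otsu`` derives the
    threshold from this image's ROI pooled with the fellow-eye image
    (``pool_with``) so both eyes of a pair share one threshold, as the
    acquisition settings were identical between eyes.  A constant image under
    Otsu falls back to the fixed threshold with a warning.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("ROI shape mismatch")
    if not roi.any():
        raise ValueError("ROI is empty")
    values = image.channel(channel)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        pooled = values[roi]
        if pool_with is not None:
            pooled = np.concatenate([pooled, pool_with.channel(channel).ravel()])
        if np.ptp(pooled) < 1e-12 or threshold_otsu is None:
            if threshold is None:
                raise ValueError("constant image under otsu and no fixed fallback")
            warnings.warn(
                "constant image under otsu; falling back to fixed threshold",
                stacklevel=2,
            )
            thr = float(threshold)
        else:
            thr = float(threshold_otsu(pooled))
    else:
        raise ValueError(f"unknown method {method!r}")
    return (values > thr) & roi, thr


def percent_area_positive(
    mask: np.ndarray,
    roi: np.ndarray,
    *,
    marker: str = "",
    tissue: Tissue = Tissue.SC,
    pixel_size: float = 1.0,
    threshold_used: float = float("nan"),
) -> LabelQuantResult:
    """Exact positive-pixel fraction of the ROI, as a percentage."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    if (mask & ~roi).any():
        raise ValueError("mask extends outside ROI")
    return LabelQuantResult(
        marker=marker,
        tissue=Tissue(tissue),
        percent_area=100.0 * int(mask.sum()) / n_roi,
        threshold_used=threshold_used,
        roi_area_um2=n_roi * pixel_size**2,
    )


def microbead_saline_ratio(
    per_animal_values: Mapping[str, tuple[float, float]] | Sequence[tuple[str, float, float]],
    *,
    group: str = "VEHICLE",
    marker: str = "",
    tissue: Tissue = Tissue.SC,
) -> tuple[list[RatioRecord], GroupRatioSummary]:
    """Per-animal microbead/saline ratios then group mean +/- SEM.

    Each entry is (microbead_value, saline_value) for one animal — already
    averaged over that animal's images.  Animals with a zero saline value
    are excluded with a warning (ratio undefined).
    """
    if isinstance(per_animal_values, Mapping):
        items = [(a, mb, sal) for a, (mb, sal) in per_animal_values.items()]
    else:
        items = [tuple(x) for x in per_animal_values]
    if not items:
        raise ValueError("need at least one animal")
    records: list[RatioRecord] = []
    for animal_id, mb, sal in items:
        if sal == 0:
            warnings.warn(
                f"animal {animal_id}: saline value is 0, ratio undefined; excluded",
                stacklevel=2,
            )
            continue
        if mb < 0 or sal < 0:
            raise ValueError(f"animal {animal_id}: negative quantity")
        records.append(
            RatioRecord(
                animal_id=str(animal_id),
                marker=marker,
                tissue=Tissue(tissue),
                microbead_value=float(mb),
                saline_value=float(sal),
            )
        )
    if not records:
        raise ValueError("no animal had a usable saline value")
    ratios = np.array([r.ratio for r in records])
    n = len(ratios)
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    summary = GroupRatioSummary(
        group=group, n=n, mean_ratio=float(ratios.mean()), sem=sem
    )
    return records, summary
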