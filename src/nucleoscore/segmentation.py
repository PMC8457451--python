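"""Nucleus instance masks for the feature stage.

Segmentation proper is a pluggable input: production use supplies
precomputed label maps (e.g. from a trained network); for fixtures a
deterministic classical baseline (threshold + watershed) is provided.  Both
are followed by the median-area post-processing filter: per image, nuclei
larger than 200% of the median nucleus area (merged nuclei) or smaller than
50% of it (nuclei insufficiently represented in the image plane) are
removed, with the median computed once over the pre-filter population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters, measure, morphology, segmentation as skseg

from nucleoscore.features import to_grayscale

__all__ = [
    "NucleusRecord",
    "SegmentationResult",
    "segment_baseline",
    "filter_by_size",
    "drop_border_instances",
    "extract_nuclei",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus: geometry plus its image crop and binary mask."""

    nucleus_id: int
    area_px: int
    centroid: tuple[float, float]  # (row, col), 0-based
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max)
    mask: np.ndarray  # bool raster of the bbox
    crop: np.ndarray  # uint8 RGB raster of the bbox


@dataclass
class SegmentationResult:
    label_map: np.ndarray
    nuclei: list[NucleusRecord]
    median_area_px: float


def segment_baseline(
    img: np.ndarray,
    threshold: str = "otsu",
    min_marker_distance: int = 7,
    min_object_area: int = 12,
) -> np.ndarray:
    """Classical nucleus segmentation: threshold, fill, distance watershed.

    Nuclei (hematoxylin) are darker than the eosin background, so foreground
    is grayscale below the global threshold.  Touching nuclei are split by
    marker-based watershed on the distance transform.  Deterministic; meant
    for the synthetic fixtures, not claimed adequate for clinical H&E.
    """
    img = np.asarray(img)
    gray = to_grayscale(img)
    if gray.max() == gray.min():
        return np.zeros(gray.shape, dtype=np.int64)
    if threshold == "otsu":
        t = filters.threshold_otsu(gray)
    else:
        t = float(threshold)
    fg = gray < t
    fg = ndimage.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=min_object_area - 1)
    if not fg.any():
        return np.zeros(gray.shape, dtype=np.int64)
    dist = ndimage.distance_transform_edt(fg)
    peaks = skfeature.peak_local_max(
        dist,
        min_distance=min_marker_distance,
        labels=fg,
        exclude_border=False,
    )
    markers = np.zeros(gray.shape, dtype=np.int64)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return measure.label(fg).astype(np.int64)
    labels = skseg.watershed(-dist, markers, mask=fg)
    return labels.astype(np.int64)


def _instance_areas(lm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids, counts = np.unique(lm[lm > 0], return_counts=True)
    return ids, counts


def filter_by_size(
    lm: np.ndarray, low: float = 0.5, high: float = 2.0
) -> np.ndarray:
    """Remove merged and partially visible nuclei by the median-area rule.

    The median area ``m`` is computed once over all pre-filter instances of
    this image; instances with area strictly greater than ``high * m`` or
    strictly smaller than ``low * m`` are set to background.  Surviving
    labels keep their ids.  Instances exactly at the bounds survive.
    """
    lm = np.asarray(lm)
    ids, counts = _instance_areas(lm)
    if ids.size == 0:
        return lm.copy()
    median = float(np.median(counts))
    keep = (counts <= high * median) & (counts >= low * median)
    removed = set(ids[~keep].tolist())
    if not removed:
        return lm.copy()
    out = lm.copy()
    out[np.isin(out, list(removed))] = 0
    return out


def drop_border_instances(lm: np.ndarray) -> np.ndarray:
    """Remove instances touching the image frame (optional, off by default)."""
    lm = np.asarray(lm)
    border_ids = set(np.unique(lm[0, :])) | set(np.unique(lm[-1, :]))
    border_ids |= set(np.unique(lm[:, 0])) | set(np.unique(lm[:, -1]))
    border_ids.discard(0)
    if not border_ids:
        return lm.copy()
    out = lm.copy()
    out[np.isin(out, list(border_ids))] = 0
    return out


def extract_nuclei(
    img: np.ndarray,
    lm: np.ndarray,
    apply_size_filter: bool = True,
    drop_border: bool = False,
) -> SegmentationResult:
    """Build per-nucleus records (crop + mask) from an image and label map.

    The median area reported in the result is the per-image pre-filter
    median, the same quantity the size filter uses.
    """
    img = np.asarray(img)
    lm = np.asarray(lm)
    if img.shape[:2] != lm.shape:
        raise ValueError(
            f"image {img.shape[:2]} and label map {lm.shape} sizes differ"
        )
    _, pre_counts = _instance_areas(lm)
    median = float(np.median(pre_counts)) if pre_counts.size else float("nan")
    filtered = filter_by_size(lm) if apply_size_filter else lm.copy()
    if drop_border:
        filtered = drop_border_instances(filtered)
    nuclei: list[NucleusRecord] = []
    for region in measure.regionprops(filtered.astype(np.int64)):
        if region.area == 0:
            warnings.warn(f"label {region.label} has zero pixels; skipped")
            continue
        rmin, cmin, rmax, cmax = region.bbox
        nuclei.append(
            NucleusRecord(
                nucleus_id=int(region.label),
                area_px=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                bbox=(rmin, cmin, rmax, cmax),
                mask=region.image.copy(),
                crop=img[rmin:rmax, cmin:cmax].copy(),
            )
        )
    return SegmentationResult(label_map=filtered, nuclei=nuclei, median_area_px=median)
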