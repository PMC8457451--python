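"""Per-nucleus morphometry: 23 color, 4 shape and 9 spatial features.

Color features describe chromatin distribution and membrane margination:
channel-wise mean/std, intensity ratios between three equal-area concentric
zones of the nucleus (border, middle, center — tertiles of the
distance-to-edge transform), six gray-level co-occurrence matrix (GLCM)
texture properties, and the Shannon entropy of the masked grayscale
histogram.  Shape features (area, perimeter, eccentricity, solidity) come
from the instance mask.  Spatial features capture nuclear crowding: counts
of neighboring nuclei within radii ``x * r_mean`` for
``x in {3, 5, 7, 9, 15, 20, 25, 30}``, where ``r_mean`` is the mean
equivalent-disk radius of all nuclei in the image, plus the Euclidean
nearest-neighbor distance.  No correction is applied for nuclei near the
image border.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform
from skimage import measure
from skimage.feature import graycomatrix, graycoprops

__all__ = [
    "COLOR_FEATURES",
    "SHAPE_FEATURES",
    "SPATIAL_FEATURES",
    "ALL_FEATURES",
    "CROWDING_MULTIPLIERS",
    "to_grayscale",
    "ring_zones",
    "color_features",
    "shape_features",
    "mean_radius",
    "crowding",
    "nn_distance",
    "extract_all",
]

#: Radius multipliers for the crowding counts.
CROWDING_MULTIPLIERS = (3, 5, 7, 9, 15, 20, 25, 30)

_CHANNELS = ("r", "g", "b", "gray")
_GLCM_PROPS = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "correlation",
    "ASM",
)

COLOR_FEATURES: tuple[str, ...] = (
    tuple(f"mean_{c}" for c in _CHANNELS)
    + tuple(f"std_{c}" for c in _CHANNELS)
    + tuple(f"ratio_border_middle_{c}" for c in _CHANNELS)
    + tuple(f"ratio_border_center_{c}" for c in _CHANNELS)
    + ("glcm_contrast", "glcm_dissimilarity", "glcm_homogeneity",
       "glcm_energy", "glcm_correlation", "glcm_asm")
    + ("shannon_entropy",)
)
SHAPE_FEATURES: tuple[str, ...] = ("area", "perimeter", "eccentricity", "solidity")
SPATIAL_FEATURES: tuple[str, ...] = tuple(
    f"crowd_x{x}" for x in CROWDING_MULTIPLIERS
) + ("nn_distance",)

#: Canonical per-nucleus feature order: 23 color + 4 shape + 9 spatial = 36.
ALL_FEATURES: tuple[str, ...] = COLOR_FEATURES + SHAPE_FEATURES + SPATIAL_FEATURES

#: ITU-R 709 luminance weights (configurable through the `weights` argument).
GRAY_WEIGHTS = (0.2125, 0.7154, 0.0721)


def to_grayscale(
    crop: np.ndarray, weights: tuple[float, float, float] = GRAY_WEIGHTS
) -> np.ndarray:
    """Luminance grayscale of an 8-bit RGB raster, real-valued in [0, 255]."""
    crop = np.asarray(crop, dtype=np.float64)
    if crop.ndim == 2:
        return crop
    w = np.asarray(weights, dtype=np.float64)
    return crop[..., :3] @ w


def ring_zones(mask: np.ndarray) -> np.ndarray:
    """Partition a nucleus mask into three equal-area concentric zones.

    Returns an int raster over the mask's bounding raster with 0 outside the
    mask, 1 = border, 2 = middle, 3 = center.  Zones are tertiles of the
    Euclidean distance-to-edge transform within the mask: the third of
    pixels closest to the nucleus boundary is the border, the deepest third
    the center.  Ties are broken by (distance, row, col) sort so the
    partition is deterministic, and zone sizes differ pairwise by at most 1.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("ring zones require a mask with >= 3 pixels")
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, rows, dist[rows, cols]))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]  # border, middle, center
    zones = np.zeros(mask.shape, dtype=np.int8)
    start = 0
    for zone_id, size in zip((1, 2, 3), sizes):
        idx = order[start : start + size]
        zones[rows[idx], cols[idx]] = zone_id
        start += size
    return zones


def _masked_glcm_props(gray8: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Six GLCM properties on the masked grayscale crop.

    Distance 1 px, the four principal directions averaged, 256 levels,
    symmetric and normalized matrices.  Out-of-mask pixels are assigned a
    reserved 257th level and all co-occurrence pairs touching it are
    discarded before normalization.
    """
    levels = 256
    img = gray8.astype(np.int32)
    img[~mask] = levels  # reserved out-of-mask level
    glcm = graycomatrix(
        img,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )
    counts = glcm[:levels, :levels, :, :].astype(np.float64)
    valid = counts.sum(axis=(0, 1))[0] > 0  # per-angle pair counts
    out: dict[str, float] = {}
    if not valid.any():
        for prop in _GLCM_PROPS:
            out[f"glcm_{prop.lower()}"] = np.nan
        return out
    single_valued = np.unique(gray8[mask]).size == 1
    for prop in _GLCM_PROPS:
        vals = graycoprops(counts, prop)[0]  # one value per angle
        out[f"glcm_{prop.lower()}"] = float(np.mean(vals[valid]))
    if single_valued:
        # a constant crop has zero GLCM variance; correlation is defined as 0
        out["glcm_correlation"] = 0.0
    return out


def _shannon_entropy(gray8: np.ndarray, mask: np.ndarray) -> float:
    """Base-2 entropy of the 256-bin histogram of masked grayscale pixels."""
    hist = np.bincount(gray8[mask].ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def color_features(crop: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """The 23 color features of one nucleus.

    Only pixels under the mask enter every statistic.  Zone ratios are
    mean(border) / mean(middle) and mean(border) / mean(center) per channel;
    a zero denominator yields NA.  Standard deviations use population
    normalization.
    """
    crop = np.asarray(crop)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    gray = to_grayscale(crop)
    gray8 = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    channels = {
        "r": crop[..., 0].astype(np.float64),
        "g": crop[..., 1].astype(np.float64),
        "b": crop[..., 2].astype(np.float64),
        "gray": gray,
    }
    out: dict[str, float] = {}
    for name, chan in channels.items():
        vals = chan[mask]
        out[f"mean_{name}"] = float(vals.mean())
        out[f"std_{name}"] = float(vals.std())
    if mask.sum() >= 3:
        zones = ring_zones(mask)
        for name, chan in channels.items():
            zone_means = {z: chan[zones == z].mean() for z in (1, 2, 3)}
            for ratio_name, denom_zone in (("middle", 2), ("center", 3)):
                denom = zone_means[denom_zone]
                key = f"ratio_border_{ratio_name}_{name}"
                out[key] = float(zone_means[1] / denom) if denom != 0 else np.nan
    else:
        for name in channels:
            out[f"ratio_border_middle_{name}"] = np.nan
            out[f"ratio_border_center_{name}"] = np.nan
    out.update(_masked_glcm_props(gray8, mask))
    out["shannon_entropy"] = _shannon_entropy(gray8, mask)
    return out


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Area, perimeter, eccentricity and solidity of one nucleus mask.

    Area is the pixel count of the instance; perimeter is the standard
    contour-weighted estimate; eccentricity is that of the ellipse with
    matched second central moments; solidity is area over convex-hull area.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    regions = measure.regionprops(mask.astype(np.uint8))
    region = max(regions, key=lambda r: r.area)
    return {
        "area": float(region.area),
        "perimeter": float(region.perimeter),
        "eccentricity": float(region.eccentricity),
        "solidity": float(region.solidity),
    }


def mean_radius(areas) -> float:
    """Mean equivalent-disk radius of one image's nuclei.

    ``r_mean = (1/n) * sum_k sqrt(A_k / pi)`` over the post-filter nuclei
    of a single image; the basis for all crowding radii.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size == 0:
        return float("nan")
    return float(np.mean(np.sqrt(areas / np.pi)))


def crowding(centroids, r_mean: float, multipliers=CROWDING_MULTIPLIERS) -> np.ndarray:
    """Neighbor counts within radii ``x * r_mean`` for each nucleus.

    For nucleus i and multiplier x, counts the OTHER nuclei whose centroid
    lies at Euclidean distance <= x * r_mean (inclusive).  No edge
    correction is performed for nuclei near the image border.
    Returns an (n, len(multipliers)) integer array.
    """
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one centroid")
    if r_mean <= 0:
        raise ValueError("r_mean must be positive")
    n = pts.shape[0]
    counts = np.zeros((n, len(multipliers)), dtype=np.int64)
    if n == 1:
        return counts
    dmat = squareform(pdist(pts))
    np.fill_diagonal(dmat, np.inf)  # exclude self
    for j, x in enumerate(multipliers):
        counts[:, j] = (dmat <= x * r_mean).sum(axis=1)
    return counts


def nn_distance(centroids) -> np.ndarray:
    """Euclidean distance to the nearest neighboring nucleus; NA if alone."""
    pts = np.asarray(centroids, dtype=np.float64)
    n = pts.shape[0]
    if n < 2:
        return np.full(n, np.nan)
    dmat = squareform(pdist(pts))
    np.fill_diagonal(dmat, np.inf)
    return dmat.min(axis=1)


def extract_all(seg, img: np.ndarray) -> pd.DataFrame:
    """One 36-feature row per nucleus of a segmented image.

    Spatial features use this image's own context: ``r_mean`` from its
    post-filter areas and its own centroid set.  Deterministic.
    """
    nuclei = seg.nuclei
    if not nuclei:
        return pd.DataFrame(columns=["nucleus_id", *ALL_FEATURES])
    areas = [rec.area_px for rec in nuclei]
    centroids = [rec.centroid for rec in nuclei]
    r_mean = mean_radius(areas)
    crowd = crowding(centroids, r_mean)
    nnd = nn_distance(centroids)
    rows = []
    for i, rec in enumerate(nuclei):
        row: dict[str, float] = {"nucleus_id": rec.nucleus_id}
        row.update(color_features(rec.crop, rec.mask))
        row.update(shape_features(rec.mask))
        for j, x in enumerate(CROWDING_MULTIPLIERS):
            row[f"crowd_x{x}"] = float(crowd[i, j])
        row["nn_distance"] = float(nnd[i])
        rows.append(row)
    return pd.DataFrame(rows, columns=["nucleus_id", *ALL_FEATURES])
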