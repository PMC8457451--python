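"""Reading and writing of on-disk artifacts and resolution harmonization.

Dataset manifests are plain CSV with one row per (patient, image):

    patient_id,class_label,image_path,labelmap_path,resolution_um_per_px

``class_label`` is ``"PTC"`` / ``"nonPTC"`` (or empty for unlabeled
inference data) and ``labelmap_path`` may be empty when segmentation is to
be computed.  Images are 8-bit RGB TIFF/PNG; label maps are 16-bit
single-channel TIFF/PNG with 0 as background.  All pixel coordinates in the
package are row-major and 0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ClassLabel",
    "ManifestEntry",
    "DatasetManifest",
    "read_manifest",
    "write_manifest",
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "rescale_image",
    "harmonize_resolution",
    "write_feature_table",
    "read_feature_table",
    "read_vote_table",
    "write_vote_table",
]

#: Working resolution of the pipeline in micrometres per pixel (40x scans).
DEFAULT_RESOLUTION_UM_PER_PX = 0.23

NA_TOKEN = "NA"


class ClassLabel(str, enum.Enum):
    """Binary diagnosis: nuclei with or without PTC-like alterations."""

    PTC_LIKE = "PTC"
    NON_PTC_LIKE = "nonPTC"


@dataclass
class ManifestEntry:
    """One patient: class label, image files and optional label maps."""

    patient_id: str
    class_label: ClassLabel | None
    image_paths: list[Path]
    labelmap_paths: list[Path] | None = None
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX


@dataclass
class DatasetManifest:
    """Validated collection of :class:`ManifestEntry`, unique patient ids."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.patient_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id values: {dupes}")
        for e in self.entries:
            if not e.image_paths:
                raise ValueError(f"patient {e.patient_id!r} has no images")
            if e.labelmap_paths is not None and len(e.labelmap_paths) != len(
                e.image_paths
            ):
                raise ValueError(
                    f"patient {e.patient_id!r}: {len(e.image_paths)} images but "
                    f"{len(e.labelmap_paths)} label maps"
                )
            if e.resolution_um_per_px <= 0:
                raise ValueError("resolution_um_per_px must be positive")

    @property
    def patient_ids(self) -> list[str]:
        return [e.patient_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _parse_label(raw) -> ClassLabel | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    return ClassLabel(str(raw))


def read_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    """Read and validate a CSV dataset manifest.

    Parameters
    ----------
    path
        Manifest CSV with one row per (patient, image).
    check_files
        Verify that every referenced image / label map exists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    root = path.parent
    entries: list[ManifestEntry] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        labels = {_parse_label(v) for v in grp.get("class_label", pd.Series([None]))}
        if len(labels) > 1:
            raise ValueError(f"patient {pid!r} has conflicting class labels")
        imgs = [root / p for p in grp["image_path"]]
        lms: list[Path] | None = None
        if "labelmap_path" in grp.columns and grp["labelmap_path"].notna().all():
            lms = [root / p for p in grp["labelmap_path"]]
        res = DEFAULT_RESOLUTION_UM_PER_PX
        if "resolution_um_per_px" in grp.columns:
            res = float(grp["resolution_um_per_px"].iloc[0])
        entries.append(ManifestEntry(str(pid), labels.pop(), imgs, lms, res))
    manifest = DatasetManifest(entries)
    if check_files:
        for e in manifest:
            for p in e.image_paths + (e.labelmap_paths or []):
                if not Path(p).exists():
                    raise FileNotFoundError(f"patient {e.patient_id!r}: {p}")
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest as CSV, paths stored relative to the CSV location."""
    path = Path(path)
    root = path.parent
    rows = []
    for e in manifest:
        lms = e.labelmap_paths or [None] * len(e.image_paths)
        for img, lm in zip(e.image_paths, lms):
            rows.append(
                {
                    "patient_id": e.patient_id,
                    "class_label": e.class_label.value if e.class_label else "",
                    "image_path": _relativize(img, root),
                    "labelmap_path": _relativize(lm, root) if lm else "",
                    "resolution_um_per_px": e.resolution_um_per_px,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _relativize(p: Path, root: Path) -> str:
    p = Path(p)
    try:
        return p.relative_to(root).as_posix()
    except ValueError:
        return p.as_posix()


# ---------------------------------------------------------------------------
# images and label maps


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image as an (H, W, 3) uint8 array."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def read_labelmap(path: str | Path) -> np.ndarray:
    """Read an instance label map (single-channel integer raster)."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"label map must be single-channel, got shape {arr.shape}")
    return arr.astype(np.int64)


def write_labelmap(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as 16-bit PNG/TIFF; lossless integer round-trip."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed 16-bit unsigned range")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def rescale_image(
    img: np.ndarray, factor: float, order: int = 3
) -> np.ndarray:
    """Rescale an RGB image by `factor` using spline interpolation.

    Matches the resolution harmonization used when mixing 20x and 40x
    material: e.g. a 20x tile is upscaled by a factor of two with order-3
    splines before segmentation and feature extraction.  Intensities are
    clipped back to [0, 255] and rounded to 8-bit.
    """
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    if not 0 <= order <= 5:
        raise ValueError("spline order must be in [0, 5]")
    img = np.asarray(img)
    if factor == 1.0:
        return img.astype(np.uint8, copy=True)
    out = ndimage.zoom(
        img.astype(np.float64),
        (factor, factor, 1) if img.ndim == 3 else factor,
        order=order,
        mode="reflect",
        grid_mode=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def harmonize_resolution(
    img: np.ndarray,
    resolution_um_per_px: float,
    target_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    order: int = 3,
) -> np.ndarray:
    """Bring an image to the pipeline's working resolution by spline rescale."""
    factor = resolution_um_per_px / target_um_per_px
    if abs(factor - 1.0) < 1e-9:
        return np.asarray(img, dtype=np.uint8)
    return rescale_image(img, factor, order=order)


# ---------------------------------------------------------------------------
# tables


def write_feature_table(
    df: pd.DataFrame, path: str | Path, feature_columns: Sequence[str] | None = None
) -> None:
    """Write a feature table as CSV with a stable, canonical column order.

    Identifier columns come first (any of patient_id / image_id / nucleus_id /
    class_label / n_nuclei present in the frame), then the features in the
    given canonical order (default: remaining columns in frame order).
    Non-finite values are written as the explicit token ``NA``.
    """
    if df.columns.duplicated().any():
        raise ValueError("feature table has duplicate column names")
    id_cols = [
        c
        for c in ("patient_id", "image_id", "nucleus_id", "class_label", "n_nuclei")
        if c in df.columns
    ]
    if feature_columns is None:
        feature_columns = [c for c in df.columns if c not in id_cols]
    ordered = df[id_cols + list(feature_columns)]
    ordered.to_csv(Path(path), index=False, na_rep=NA_TOKEN)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), na_values=[NA_TOKEN], dtype={"patient_id": str})


def read_vote_table(path: str | Path) -> pd.DataFrame:
    """Read a pathologist-vote table.

    Columns: case_id, votes_non_ptc, votes_ptc, rereviewed (bool),
    rereview_ptc_count (optional integer, present iff rereviewed).
    """
    df = pd.read_csv(Path(path), na_values=[NA_TOKEN], dtype={"case_id": str})
    required = {"case_id", "votes_non_ptc", "votes_ptc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"vote table missing columns: {sorted(missing)}")
    if "rereviewed" not in df.columns:
        df["rereviewed"] = False
    df["rereviewed"] = df["rereviewed"].astype(bool)
    if "rereview_ptc_count" not in df.columns:
        df["rereview_ptc_count"] = np.nan
    return df


def write_vote_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["case_id", "votes_non_ptc", "votes_ptc", "rereviewed", "rereview_ptc_count"]
    out = df[[c for c in cols if c in df.columns]]
    out.to_csv(Path(path), index=False, na_rep=NA_TOKEN)
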