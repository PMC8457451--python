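"""End-to-end orchestration: segmentation -> features -> aggregation -> CV.

Thin composition layer used by the CLI, the tests and the acceptance
script; all science lives in the stage modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nucleoscore import aggregation, features, io_manifest, model_selection, segmentation
from nucleoscore.io_manifest import DatasetManifest
from nucleoscore.model_selection import EvaluationReport, PipelineConfig
from nucleoscore.synthetic import SyntheticDataset

__all__ = [
    "extract_image_features",
    "nucleus_table_from_dataset",
    "patient_table_from_dataset",
    "nucleus_table_from_manifest",
    "run_synthetic_experiment",
]


def extract_image_features(
    img: np.ndarray, labelmap: np.ndarray | None = None, drop_border: bool = False
) -> pd.DataFrame:
    """Per-nucleus feature table of one image.

    Uses the given ground-truth/precomputed label map if any, else the
    classical baseline segmenter; always applies the median-area filter.
    """
    if labelmap is None:
        labelmap = segmentation.segment_baseline(img)
    seg = segmentation.extract_nuclei(img, labelmap, drop_border=drop_border)
    return features.extract_all(seg, img)


def nucleus_table_from_dataset(
    ds: SyntheticDataset, use_ground_truth: bool = True
) -> pd.DataFrame:
    """Pool per-nucleus features over every image of a synthetic cohort."""
    frames = []
    for pat in ds.patients:
        for i, img in enumerate(pat.images):
            lm = pat.label_maps[i] if use_ground_truth else None
            df = extract_image_features(img, lm)
            df.insert(0, "patient_id", pat.patient_id)
            df.insert(1, "image_id", f"{pat.patient_id}_{i}")
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _dataset_manifest(ds: SyntheticDataset) -> DatasetManifest:
    from nucleoscore.io_manifest import ManifestEntry
    from pathlib import Path

    return DatasetManifest(
        [
            ManifestEntry(
                p.patient_id,
                p.class_label,
                [Path(f"{p.patient_id}_{i}.png") for i in range(len(p.images))],
            )
            for p in ds.patients
        ]
    )


def patient_table_from_dataset(
    ds: SyntheticDataset, use_ground_truth: bool = True
) -> pd.DataFrame:
    nuclei = nucleus_table_from_dataset(ds, use_ground_truth=use_ground_truth)
    return aggregation.aggregate(nuclei, _dataset_manifest(ds))


def nucleus_table_from_manifest(
    manifest: DatasetManifest, use_precomputed: bool = True
) -> pd.DataFrame:
    """Per-nucleus features for an on-disk dataset, resolution-harmonized."""
    frames = []
    for entry in manifest:
        factor = entry.resolution_um_per_px / io_manifest.DEFAULT_RESOLUTION_UM_PER_PX
        lms = entry.labelmap_paths if use_precomputed else None
        for i, img_path in enumerate(entry.image_paths):
            img = io_manifest.read_image(img_path)
            if abs(factor - 1.0) > 1e-9:
                img = io_manifest.rescale_image(img, factor, order=3)
            lm = None
            if lms is not None:
                lm = io_manifest.read_labelmap(lms[i])
                if abs(factor - 1.0) > 1e-9:
                    from scipy import ndimage as ndi

                    # labels are categorical: nearest-neighbor rescale
                    lm = ndi.zoom(lm, factor, order=0, grid_mode=True, mode="nearest")
            df = extract_image_features(img, lm)
            df.insert(0, "patient_id", entry.patient_id)
            df.insert(1, "image_id", img_path.stem)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_synthetic_experiment(
    ds: SyntheticDataset, cfg: PipelineConfig, use_ground_truth: bool = True
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Full pipeline on a synthetic cohort: features, aggregation, nested CV."""
    patients = patient_table_from_dataset(ds, use_ground_truth=use_ground_truth)
    report = model_selection.nested_cv(patients, cfg)
    return patients, report
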