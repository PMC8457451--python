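"""Patient-level aggregation of per-nucleus features.

Nuclei are pooled across ALL images of a patient (not averaged per image
first) and each of the 36 features is summarized by its mean and standard
deviation, yielding 72 features per patient.  Standard deviations use
population normalization (divide by n), so a single-nucleus patient gets
std 0 rather than NA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from nucleoscore.features import ALL_FEATURES

__all__ = ["PATIENT_FEATURES", "aggregate"]

#: Canonical 72-column order: mean of each feature, then std of each feature.
PATIENT_FEATURES: tuple[str, ...] = tuple(f"mean_{f}" for f in ALL_FEATURES) + tuple(
    f"std_{f}" for f in ALL_FEATURES
)


def aggregate(per_nucleus: pd.DataFrame, manifest=None) -> pd.DataFrame:
    """Collapse a per-nucleus feature table to one row per patient.

    Parameters
    ----------
    per_nucleus
        Table with a ``patient_id`` column and the 36 canonical feature
        columns (extra id columns are ignored).
    manifest
        Optional :class:`~nucleoscore.io_manifest.DatasetManifest`; when
        given, class labels are attached and unknown patients rejected.

    Returns
    -------
    DataFrame with columns ``patient_id``, optional ``class_label``,
    ``n_nuclei`` and the 72 aggregate features.  Per-feature NA values
    (e.g. ``nn_distance`` on single-nucleus images) are excluded from that
    feature's mean/std; a patient with zero nuclei is dropped with a
    warning.  ``n_nuclei`` is metadata, never one of the 72.
    """
    missing = [f for f in ALL_FEATURES if f not in per_nucleus.columns]
    if missing:
        raise ValueError(f"per-nucleus table missing features: {missing[:5]} ...")
    if "patient_id" not in per_nucleus.columns:
        raise ValueError("per-nucleus table needs a patient_id column")
    labels = {}
    if manifest is not None:
        known = set(manifest.patient_ids)
        unknown = set(per_nucleus["patient_id"].astype(str)) - known
        if unknown:
            raise ValueError(f"nuclei for patients absent from manifest: {sorted(unknown)}")
        labels = {
            e.patient_id: (e.class_label.value if e.class_label else None)
            for e in manifest
        }
    rows = []
    for pid, grp in per_nucleus.groupby("patient_id", sort=True):
        if len(grp) == 0:
            warnings.warn(f"patient {pid!r} has no nuclei; dropped")
            continue
        row: dict = {"patient_id": str(pid)}
        if manifest is not None:
            row["class_label"] = labels.get(str(pid))
        row["n_nuclei"] = int(len(grp))
        for f in ALL_FEATURES:
            vals = grp[f].to_numpy(dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                warnings.warn(f"patient {pid!r}: feature {f!r} all-NA; aggregate NA")
                row[f"mean_{f}"] = np.nan
                row[f"std_{f}"] = np.nan
            else:
                row[f"mean_{f}"] = float(vals.mean())
                row[f"std_{f}"] = float(vals.std())  # population std; n=1 -> 0
        rows.append(row)
    id_cols = ["patient_id"] + (["class_label"] if manifest is not None else []) + [
        "n_nuclei"
    ]
    return pd.DataFrame(rows, columns=id_cols + list(PATIENT_FEATURES))
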