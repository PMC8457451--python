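"""Synthetic H&E-like fixture datasets with ground-truth instance masks.

Tiles emulate hematoxylin-stained nuclei on an eosin-pink background.
Nuclei are radially perturbed ellipses (low-order harmonics 2-6 scaled by a
boundary-irregularity amplitude), placed by a clustered point process to
create crowding, and shaded with a radial intensity profile whose center is
brighter by a configurable "chromatin clearing" factor.  The two class
presets differ in the directions pathologists use for PTC-like nuclei:
larger nuclei, more irregular membranes, stronger central clearing and more
crowding.  A synthetic pathologist-vote table is drawn from a beta-binomial
whose mean tracks the class and whose concentration controls how many
borderline cases appear.

The generator is deterministic under its seed.  It emulates the geometric
and chromatic contrasts the morphometry measures — not stain variation,
scanner artifacts or real chromatin texture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from nucleoscore import io_manifest
from nucleoscore.io_manifest import (
    ClassLabel,
    DatasetManifest,
    ManifestEntry,
)

__all__ = [
    "ClassPreset",
    "GeneratorConfig",
    "SyntheticPatient",
    "SyntheticDataset",
    "generate_dataset",
    "perturb_labels",
    "write_dataset",
]

#: Hematoxylin-purple nuclei on an eosin-pink background (cosmetic).
NUCLEUS_RGB = (88, 60, 130)
BACKGROUND_RGB = (235, 200, 215)


@dataclass
class ClassPreset:
    """Nuclear phenotype parameters of one class."""

    radius_mean: float  # px, equivalent-disk radius
    radius_sd: float
    axis_ratio: tuple[float, float]  # (min, max) minor/major axis ratio
    boundary_irregularity: float  # radial perturbation, fraction of radius
    center_clearing: float  # >= 1; center / border intensity ratio
    base_color: tuple[int, int, int] = NUCLEUS_RGB
    noise_sd: float = 6.0
    crowding_cluster_sd: float = 28.0  # scatter of nuclei around cluster seeds
    vote_ptc_mean: float = 0.5  # mean PTC-vote fraction for the vote table


def ptc_like_preset() -> ClassPreset:
    return ClassPreset(
        radius_mean=13.0,
        radius_sd=1.6,
        axis_ratio=(0.55, 0.85),
        boundary_irregularity=0.22,
        center_clearing=1.7,
        crowding_cluster_sd=22.0,
        vote_ptc_mean=0.85,
    )


def non_ptc_like_preset() -> ClassPreset:
    return ClassPreset(
        radius_mean=9.0,
        radius_sd=1.1,
        axis_ratio=(0.75, 0.95),
        boundary_irregularity=0.05,
        center_clearing=1.1,
        crowding_cluster_sd=34.0,
        vote_ptc_mean=0.15,
    )


@dataclass
class GeneratorConfig:
    n_patients_per_class: int = 10
    images_per_patient: int = 2
    nuclei_per_image: tuple[int, int] = (18, 26)  # inclusive range
    image_size: tuple[int, int] = (256, 256)
    ptc_preset: ClassPreset = field(default_factory=ptc_like_preset)
    non_ptc_preset: ClassPreset = field(default_factory=non_ptc_like_preset)
    n_clusters: int = 4
    n_raters: int = 24
    vote_concentration: float = 12.0  # beta-binomial concentration
    seed: int = 0

    def __post_init__(self):
        if self.ptc_preset.radius_mean <= self.non_ptc_preset.radius_mean:
            raise ValueError("PTC preset must have larger radius_mean")
        if (
            self.ptc_preset.boundary_irregularity
            <= self.non_ptc_preset.boundary_irregularity
        ):
            raise ValueError("PTC preset must have higher boundary_irregularity")
        if self.ptc_preset.center_clearing <= self.non_ptc_preset.center_clearing:
            raise ValueError("PTC preset must have higher center_clearing")


@dataclass
class SyntheticPatient:
    patient_id: str
    class_label: ClassLabel
    images: list[np.ndarray]
    label_maps: list[np.ndarray]
    n_placed: list[int]  # nuclei actually placed per image


@dataclass
class SyntheticDataset:
    patients: list[SyntheticPatient]
    votes: pd.DataFrame
    config: GeneratorConfig
    log: dict


def _nucleus_polygon(
    rng: np.random.Generator, preset: ClassPreset, n_vertices: int = 96
):
    """Vertex offsets of one radially perturbed ellipse around its center."""
    r_eq = max(2.5, rng.normal(preset.radius_mean, preset.radius_sd))
    q = rng.uniform(*preset.axis_ratio)  # minor/major ratio, area preserved
    a, b = r_eq / np.sqrt(q), r_eq * np.sqrt(q)
    theta = rng.uniform(0, np.pi)
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    # harmonics 2-6 emulate membrane irregularity
    perturb = np.zeros_like(phi)
    if preset.boundary_irregularity > 0:
        amps = rng.uniform(0.3, 1.0, size=5)
        amps *= preset.boundary_irregularity / amps.sum()
        phases = rng.uniform(0, 2 * np.pi, size=5)
        for h, amp, ph in zip(range(2, 7), amps, phases):
            perturb += amp * np.cos(h * phi + ph)
    rad = np.sqrt((a * np.cos(phi)) ** 2 + (b * np.sin(phi)) ** 2)
    # ellipse in polar form about its center, rotated by theta
    ex = a * np.cos(phi)
    ey = b * np.sin(phi)
    rr = ex * np.cos(theta) - ey * np.sin(theta)
    cc = ex * np.sin(theta) + ey * np.cos(theta)
    scale = 1.0 + perturb
    return rr * scale, cc * scale, r_eq


def _render_image(
    rng: np.random.Generator, cfg: GeneratorConfig, preset: ClassPreset
) -> tuple[np.ndarray, np.ndarray, int]:
    """One tile: RGB image, ground-truth label map, #nuclei placed."""
    H, W = cfg.image_size
    n_target = int(rng.integers(cfg.nuclei_per_image[0], cfg.nuclei_per_image[1] + 1))
    margin = preset.radius_mean * 1.5
    clusters = rng.uniform([margin, margin], [H - margin, W - margin], size=(cfg.n_clusters, 2))
    centers: list[np.ndarray] = []
    min_sep = 1.7 * preset.radius_mean
    attempts = 0
    while len(centers) < n_target and attempts < n_target * 60:
        attempts += 1
        k = int(rng.integers(cfg.n_clusters))
        c = clusters[k] + rng.normal(0, preset.crowding_cluster_sd, size=2)
        if not (margin <= c[0] <= H - margin and margin <= c[1] <= W - margin):
            continue
        if centers and np.min(
            np.linalg.norm(np.asarray(centers) - c, axis=1)
        ) < min_sep:
            continue
        centers.append(c)
    n_placed = len(centers)
    if n_placed < n_target:
        warnings.warn(
            f"packing infeasible: placed {n_placed}/{n_target} nuclei"
        )
    labels = np.zeros((H, W), dtype=np.int64)
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    base = np.asarray(preset.base_color, dtype=np.float64)
    for i, (cy, cx) in enumerate(centers, start=1):
        drr, dcc, _ = _nucleus_polygon(rng, preset)
        rr, cc = draw.polygon(cy + drr, cx + dcc, shape=(H, W))
        if rr.size == 0:
            continue
        labels[rr, cc] = i  # later-placed nucleus wins contested pixels
    # radial shading per visible instance: center brighter by center_clearing
    for i in range(1, n_placed + 1):
        mask = labels == i
        if not mask.any():
            continue
        dist = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
        dmax = dist[mask].max()
        dnorm = dist[mask] / dmax if dmax > 0 else np.zeros(int(mask.sum()))
        scale = 1.0 + (preset.center_clearing - 1.0) * dnorm
        img[mask] = base[None, :] * scale[:, None]
    img += rng.normal(0, preset.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # drop instances fully occluded during rasterization
    surviving = np.unique(labels[labels > 0]).size
    return img, labels, surviving


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate a full two-class synthetic cohort.

    Deterministic under ``cfg.seed``: images, label maps and the vote table
    are byte-identical across runs with the same configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    patients: list[SyntheticPatient] = []
    vote_rows = []
    log: dict = {"per_patient": {}}
    for class_label, preset, prefix in (
        (ClassLabel.PTC_LIKE, cfg.ptc_preset, "ptc"),
        (ClassLabel.NON_PTC_LIKE, cfg.non_ptc_preset, "non"),
    ):
        for p in range(cfg.n_patients_per_class):
            pid = f"{prefix}{p:03d}"
            images, lms, placed = [], [], []
            for _ in range(cfg.images_per_patient):
                img, lm, n = _render_image(rng, cfg, preset)
                images.append(img)
                lms.append(lm)
                placed.append(n)
            patients.append(SyntheticPatient(pid, class_label, images, lms, placed))
            log["per_patient"][pid] = {
                "class": class_label.value,
                "nuclei_placed": placed,
            }
            # beta-binomial pathologist votes; concentration -> borderline rate
            mu = preset.vote_ptc_mean
            conc = cfg.vote_concentration
            pvote = rng.beta(conc * mu, conc * (1 - mu))
            votes_ptc = int(rng.binomial(cfg.n_raters, pvote))
            vote_rows.append(
                {
                    "case_id": pid,
                    "votes_non_ptc": cfg.n_raters - votes_ptc,
                    "votes_ptc": votes_ptc,
                    "rereviewed": False,
                    "rereview_ptc_count": np.nan,
                }
            )
    votes = pd.DataFrame(vote_rows)
    log["n_patients"] = len(patients)
    return SyntheticDataset(patients=patients, votes=votes, config=cfg, log=log)


def perturb_labels(
    lm: np.ndarray, merge_rate: float, drop_rate: float, seed: int
) -> np.ndarray:
    """Inject segmentation-failure modes for size-filter fixtures.

    With probability ``merge_rate`` per adjacent instance pair, the pair is
    merged under one label (emulating merged nuclei); with probability
    ``drop_rate`` per instance, the instance is cropped to a fragment below
    half the median area (emulating nuclei insufficiently in the image
    plane).  Rates 0 return an identical copy.  Deterministic under seed.
    """
    if not (0 <= merge_rate <= 1 and 0 <= drop_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    lm = np.asarray(lm)
    out = lm.copy()
    ids = np.unique(out[out > 0])
    if ids.size == 0 or (merge_rate == 0 and drop_rate == 0):
        return out
    rng = np.random.default_rng(seed)
    # adjacency: instance pairs whose dilations touch
    if merge_rate > 0 and ids.size >= 2:
        dil = ndimage.grey_dilation(out, size=(3, 3))
        pairs = set()
        touching = (out > 0) & (dil != out)
        for a, b in zip(out[touching].ravel(), dil[touching].ravel()):
            if a > 0 and b > 0 and a != b:
                pairs.add((min(a, b), max(a, b)))
        # also merge nearest centroid pairs when nothing touches
        if not pairs:
            coms = ndimage.center_of_mass(out > 0, out, ids)
            coms = np.asarray(coms)
            for i, a in enumerate(ids):
                d = np.linalg.norm(coms - coms[i], axis=1)
                d[i] = np.inf
                j = int(np.argmin(d))
                if d[j] < np.inf:
                    pairs.add((min(a, ids[j]), max(a, ids[j])))
        for a, b in sorted(pairs):
            if rng.random() < merge_rate:
                out[out == b] = a
    ids = np.unique(out[out > 0])
    if drop_rate > 0 and ids.size > 0:
        _, counts = np.unique(out[out > 0], return_counts=True)
        median = float(np.median(counts))
        for i in ids:
            if rng.random() < drop_rate:
                rows, cols = np.nonzero(out == i)
                keep = max(1, int(0.4 * median))
                if keep < rows.size:
                    order = np.lexsort((cols, rows))
                    kill = order[keep:]
                    out[rows[kill], cols[kill]] = 0
    return out


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> DatasetManifest:
    """Materialize a synthetic dataset to disk (images/, labels/, CSVs)."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)
    entries = []
    for pat in ds.patients:
        img_paths, lm_paths = [], []
        for i, (img, lm) in enumerate(zip(pat.images, pat.label_maps)):
            ip = outdir / "images" / f"{pat.patient_id}_{i}.png"
            lp = outdir / "labels" / f"{pat.patient_id}_{i}.png"
            io_manifest.write_image(img, ip)
            io_manifest.write_labelmap(lm, lp)
            img_paths.append(ip)
            lm_paths.append(lp)
        entries.append(
            ManifestEntry(pat.patient_id, pat.class_label, img_paths, lm_paths)
        )
    manifest = DatasetManifest(entries)
    io_manifest.write_manifest(manifest, outdir / "manifest.csv")
    io_manifest.write_vote_table(ds.votes, outdir / "votes.csv")
    import json

    cfg = asdict(ds.config)
    with open(outdir / "generation_log.json", "w") as fh:
        json.dump({"config": cfg, "log": ds.log}, fh, indent=2, default=str)
    return manifest
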