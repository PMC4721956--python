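"""Synthetic atlas populations with controlled inter-subject variability.

Real functional atlas databases (hundreds of manually labeled
face-selective regions) are not redistributable, so every pipeline
stage is exercised on generated cohorts instead.  Each subject's fROIs
are ellipsoidal blobs whose centre, size, and boundary are perturbed
per subject; the Z map is a within-ROI activation bump (peaking at the
displaced centre, decaying linearly in normalized ellipsoid radius to
the activation threshold at the boundary) plus smoothed Gaussian
background noise.  With more than one latent prototype, subjects fall
into subgroups whose activation patterns are mutually more similar —
the regime in which activation-pattern atlas selection is
demonstrably useful.

The generator emulates inter-subject variability of location, extent,
shape, and amplitude.  It does not emulate cortical geometry, spatial
registration error, or BOLD time-series noise, so passing tests speak
to the algorithmic behaviour of the pipeline, not to accuracy on real
brains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    ActivationMap,
    Atlas,
    AtlasDatabase,
    DEFAULT_Z_THRESHOLD,
    LabelMap,
    VolumeGrid,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RoiTemplate:
    """Population-level prototype of one fROI: an ellipsoid in world mm."""

    label: int
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("ROI labels must be positive (0 = background)")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("ROI radii must be positive")


def default_roi_templates() -> list[RoiTemplate]:
    """Two well-separated blobs standing in for a pair of face-selective
    regions (OFA-like and pFFA-like) on the default grid."""
    return [
        RoiTemplate(label=1, center_mm=(10.0, -14.0, -6.0), radii_mm=(7.0, 6.0, 5.0), name="OFA"),
        RoiTemplate(label=2, center_mm=(-8.0, 12.0, 6.0), radii_mm=(8.0, 6.0, 6.0), name="pFFA"),
    ]


@dataclass(frozen=True)
class PopulationSpec:
    """Generative settings of one synthetic cohort.

    Distances are millimetres on a 2 mm isotropic grid; the default
    grid is three orders of magnitude smaller than a full MNI 2 mm
    volume so that complete LOSOCV experiments run in minutes.
    ``translation_sd_mm`` displaces each subject's ROI centres,
    ``scale_sd`` rescales the radii multiplicatively, and
    ``shape_jitter_sd`` perturbs the boundary through a smoothed random
    field added to the normalized ellipsoid radius.  With
    ``n_prototypes > 1``, each prototype is a fixed random offset of
    the templates (per-axis SD ``prototype_offset_mm``, default twice
    the translation SD) and subjects are assigned to prototypes in
    round-robin order.
    """

    grid_shape: tuple[int, int, int] = (32, 38, 28)
    n_subjects: int = 10
    rois: tuple[RoiTemplate, ...] = field(default_factory=lambda: tuple(default_roi_templates()))
    translation_sd_mm: float = 0.0
    scale_sd: float = 0.0
    shape_jitter_sd: float = 0.0
    n_prototypes: int = 1
    prototype_offset_mm: float | None = None
    noise_smoothing_fwhm_mm: float = 4.0
    z_peak_mean: float = 5.0
    z_peak_sd: float = 0.0
    background_noise_sd: float = 1.0
    z_threshold: float = DEFAULT_Z_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        if self.n_subjects < 2:
            raise ValueError("a population needs at least 2 subjects")
        if not self.rois:
            raise ValueError("at least one ROI template is required")
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI template labels must be unique")
        for sd in (self.translation_sd_mm, self.scale_sd, self.shape_jitter_sd,
                   self.z_peak_sd, self.background_noise_sd):
            if sd < 0:
                raise ValueError("all variability SDs must be >= 0")
        if self.n_prototypes < 1:
            raise ValueError("n_prototypes must be >= 1")

    def make_grid(self) -> VolumeGrid:
        """2 mm isotropic grid centred on the world origin."""
        shape = self.grid_shape
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-(s - 1) for s in shape]
        return VolumeGrid(shape, affine, identifier="synthetic-2mm")

    @property
    def label_names(self) -> dict[int, str]:
        return {r.label: (r.name or f"roi{r.label}") for r in self.rois}


def _unit_smooth_field(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Smoothed white noise rescaled to unit pointwise SD."""
    f = rng.standard_normal(shape)
    if sigma_vox > 0:
        f = gaussian_filter(f, sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_population(
    spec: PopulationSpec,
) -> tuple[AtlasDatabase, dict[str, LabelMap]]:
    """Draw a cohort of atlases plus per-subject ground-truth label maps.

    Ground truth is the full (pre-threshold) blob geometry; the atlas
    label maps are the ground truth restricted to the subject's
    supra-threshold voxels, exactly as manual labels are drawn on
    thresholded activation maps.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.make_grid()
    shape = grid.shape
    vox = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    mm = grid.voxel_to_mm(vox.reshape(-1, 3)).reshape(shape + (3,))
    mm_lo, mm_hi = mm.reshape(-1, 3).min(axis=0), mm.reshape(-1, 3).max(axis=0)

    proto_sd = (
        spec.prototype_offset_mm
        if spec.prototype_offset_mm is not None
        else 2.0 * spec.translation_sd_mm
    )
    if spec.n_prototypes == 1:
        proto_offsets = np.zeros((1, len(spec.rois), 3))
    else:
        proto_offsets = rng.normal(0.0, proto_sd, size=(spec.n_prototypes, len(spec.rois), 3))

    sigma_noise = spec.noise_smoothing_fwhm_mm * _FWHM_TO_SIGMA / 2.0  # mm -> voxels (2 mm)
    jitter_sigma = 2.0  # voxels; boundary perturbations span a few voxels

    names = spec.label_names
    atlases: list[Atlas] = []
    truths: dict[str, LabelMap] = {}
    for i in range(spec.n_subjects):
        sid = f"sub{i:03d}"
        proto = i % spec.n_prototypes
        bump = np.zeros(shape)
        r_best = np.full(shape, np.inf)
        lab = np.zeros(shape, dtype=np.int64)
        for j, roi in enumerate(spec.rois):
            center = (
                np.asarray(roi.center_mm)
                + proto_offsets[proto, j]
                + rng.normal(0.0, spec.translation_sd_mm, size=3)
            )
            scale = max(float(rng.normal(1.0, spec.scale_sd)), 0.2)
            radii = np.asarray(roi.radii_mm) * scale
            r = np.sqrt((((mm - center) / radii) ** 2).sum(axis=-1))
            if spec.shape_jitter_sd > 0:
                r = r + spec.shape_jitter_sd * _unit_smooth_field(rng, shape, jitter_sigma)
            inside = r <= 1.0
            if not inside.any():
                raise ValueError(
                    f"ROI {roi.name or roi.label} escaped the grid for subject {sid}"
                )
            if np.any(center - radii < mm_lo) or np.any(center + radii > mm_hi):
                warnings.warn(
                    f"ROI {roi.name or roi.label} clipped at the grid edge for {sid}",
                    stacklevel=2,
                )
            peak = max(
                float(rng.normal(spec.z_peak_mean, spec.z_peak_sd)),
                spec.z_threshold + 0.5,
            )
            b = np.where(inside, peak - (peak - spec.z_threshold) * np.clip(r, 0.0, 1.0), 0.0)
            bump = np.maximum(bump, b)
            closer = inside & (r < r_best)
            lab[closer] = roi.label
            r_best[closer] = r[closer]
        z = bump.copy()
        if spec.background_noise_sd > 0:
            z = z + spec.background_noise_sd * _unit_smooth_field(rng, shape, sigma_noise)
        truth = LabelMap(grid, lab, dict(names))
        act = ActivationMap(grid, z, subject_id=sid)
        atlases.append(
            Atlas(act, LabelMap(grid, lab.copy(), dict(names)), z_threshold=spec.z_threshold)
        )
        truths[sid] = truth
    return AtlasDatabase(atlases), truths


def population_variability_report(
    db: AtlasDatabase, ground_truth: dict[str, LabelMap]
) -> pd.DataFrame:
    """Per-ROI variability summary of a cohort's ground-truth geometry.

    Columns: mean pairwise Dice of the ground-truth regions, centroid
    dispersion (mean distance, in mm, of per-subject centroids from
    their grand mean), and the coefficient of variation of region
    volume (voxel count).
    """
    from .evaluation import dice_coefficient  # deferred: evaluation imports core types

    grid = db.grid
    labels = sorted({l for lm in ground_truth.values() for l in lm.present_labels})
    names = {}
    for a in db:
        names.update(a.labels.label_names)
    rows = []
    sids = db.subject_ids
    for label in labels:
        regions = [ground_truth[s].region(label) for s in sids]
        dices = [
            d
            for i in range(len(regions))
            for j in range(i + 1, len(regions))
            if not np.isnan(d := dice_coefficient(regions[i], regions[j]))
        ]
        centroids = []
        volumes = []
        for reg in regions:
            volumes.append(int(reg.sum()))
            if reg.any():
                centroids.append(grid.voxel_to_mm(np.argwhere(reg)).mean(axis=0))
        centroids = np.asarray(centroids)
        dispersion = (
            float(np.linalg.norm(centroids - centroids.mean(axis=0), axis=1).mean())
            if len(centroids)
            else float("nan")
        )
        volumes = np.asarray(volumes, dtype=float)
        vol_cv = float(volumes.std() / volumes.mean()) if volumes.mean() > 0 else float("nan")
        rows.append(
            {
                "label": label,
                "name": names.get(label, f"label{label}"),
                "mean_pairwise_dice": float(np.mean(dices)) if dices else float("nan"),
                "centroid_dispersion_mm": dispersion,
                "volume_cv": vol_cv,
            }
        )
    return pd.DataFrame(rows)
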