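"""Single-atlas labeling baseline: the Group-constrained Subject-Specific
(GSS) procedure.

Three steps: (1) per-fROI probabilistic maps, each voxel's value the
fraction of reference subjects whose label covers it; (2) a maximum
probability map (MPM) assigning each voxel the fROI of highest group
probability after zeroing probabilities strictly below a threshold;
(3) intersection of the MPM parcels with the individual's
supra-threshold activation.  With ``use_selection`` the reference set
is first restricted to the top-N most similar atlases (GSS+AS), using
exactly the same mask, metric, and N as the multi-atlas path.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ActivationMap,
    Atlas,
    AtlasDatabase,
    CollectiveMask,
    ExperimentConfig,
    LabelMap,
    VolumeGrid,
    build_collective_mask,
    _check_same_grid,
)
from .selection import rank_atlases, select_atlases


def build_probabilistic_maps(
    atlases: list[Atlas], labels: set[int]
) -> dict[int, np.ndarray]:
    """Per-fROI group probability volumes: mean of per-subject indicators.

    Every value is an exact rational k/n where k of the n atlases label
    the voxel.
    """
    if not atlases:
        raise ValueError("cannot build probabilistic maps from an empty atlas list")
    grid = atlases[0].grid
    for a in atlases[1:]:
        _check_same_grid(grid, a.grid, "build_probabilistic_maps")
    out: dict[int, np.ndarray] = {}
    for label in sorted(int(l) for l in labels):
        acc = np.zeros(grid.shape, dtype=np.float64)
        for a in atlases:
            acc += a.labels.labels == label
        out[label] = acc / len(atlases)
    return out


def build_mpm(
    prob_maps: dict[int, np.ndarray],
    threshold: float,
    grid: VolumeGrid,
    label_names: dict[int, str] | None = None,
) -> LabelMap:
    """Maximum probability map at a given probability threshold.

    Probabilities strictly below the threshold are zeroed (>= survives;
    at threshold 0 everything survives).  A voxel whose surviving
    probabilities are all zero is background; otherwise it takes the
    label of highest surviving probability, ties toward the lowest
    label id.  Labeled voxels shrink monotonically as the threshold
    rises.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("MPM threshold must lie in [0, 1]")
    if not prob_maps:
        raise ValueError("no probabilistic maps given")
    labels = sorted(prob_maps)
    shapes = {prob_maps[l].shape for l in labels}
    if shapes != {grid.shape}:
        raise ValueError(f"inconsistent probabilistic-map shapes {shapes} for grid {grid.shape}")
    stack = np.stack([prob_maps[l] for l in labels], axis=-1)
    surviving = np.where(stack >= threshold, stack, 0.0)
    best = np.argmax(surviving, axis=-1)  # first max -> lowest label id on ties
    out = np.asarray(labels, dtype=np.int64)[best]
    out[surviving.max(axis=-1) <= 0.0] = 0
    return LabelMap(grid, out, label_names)


def gss_label_subject(
    target: ActivationMap,
    atlases: list[Atlas],
    labels: set[int],
    cfg: ExperimentConfig,
    threshold: float,
    use_selection: bool = False,
    mask: CollectiveMask | None = None,
    label_names: dict[int, str] | None = None,
) -> LabelMap:
    """Label one subject with the GSS (or GSS+AS) procedure.

    Output carries label l at exactly the voxels where the MPM says l
    AND the target activation exceeds the Z threshold.
    """
    ids = [a.subject_id for a in atlases]
    if target.subject_id and target.subject_id in ids:
        raise ValueError(
            f"target subject {target.subject_id!r} must be excluded from the reference atlases"
        )
    subset = list(atlases)
    if use_selection:
        db = AtlasDatabase(subset)
        if mask is None:
            mask = build_collective_mask(db, labels)
        ranked = rank_atlases(target, db, mask, metric=cfg.similarity_metric, n_bins=cfg.nmi_bins)
        chosen = set(select_atlases(ranked, cfg.n_selected_atlases))
        subset = [a for a in subset if a.subject_id in chosen]
    prob_maps = build_probabilistic_maps(subset, labels)
    mpm = build_mpm(prob_maps, threshold, subset[0].grid, label_names)
    _check_same_grid(target.grid, mpm.grid, "gss_label_subject")
    out = np.where(target.values > cfg.z_threshold, mpm.labels, 0)
    return LabelMap(target.grid, out, label_names)


def gss_multi_threshold_accuracy(
    target: ActivationMap,
    atlases: list[Atlas],
    labels: set[int],
    cfg: ExperimentConfig,
    gold: LabelMap,
    use_selection: bool = False,
    mask: CollectiveMask | None = None,
) -> dict[int, float]:
    """Across-threshold mean Dice per fROI for one subject.

    Runs the GSS labeling once per MPM threshold in
    ``cfg.mpm_thresholds``, scores Dice against the manual labels, and
    averages over thresholds (undefined both-empty Dice excluded).
    """
    from .evaluation import dice_coefficient  # deferred: evaluation drives gss in LOSOCV

    per_label: dict[int, list[float]] = {int(l): [] for l in labels}
    for t in cfg.mpm_thresholds:
        auto = gss_label_subject(
            target, atlases, labels, cfg, t, use_selection=use_selection, mask=mask
        )
        for label in per_label:
            d = dice_coefficient(auto.region(label), gold.region(label))
            if not np.isnan(d):
                per_label[label].append(d)
    return {
        label: (float(np.mean(vals)) if vals else float("nan"))
        for label, vals in per_label.items()
    }
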