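"""Label fusion: averaging per-atlas probabilistic predictions and
majority voting, plus the image-based (direct transfer) baseline and
the end-to-end multi-atlas labeling of one subject.
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
    ProbLabelMap,
    build_collective_mask,
    candidate_voxels,
    _check_same_grid,
)
from .encoding import EncodedAtlas, predict_prob_map, train_atlas_encoder
from .selection import rank_atlases, select_atlases


def _aligned_probs(m: ProbLabelMap, full: list[int]) -> np.ndarray:
    out = np.zeros(m.grid.shape + (len(full),), dtype=np.float64)
    cols = np.searchsorted(full, m.classes)
    out[..., cols] = m.probs
    return out


def fuse_prob_maps(maps: list[ProbLabelMap]) -> ProbLabelMap:
    """Voxelwise arithmetic mean of probabilistic label maps.

    Class lists are unioned and aligned; a class missing from one map
    contributes probability 0 there.  Fusion is permutation-invariant.
    """
    if not maps:
        raise ValueError("cannot fuse an empty list of probability maps")
    grid = maps[0].grid
    for m in maps[1:]:
        _check_same_grid(grid, m.grid, "fuse_prob_maps")
    full = sorted({0} | {c for m in maps for c in m.classes})
    acc = np.zeros(grid.shape + (len(full),), dtype=np.float64)
    for m in maps:
        acc += _aligned_probs(m, full)
    return ProbLabelMap(grid, tuple(full), acc / len(maps))


def vote_classes(probs: np.ndarray, classes: tuple[int, ...] | np.ndarray) -> np.ndarray:
    """Argmax over the last axis with the fusion tie rule.

    ``classes`` must be strictly increasing with background 0 first, so
    numpy's first-maximum argmax realizes "ties toward background, then
    lowest label id" directly.
    """
    classes = np.asarray(classes, dtype=np.int64)
    return classes[np.argmax(probs, axis=-1)]


def majority_vote(fused: ProbLabelMap, label_names: dict[int, str] | None = None) -> LabelMap:
    """Final per-voxel label: class of maximal averaged probability.

    Ties break toward background first, then the lowest label id.
    """
    labels = vote_classes(fused.probs, fused.classes)
    return LabelMap(fused.grid, labels, label_names)


def image_based_transfer(
    atlases: list[Atlas],
    target: ActivationMap,
    mask: CollectiveMask,
    labels: set[int],
    cfg: ExperimentConfig,
    label_names: dict[int, str] | None = None,
) -> LabelMap:
    """Direct label transfer baseline (one-to-one voxel correspondence).

    Each atlas contributes, at every target candidate voxel, the one-hot
    vector of its own label at that very voxel (background where
    unlabeled or carrying an unrequested label); the vectors are
    averaged and majority-voted exactly as in the forest-based path.
    """
    if not atlases:
        raise ValueError("image_based_transfer needs at least one atlas")
    for a in atlases:
        _check_same_grid(a.grid, mask.grid, "image_based_transfer")
    _check_same_grid(target.grid, mask.grid, "image_based_transfer")
    full = sorted({0} | {int(l) for l in labels})
    cand = candidate_voxels(target, mask, cfg.z_threshold)
    probs = np.zeros(target.grid.shape + (len(full),), dtype=np.float64)
    probs[..., 0] = 1.0
    if len(cand):
        wanted = np.asarray(full[1:])
        counts = np.zeros((len(cand), len(full)), dtype=np.float64)
        for a in atlases:
            lab = a.labels.labels[tuple(cand.T)]
            lab = np.where(np.isin(lab, wanted), lab, 0)
            counts[np.arange(len(cand)), np.searchsorted(full, lab)] += 1.0
        probs[tuple(cand.T)] = counts / len(atlases)
    fused = ProbLabelMap(target.grid, tuple(full), probs)
    return majority_vote(fused, label_names)


def mal_label_subject(
    target: ActivationMap,
    db: AtlasDatabase,
    labels: set[int],
    cfg: ExperimentConfig,
    mask: CollectiveMask | None = None,
    encoders: dict[str, EncodedAtlas] | None = None,
    label_names: dict[int, str] | None = None,
    return_prob: bool = False,
):
    """End-to-end multi-atlas labeling of one target subject.

    Builds (or reuses) the collective mask, ranks the database by
    activation-pattern similarity, selects the top ``cfg.n_selected_atlases``
    (0 = all), trains or reuses each selected atlas's encoder, predicts,
    fuses by averaging, and majority-votes.  ``encoders`` acts as a
    cache keyed by subject_id; missing entries are trained and inserted.
    Deterministic given the config seed.
    """
    if target.subject_id and target.subject_id in db.subject_ids:
        raise ValueError(
            f"target subject {target.subject_id!r} must be excluded from the database"
        )
    if mask is None:
        mask = build_collective_mask(db, labels)
    ranked = rank_atlases(target, db, mask, metric=cfg.similarity_metric, n_bins=cfg.nmi_bins)
    selected = select_atlases(ranked, cfg.n_selected_atlases)
    if encoders is None:
        encoders = {}
    preds = []
    for sid in selected:
        if sid not in encoders:
            encoders[sid] = train_atlas_encoder(db.get(sid), mask, labels, cfg)
        preds.append(predict_prob_map(encoders[sid], target, mask, cfg, classes=labels))
    fused = fuse_prob_maps(preds)
    voted = majority_vote(fused, label_names)
    if return_prob:
        return voted, fused
    return voted
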