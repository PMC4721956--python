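"""Hand-built volume constructors used across test modules."""

import numpy as np

import froimal as fm


def make_grid(shape=(12, 12, 12), scale=2.0, identifier="test-grid"):
    affine = np.diag([scale, scale, scale, 1.0])
    return fm.VolumeGrid(tuple(shape), affine, identifier=identifier)


def cuboid_atlas(grid, boxes, subject_id, z_inside=4.0, z_background=0.0,
                 extra_active=None, z_threshold=2.3):
    """An atlas whose fROIs are axis-aligned cuboids.

    ``boxes`` maps label -> (slice, slice, slice).  Every labeled voxel
    gets activation ``z_inside``; ``extra_active`` (list of slice
    triples) marks activated-but-unlabeled voxels.
    """
    labels = np.zeros(grid.shape, dtype=np.int64)
    act = np.full(grid.shape, z_background, dtype=np.float64)
    for label, box in boxes.items():
        labels[box] = label
        act[box] = z_inside
    for box in extra_active or []:
        act[box] = z_inside
    names = {int(l): f"roi{l}" for l in boxes}
    amap = fm.ActivationMap(grid, act, subject_id=subject_id)
    lmap = fm.LabelMap(grid, labels, names)
    return fm.Atlas(amap, lmap, z_threshold=z_threshold)


def random_blob_atlas(grid, rng, labels=(1, 2), n_blob_voxels=15, z_inside=4.0,
                      subject_id="sub"):
    """An atlas with small random voxel clouds per label (may be messy)."""
    lab = np.zeros(grid.shape, dtype=np.int64)
    act = np.zeros(grid.shape, dtype=np.float64)
    flat = rng.choice(grid.n_voxels, size=n_blob_voxels * len(labels), replace=False)
    coords = np.array(np.unravel_index(flat, grid.shape)).T
    for i, label in enumerate(labels):
        part = coords[i * n_blob_voxels:(i + 1) * n_blob_voxels]
        lab[tuple(part.T)] = label
        act[tuple(part.T)] = z_inside
    names = {int(l): f"roi{l}" for l in labels}
    return fm.Atlas(
        fm.ActivationMap(grid, act, subject_id=subject_id),
        fm.LabelMap(grid, lab, names),
    )


def random_prob_map(grid, classes, rng):
    raw = rng.random(grid.shape + (len(classes),))
    probs = raw / raw.sum(axis=-1, keepdims=True)
    return fm.ProbLabelMap(grid, tuple(classes), probs)
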