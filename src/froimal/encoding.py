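"""Classifier-based atlas encoding.

Each reference atlas is distilled into a randomized decision forest
mapping a voxel's spatial coordinate (its 3 integer grid indices) to an
fROI label.  Every activated voxel inside the collective mask is a
training sample; activated-but-unlabeled voxels are explicit background
samples, which is what lets the fused map say "no fROI here".  Trees
split on a single uniformly drawn coordinate dimension per node,
maximizing information gain (entropy), are grown to a fixed depth cap,
and are bagged on bootstrap resamples of the training voxels.

The forest is fit with scikit-learn (``RandomForestClassifier`` with
``max_features=1``, entropy criterion, bootstrap bagging) and then
frozen into plain arrays — per-node split feature/threshold, children,
and leaf class distributions — so that prediction is a pure, portable
array traversal and encoders serialize to versioned JSON without any
pickle dependency.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import (
    ActivationMap,
    Atlas,
    CollectiveMask,
    ExperimentConfig,
    ForestParams,
    ProbLabelMap,
    VolumeGrid,
    candidate_voxels,
)

_FORMAT = "froimal-encoded-atlas"
_VERSION = 1


@dataclass
class TreeArrays:
    """One frozen decision tree: flat node arrays, sklearn layout.

    ``children_left[i] == -1`` marks node *i* as a leaf; internal nodes
    route a sample left when ``x[feature[i]] <= threshold[i]``.
    ``leaf_proba`` holds the training-sample class distribution of every
    node (rows sum to 1).
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    leaf_proba: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index reached by each row of ``X`` (vectorized descent)."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            internal = self.children_left[node] >= 0
            if not internal.any():
                return node
            idx = np.nonzero(internal)[0]
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur], self.children_right[cur])


def encoder_seed(params: ForestParams, subject_id: str) -> int:
    """Deterministic per-atlas forest seed derived from the master seed."""
    return int((params.seed + zlib.crc32(subject_id.encode("utf-8"))) % (2**31 - 1))


def _extract_tree(est, n_in_classes: int, col_map: np.ndarray, n_classes: int) -> TreeArrays:
    t = est.tree_
    value = np.asarray(t.value)[:, 0, :]  # (n_nodes, n_in_classes)
    row_sums = value.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    proba = np.zeros((value.shape[0], n_classes), dtype=np.float64)
    proba[:, col_map] = value / row_sums
    return TreeArrays(
        feature=np.asarray(t.feature, dtype=np.int64).copy(),
        threshold=np.asarray(t.threshold, dtype=np.float64).copy(),
        children_left=np.asarray(t.children_left, dtype=np.int64).copy(),
        children_right=np.asarray(t.children_right, dtype=np.int64).copy(),
        leaf_proba=proba,
    )


@dataclass
class EncodedAtlas:
    """A trained coordinate-to-label forest distilled from one atlas."""

    trees: list[TreeArrays]
    classes: np.ndarray
    params: ForestParams
    source_subject_id: str

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if 0 not in self.classes:
            raise ValueError("encoder classes must include background 0")
        if not np.all(np.diff(self.classes) > 0):
            raise ValueError("encoder classes must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def predict_proba(self, coords: np.ndarray, vote: str = "soft") -> np.ndarray:
        """Per-coordinate class probabilities, averaged over trees.

        ``vote="soft"`` averages the leaf class distributions (default);
        ``vote="hard"`` averages one-hot per-tree majority votes (ties
        toward the lowest class).
        """
        X = np.asarray(coords, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {X.shape}")
        if vote not in ("soft", "hard"):
            raise ValueError(f"vote must be 'soft' or 'hard', got {vote!r}")
        acc = np.zeros((X.shape[0], self.n_classes), dtype=np.float64)
        for tree in self.trees:
            p = tree.leaf_proba[tree.apply(X)]
            if vote == "hard":
                hard = np.zeros_like(p)
                hard[np.arange(len(p)), np.argmax(p, axis=1)] = 1.0
                p = hard
            acc += p
        return acc / len(self.trees)

    # -- serialization -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the encoder to versioned JSON (one file per atlas)."""
        payload = {
            "format": _FORMAT,
            "version": _VERSION,
            "source_subject_id": self.source_subject_id,
            "params": {
                "n_trees": self.params.n_trees,
                "max_depth": self.params.max_depth,
                "seed": self.params.seed,
            },
            "classes": [int(c) for c in self.classes],
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "leaf_proba": t.leaf_proba.tolist(),
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EncodedAtlas":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a {_FORMAT} file")
        if payload.get("version") != _VERSION:
            raise ValueError(f"{path}: unsupported version {payload.get('version')}")
        trees = [
            TreeArrays(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray(t["threshold"], dtype=np.float64),
                children_left=np.asarray(t["children_left"], dtype=np.int64),
                children_right=np.asarray(t["children_right"], dtype=np.int64),
                leaf_proba=np.asarray(t["leaf_proba"], dtype=np.float64),
            )
            for t in payload["trees"]
        ]
        p = payload["params"]
        return cls(
            trees=trees,
            classes=np.asarray(payload["classes"], dtype=np.int64),
            params=ForestParams(p["n_trees"], p["max_depth"], p["seed"]),
            source_subject_id=payload["source_subject_id"],
        )


def train_atlas_encoder(
    atlas: Atlas,
    mask: CollectiveMask,
    labels: set[int],
    cfg: ExperimentConfig,
) -> EncodedAtlas:
    """Fit a coordinate->label forest on one atlas's activated voxels.

    Training samples are the atlas's candidate voxels (activated and
    inside the collective mask); the target is the atlas label when it
    is one of the requested fROI labels, otherwise background 0.  A
    single-class training set yields a valid degenerate encoder that
    predicts that class with probability 1.
    """
    cand = candidate_voxels(atlas.activation, mask, cfg.z_threshold)
    if len(cand) == 0:
        raise ValueError(
            f"no candidate voxels to train an encoder for subject {atlas.subject_id!r}"
        )
    wanted = np.array(sorted(int(l) for l in labels))
    y = atlas.labels.labels[tuple(cand.T)]
    y = np.where(np.isin(y, wanted), y, 0)
    rf = RandomForestClassifier(
        n_estimators=cfg.forest.n_trees,
        criterion="entropy",
        max_depth=cfg.forest.max_depth,
        max_features=1,
        bootstrap=True,
        min_samples_leaf=1,
        random_state=encoder_seed(cfg.forest, atlas.subject_id),
        n_jobs=1,
    )
    rf.fit(cand.astype(np.float64), y)
    fit_classes = np.asarray(rf.classes_, dtype=np.int64)
    classes = np.unique(np.append(fit_classes, 0))
    col_map = np.searchsorted(classes, fit_classes)
    trees = [_extract_tree(est, len(fit_classes), col_map, len(classes)) for est in rf.estimators_]
    return EncodedAtlas(
        trees=trees,
        classes=classes,
        params=cfg.forest,
        source_subject_id=atlas.subject_id,
    )


def predict_prob_map(
    enc: EncodedAtlas,
    target: ActivationMap,
    mask: CollectiveMask,
    cfg: ExperimentConfig,
    classes: set[int] | None = None,
    vote: str = "soft",
) -> ProbLabelMap:
    """Apply an encoder to a target's activated voxels.

    Candidate voxels of the target get the forest's probability vector;
    every other voxel gets the degenerate background vector.  ``classes``
    widens the class list to the experiment's full label set (classes
    the encoder never saw are padded with probability 0).  The output
    depends only on *which* voxels pass the threshold, never on the
    actual Z values.
    """
    full = sorted({0} | {int(c) for c in enc.classes} | {int(c) for c in (classes or ())})
    cand = candidate_voxels(target, mask, cfg.z_threshold)
    probs = np.zeros(target.grid.shape + (len(full),), dtype=np.float64)
    probs[..., 0] = 1.0
    if len(cand):
        p = enc.predict_proba(cand, vote=vote)
        aligned = np.zeros((len(cand), len(full)), dtype=np.float64)
        cols = np.searchsorted(full, enc.classes)
        aligned[:, cols] = p
        probs[tuple(cand.T)] = aligned
    return ProbLabelMap(target.grid, tuple(full), probs)
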