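"""Core domain types shared by every stage of the labeling pipeline.

All volumes live on a single common stereotaxic grid (in real use, the
MNI152 template grid that statistical maps are warped to; in tests, a
small synthetic grid).  A *voxel* is addressed by its 0-based integer
index triple ``(i, j, k)``; conversion to world millimetres happens only
through the grid's affine.  Activation values are Z statistics from a
functional contrast; a voxel counts as *activated* when its Z value is
strictly greater than the experiment's threshold (default 2.3,
p < 0.01 uncorrected).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from nibabel.affines import apply_affine

logger = logging.getLogger(__name__)

#: Default activation threshold on Z maps (p < 0.01, uncorrected).
DEFAULT_Z_THRESHOLD = 2.3


@dataclass(frozen=True, eq=False)
class VolumeGrid:
    """Shape + voxel-to-world affine of the common stereotaxic grid.

    Two grids compare equal only when their shapes match and their
    affines are bitwise identical; every volume in one experiment must
    share one grid.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    identifier: str = ""

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {shape!r}")
        affine = np.ascontiguousarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and self.affine.tobytes() == other.affine.tobytes()

    def __ne__(self, other: object) -> bool:
        eq = self.__eq__(other)
        return NotImplemented if eq is NotImplemented else not eq

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, voxels: np.ndarray) -> np.ndarray:
        """Map integer voxel indices to world-space millimetres."""
        return apply_affine(self.affine, np.asarray(voxels, dtype=np.float64))


def _check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str) -> None:
    if a != b:
        raise ValueError(f"grid mismatch in {what}: {a.shape}/{a.identifier!r} vs {b.shape}/{b.identifier!r}")


@dataclass
class ActivationMap:
    """One subject's Z-statistic volume on the common grid."""

    grid: VolumeGrid
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"activation values shape {values.shape} does not match grid {self.grid.shape}"
            )
        if not np.isfinite(values).all():
            raise ValueError(f"activation map for {self.subject_id!r} contains NaN/Inf")
        self.values = values


@dataclass
class LabelMap:
    """Integer fROI labels per voxel; 0 is reserved for background."""

    grid: VolumeGrid
    labels: np.ndarray
    label_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, labels.astype(np.int64)):
                raise ValueError("label volume must be integer valued")
            labels = labels.astype(np.int64)
        else:
            labels = labels.astype(np.int64)
        if labels.shape != self.grid.shape:
            raise ValueError(f"label shape {labels.shape} does not match grid {self.grid.shape}")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        present = self.present_labels_of(labels)
        if self.label_names is None:
            self.label_names = {int(l): f"label{int(l)}" for l in present}
        else:
            self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
            missing = [l for l in present if l not in self.label_names]
            if missing:
                raise ValueError(f"labels {missing} present in volume but absent from label_names")
        self.labels = labels

    @staticmethod
    def present_labels_of(labels: np.ndarray) -> list[int]:
        u = np.unique(labels)
        return [int(l) for l in u if l != 0]

    @property
    def present_labels(self) -> list[int]:
        return self.present_labels_of(self.labels)

    def region(self, label: int) -> np.ndarray:
        """Boolean volume of the voxels carrying ``label``."""
        return self.labels == int(label)


@dataclass
class Atlas:
    """A reference subject: activation map + expert label map.

    Construction enforces the invariant that every labeled voxel is
    activated: labels sitting on voxels at or below ``z_threshold`` are
    zeroed (manual labels may graze the threshold in real data) and the
    count of zeroed voxels is logged and kept on ``n_zeroed_labels``.
    """

    activation: ActivationMap
    labels: LabelMap
    subject_id: str = ""
    z_threshold: float = DEFAULT_Z_THRESHOLD
    n_zeroed_labels: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        _check_same_grid(self.activation.grid, self.labels.grid, "Atlas construction")
        if not self.subject_id:
            self.subject_id = self.activation.subject_id
        if self.activation.subject_id and self.subject_id != self.activation.subject_id:
            raise ValueError(
                f"atlas subject_id {self.subject_id!r} does not match "
                f"activation subject_id {self.activation.subject_id!r}"
            )
        violating = (self.labels.labels > 0) & (self.activation.values <= self.z_threshold)
        n = int(violating.sum())
        if n:
            logger.info(
                "atlas %s: zeroed %d sub-threshold labeled voxels (Z <= %g)",
                self.subject_id, n, self.z_threshold,
            )
            cleaned = self.labels.labels.copy()
            cleaned[violating] = 0
            self.labels = LabelMap(self.labels.grid, cleaned, self.labels.label_names)
        self.n_zeroed_labels = n

    @property
    def grid(self) -> VolumeGrid:
        return self.activation.grid


@dataclass
class AtlasDatabase:
    """Ordered collection of atlases sharing one grid, unique subject ids."""

    atlases: list[Atlas]

    def __post_init__(self) -> None:
        ids = [a.subject_id for a in self.atlases]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids in database: {dupes}")
        if self.atlases:
            g = self.atlases[0].grid
            for a in self.atlases[1:]:
                _check_same_grid(g, a.grid, f"AtlasDatabase (subject {a.subject_id})")

    @property
    def grid(self) -> VolumeGrid:
        if not self.atlases:
            raise ValueError("empty atlas database has no grid")
        return self.atlases[0].grid

    @property
    def subject_ids(self) -> list[str]:
        return [a.subject_id for a in self.atlases]

    def get(self, subject_id: str) -> Atlas:
        for a in self.atlases:
            if a.subject_id == subject_id:
                return a
        raise KeyError(subject_id)

    def without(self, subject_id: str) -> "AtlasDatabase":
        """A new database with one subject removed (LOSOCV helper)."""
        if subject_id not in self.subject_ids:
            raise KeyError(subject_id)
        return AtlasDatabase([a for a in self.atlases if a.subject_id != subject_id])

    def __len__(self) -> int:
        return len(self.atlases)

    def __iter__(self):
        return iter(self.atlases)

    def __getitem__(self, i: int) -> Atlas:
        return self.atlases[i]


@dataclass
class CollectiveMask:
    """Union of the requested fROI labels over every atlas in a database.

    Serves as the spatial constraint restricting which voxels enter
    encoder training and prediction.
    """

    grid: VolumeGrid
    mask: np.ndarray
    source_labels: frozenset[int]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {self.grid.shape}")
        self.mask = mask
        self.source_labels = frozenset(int(l) for l in self.source_labels)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ForestParams:
    """Decision-forest hyperparameters: T trees grown to depth D."""

    n_trees: int = 30
    max_depth: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved parameters of one labeling experiment.

    Defaults mirror the operating point of the method: activation
    threshold Z > 2.3, 40 selected atlases (0 = use every atlas),
    forests of 30 trees grown to depth 20, Pearson activation-pattern
    similarity, and maximum-probability-map thresholds {0, 0.1, 0.2}
    for the single-atlas baseline.
    """

    z_threshold: float = DEFAULT_Z_THRESHOLD
    n_selected_atlases: int = 40
    mpm_thresholds: tuple[float, ...] = (0.0, 0.1, 0.2)
    forest: ForestParams = field(default_factory=ForestParams)
    similarity_metric: str = "pearson"
    nmi_bins: int = 32
    peak_match_radius_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.n_selected_atlases < 0:
            raise ValueError("n_selected_atlases must be >= 0 (0 = all)")
        ts = tuple(float(t) for t in self.mpm_thresholds)
        if any(not (0.0 <= t <= 1.0) for t in ts):
            raise ValueError("mpm_thresholds must lie in [0, 1]")
        if list(ts) != sorted(ts):
            raise ValueError("mpm_thresholds must be sorted ascending")
        object.__setattr__(self, "mpm_thresholds", ts)
        if self.similarity_metric not in ("pearson", "nmi"):
            raise ValueError(f"unknown similarity metric {self.similarity_metric!r}")
        if self.peak_match_radius_mm < 0:
            raise ValueError("peak_match_radius_mm must be >= 0")

    def with_forest(self, n_trees: int, max_depth: int, seed: int | None = None) -> "ExperimentConfig":
        fp = ForestParams(n_trees, max_depth, self.forest.seed if seed is None else seed)
        return replace(self, forest=fp)


@dataclass
class ProbLabelMap:
    """Per-voxel probability vectors over an ordered class list.

    ``classes`` is strictly increasing and always contains background 0
    (first entry).  Voxels outside the evaluated domain carry the
    degenerate vector with all mass on background.
    """

    grid: VolumeGrid
    classes: tuple[int, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        classes = tuple(int(c) for c in self.classes)
        if not classes or classes[0] != 0 or list(classes) != sorted(set(classes)):
            raise ValueError(f"classes must be strictly increasing and start with background 0, got {classes}")
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.shape != self.grid.shape + (len(classes),):
            raise ValueError(
                f"probs shape {probs.shape} does not match grid {self.grid.shape} + {len(classes)} classes"
            )
        if probs.min() < -1e-12:
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=-1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("per-voxel probability vectors must sum to 1 (+-1e-9)")
        self.classes = classes
        self.probs = probs


def build_collective_mask(db: AtlasDatabase, labels: set[int]) -> CollectiveMask:
    """Merge the requested fROI labels from every atlas into one mask.

    A voxel is in the mask iff at least one atlas assigns one of the
    requested labels there.  The mask is order-invariant over atlases.
    """
    labels = {int(l) for l in labels}
    if not labels:
        raise ValueError("label set must be non-empty")
    if len(db) == 0:
        raise ValueError("cannot build a collective mask from an empty atlas database")
    known: set[int] = set()
    for a in db:
        known.update(a.labels.label_names.keys())
    unknown = labels - known
    if unknown:
        raise ValueError(f"unknown label id(s) {sorted(unknown)}: not present in any atlas")
    grid = db.grid
    mask = np.zeros(grid.shape, dtype=bool)
    wanted = np.array(sorted(labels))
    for a in db:
        mask |= np.isin(a.labels.labels, wanted)
    if not mask.any():
        warnings.warn(
            f"collective mask for labels {sorted(labels)} is empty", stacklevel=2
        )
    return CollectiveMask(grid, mask, frozenset(labels))


def candidate_voxels(
    a: ActivationMap, m: CollectiveMask, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> np.ndarray:
    """Activated voxels inside the collective mask, lexicographically ordered.

    Returns an ``(n, 3)`` integer array of voxel indices where the Z
    value is *strictly* greater than ``z_threshold`` and the mask is
    true; a voxel at exactly the threshold is excluded.
    """
    _check_same_grid(a.grid, m.grid, "candidate_voxels")
    sel = (a.values > z_threshold) & m.mask
    return np.argwhere(sel).astype(np.intp)
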