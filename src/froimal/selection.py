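"""Atlas selection by activation-pattern similarity.

Because fROIs are defined from a one-sided functional contrast, only
positive activation carries signal: before comparing two Z maps, the
values of negatively activated voxels are clamped to zero, and the maps
are restricted to the collective mask.  Similarity is then Pearson's
correlation (or, optionally, normalized mutual information of the
binned values).  Atlases are ranked descending by similarity to the
target and the top N are retained for fusion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .core import ActivationMap, AtlasDatabase, CollectiveMask, _check_same_grid


def _masked_clamped(a: ActivationMap, mask: CollectiveMask, clamp: bool = True) -> np.ndarray:
    v = a.values[mask.mask]
    return np.maximum(v, 0.0) if clamp else v


def activation_pattern_similarity(
    target: ActivationMap, atlas_act: ActivationMap, mask: CollectiveMask
) -> float:
    """Pearson correlation of two positive activation patterns in the mask.

    Negative Z values are set to zero in both maps before correlating.
    Returns 0 (with a warning) when either clamped vector is constant,
    so uninformative atlases sort last.
    """
    _check_same_grid(target.grid, mask.grid, "activation_pattern_similarity")
    _check_same_grid(atlas_act.grid, mask.grid, "activation_pattern_similarity")
    if mask.n_voxels < 2:
        raise ValueError("similarity needs a mask with at least 2 voxels")
    x = _masked_clamped(target, mask)
    y = _masked_clamped(atlas_act, mask)
    if x.std() == 0.0 or y.std() == 0.0:
        warnings.warn(
            "constant clamped activation vector; similarity defined as 0", stacklevel=2
        )
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def nmi_similarity(
    target: ActivationMap,
    atlas_act: ActivationMap,
    mask: CollectiveMask,
    n_bins: int = 32,
    clamp: bool = True,
) -> float:
    """Normalized mutual information 2 I(X;Y) / (H(X) + H(Y)).

    Both masked vectors (negatives clamped to zero by default) are
    discretized on a shared equal-width grid spanning their pooled
    range.  Degenerate single-bin input returns 0 with a warning.
    """
    _check_same_grid(target.grid, mask.grid, "nmi_similarity")
    _check_same_grid(atlas_act.grid, mask.grid, "nmi_similarity")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mask.n_voxels < 2:
        raise ValueError("similarity needs a mask with at least 2 voxels")
    x = _masked_clamped(target, mask, clamp)
    y = _masked_clamped(atlas_act, mask, clamp)
    pooled_lo = min(x.min(), y.min())
    pooled_hi = max(x.max(), y.max())
    if pooled_hi == pooled_lo:
        warnings.warn("degenerate single-bin input; NMI defined as 0", stacklevel=2)
        return 0.0
    edges = np.linspace(pooled_lo, pooled_hi, n_bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = float(entropy(px))
    hy = float(entropy(py))
    if hx == 0.0 or hy == 0.0:
        warnings.warn("degenerate single-bin marginal; NMI defined as 0", stacklevel=2)
        return 0.0
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (np.outer(px, py)[nz]))))
    return 2.0 * mi / (hx + hy)


def rank_atlases(
    target: ActivationMap,
    db: AtlasDatabase,
    mask: CollectiveMask,
    metric: str = "pearson",
    n_bins: int = 32,
) -> list[tuple[str, float]]:
    """Rank database atlases by similarity to the target, most similar first.

    Ties are broken by subject_id lexicographic order.  The target must
    not itself be in the database (leave-one-out leakage guard, checked
    by subject_id).
    """
    if target.subject_id and target.subject_id in db.subject_ids:
        raise ValueError(
            f"target subject {target.subject_id!r} is present in the reference database "
            "(leave-one-out leakage)"
        )
    if metric == "pearson":
        sims = [activation_pattern_similarity(target, a.activation, mask) for a in db]
    elif metric == "nmi":
        sims = [nmi_similarity(target, a.activation, mask, n_bins=n_bins) for a in db]
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    pairs = list(zip(db.subject_ids, sims))
    return sorted(pairs, key=lambda t: (-t[1], t[0]))


def select_atlases(ranked: list[tuple[str, float]], n: int) -> list[str]:
    """The top-n subject ids from a ranking (n=0 selects all)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(ranked):
        raise ValueError(f"cannot select {n} atlases from a ranking of {len(ranked)}")
    if n == 0:
        return [sid for sid, _ in ranked]
    return [sid for sid, _ in ranked[:n]]


def ranking_frame(ranked: list[tuple[str, float]]) -> pd.DataFrame:
    """Tidy (subject_id, similarity, rank) table; rank 1 = most similar."""
    return pd.DataFrame(
        {
            "subject_id": [sid for sid, _ in ranked],
            "similarity": [sim for _, sim in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
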