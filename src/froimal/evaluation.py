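"""Metrics and experiment drivers.

Dice overlap, peak-location consistency, pairwise atlas similarity
before/after forest encoding, leave-one-subject-out cross-validation
(LOSOCV) over the labeling methods, the atlas-count sweep (ranked vs
random reference subsets), the forest-parameter grid, and the
concordance of region-mean activation intensities tested with
Steiger's Z for two dependent correlations sharing a variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ActivationMap,
    Atlas,
    AtlasDatabase,
    CollectiveMask,
    ExperimentConfig,
    ForestParams,
    LabelMap,
    build_collective_mask,
    candidate_voxels,
    _check_same_grid,
)
from .encoding import EncodedAtlas, predict_prob_map, train_atlas_encoder
from .fusion import image_based_transfer, mal_label_subject, vote_classes
from .gss import gss_label_subject, gss_multi_threshold_accuracy
from .selection import rank_atlases

METHODS = ("mal", "image_based", "gss", "gss_as")


def dice_coefficient(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two voxel sets.

    Accepts boolean volumes (same shape) or sets of voxel tuples.
    Both empty -> NaN (undefined; excluded from averages); exactly one
    empty -> 0.
    """
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a = np.asarray(a, dtype=bool)
        b = np.asarray(b, dtype=bool)
        if a.shape != b.shape:
            raise ValueError(f"voxel sets on different grids: {a.shape} vs {b.shape}")
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
    else:
        a, b = set(a), set(b)
        na, nb = len(a), len(b)
        inter = len(a & b)
    if na == 0 and nb == 0:
        return float("nan")
    return 2.0 * inter / (na + nb)


def _region_peak(act: ActivationMap, region: np.ndarray) -> tuple[int, int, int]:
    """Argmax-Z voxel inside a region; ties -> lexicographically first voxel."""
    vals = np.where(region, act.values, -np.inf)
    flat = int(np.argmax(vals))  # C-order first maximum = lexicographic tie-break
    return tuple(int(i) for i in np.unravel_index(flat, act.grid.shape))


def peak_consistency(
    auto: LabelMap,
    manual: LabelMap,
    act: ActivationMap,
    label: int,
    radius_mm: float = 0.0,
):
    """Whether the auto and manual regions share their activation peak.

    True iff the argmax-Z voxels of the two regions lie within
    ``radius_mm`` of each other in world space (radius 0 = identical
    voxel).  False when the auto region is empty; None (undefined,
    excluded from proportions) when the manual region is empty.
    """
    _check_same_grid(auto.grid, manual.grid, "peak_consistency")
    _check_same_grid(act.grid, manual.grid, "peak_consistency")
    manual_region = manual.region(label)
    if not manual_region.any():
        return None
    auto_region = auto.region(label)
    if not auto_region.any():
        return False
    pa = _region_peak(act, auto_region)
    pm = _region_peak(act, manual_region)
    d = float(np.linalg.norm(act.grid.voxel_to_mm(pa) - act.grid.voxel_to_mm(pm)))
    return bool(d <= radius_mm + 1e-9)


@dataclass
class EvaluationRecord:
    """One (held-out subject, method, fROI) outcome of a LOSOCV fold."""

    target_subject: str
    method: str
    roi_label: int
    dice: float  # NaN when both auto and manual regions are empty
    peak_match: bool | None
    n_atlases: int
    params: ForestParams


def records_to_frame(records: Iterable[EvaluationRecord]) -> pd.DataFrame:
    rows = [
        {
            "target_subject": r.target_subject,
            "method": r.method,
            "roi_label": r.roi_label,
            "dice": r.dice,
            "peak_match": r.peak_match,
            "n_atlases": r.n_atlases,
            "n_trees": r.params.n_trees,
            "max_depth": r.params.max_depth,
            "seed": r.params.seed,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def summarize_records(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SEM Dice and peak-match proportion per method and fROI."""
    def agg(g: pd.DataFrame) -> pd.Series:
        dice = g["dice"].dropna()
        peaks = g["peak_match"].dropna()
        return pd.Series(
            {
                "mean_dice": dice.mean(),
                "sem_dice": dice.sem() if len(dice) > 1 else 0.0,
                "peak_consistency": peaks.astype(float).mean() if len(peaks) else np.nan,
                "n": len(g),
            }
        )

    grouped = frame.groupby(["method", "roi_label"], sort=True)
    return grouped.apply(agg, include_groups=False).reset_index()


def train_all_encoders(
    db: AtlasDatabase,
    mask: CollectiveMask,
    labels: set[int],
    cfg: ExperimentConfig,
) -> dict[str, EncodedAtlas]:
    """Train every atlas's encoder once; safe to share across LOSOCV folds
    because an encoder depends only on its own atlas, never on the fold."""
    return {a.subject_id: train_atlas_encoder(a, mask, labels, cfg) for a in db}


def pairwise_encoded_similarity(
    a1: Atlas,
    a2: Atlas,
    mask: CollectiveMask,
    labels: set[int],
    cfg: ExperimentConfig,
    encoders: dict[str, EncodedAtlas] | None = None,
) -> dict[int, tuple[float, float]]:
    """Per-fROI Dice between two atlases before and after forest encoding.

    "Before" compares the raw label maps; "after" compares the hard
    (voted) label maps each atlas's forest produces over the full
    collective-mask voxel set.
    """
    _check_same_grid(a1.grid, mask.grid, "pairwise_encoded_similarity")
    _check_same_grid(a2.grid, mask.grid, "pairwise_encoded_similarity")
    if encoders is None:
        encoders = {}
    for a in (a1, a2):
        if a.subject_id not in encoders:
            encoders[a.subject_id] = train_atlas_encoder(a, mask, labels, cfg)
    coords = np.argwhere(mask.mask)
    hard = {}
    for a in (a1, a2):
        enc = encoders[a.subject_id]
        p = enc.predict_proba(coords)
        vol = np.zeros(mask.grid.shape, dtype=np.int64)
        vol[tuple(coords.T)] = vote_classes(p, enc.classes)
        hard[a.subject_id] = vol
    out = {}
    for label in sorted(int(l) for l in labels):
        d_orig = dice_coefficient(a1.labels.region(label), a2.labels.region(label))
        d_enc = dice_coefficient(hard[a1.subject_id] == label, hard[a2.subject_id] == label)
        out[label] = (d_orig, d_enc)
    return out


def _gss_peak_threshold(cfg: ExperimentConfig) -> float:
    # peak consistency for GSS is scored at the middle MPM threshold
    ts = cfg.mpm_thresholds
    return ts[len(ts) // 2]


def losocv(
    db: AtlasDatabase,
    labels: set[int],
    cfg: ExperimentConfig,
    methods: Sequence[str] = ("mal",),
    encoders: dict[str, EncodedAtlas] | None = None,
    mask: CollectiveMask | None = None,
) -> list[EvaluationRecord]:
    """Leave-one-subject-out cross-validation of the requested methods.

    Each subject is iteratively held out, labeled from the remaining
    atlases, and scored (Dice, peak match) against its own manual
    labels.  Encoders are trained once and cached across folds.
    """
    if len(db) < 2:
        raise ValueError("LOSOCV needs at least 2 atlases")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")
    if mask is None:
        mask = build_collective_mask(db, labels)
    if "mal" in methods and encoders is None:
        encoders = train_all_encoders(db, mask, labels, cfg)
    label_list = sorted(int(l) for l in labels)
    records: list[EvaluationRecord] = []
    for atlas in db:
        sid = atlas.subject_id
        refs = db.without(sid)
        assert sid not in refs.subject_ids, "leakage: held-out subject present in references"
        gold, act = atlas.labels, atlas.activation
        for method in methods:
            if method == "mal":
                auto = mal_label_subject(
                    act, refs, labels, cfg, mask=mask, encoders=encoders
                )
                n_at = cfg.n_selected_atlases or len(refs)
                dices = {
                    l: dice_coefficient(auto.region(l), gold.region(l)) for l in label_list
                }
                peaks = {
                    l: peak_consistency(auto, gold, act, l, cfg.peak_match_radius_mm)
                    for l in label_list
                }
            elif method == "image_based":
                auto = image_based_transfer(refs.atlases, act, mask, labels, cfg)
                n_at = len(refs)
                dices = {
                    l: dice_coefficient(auto.region(l), gold.region(l)) for l in label_list
                }
                peaks = {
                    l: peak_consistency(auto, gold, act, l, cfg.peak_match_radius_mm)
                    for l in label_list
                }
            else:  # gss / gss_as
                use_sel = method == "gss_as"
                dices = gss_multi_threshold_accuracy(
                    act, refs.atlases, labels, cfg, gold, use_selection=use_sel, mask=mask
                )
                auto = gss_label_subject(
                    act, refs.atlases, labels, cfg, _gss_peak_threshold(cfg),
                    use_selection=use_sel, mask=mask,
                )
                n_at = cfg.n_selected_atlases if use_sel else len(refs)
                peaks = {
                    l: peak_consistency(auto, gold, act, l, cfg.peak_match_radius_mm)
                    for l in label_list
                }
            for l in label_list:
                records.append(
                    EvaluationRecord(
                        target_subject=sid,
                        method=method,
                        roi_label=l,
                        dice=dices[l],
                        peak_match=peaks[l],
                        n_atlases=n_at,
                        params=cfg.forest,
                    )
                )
    return records


def _candidate_prediction(
    enc: EncodedAtlas, cand: np.ndarray, full: list[int]
) -> np.ndarray:
    """Encoder probabilities at candidate voxels, aligned to ``full`` classes."""
    p = enc.predict_proba(cand)
    aligned = np.zeros((len(cand), len(full)), dtype=np.float64)
    aligned[:, np.searchsorted(full, enc.classes)] = p
    return aligned


def _dice_at_candidates(
    pred_labels: np.ndarray, gold_labels: np.ndarray, label_list: list[int]
) -> float:
    dices = []
    for l in label_list:
        d = dice_coefficient(set(np.nonzero(pred_labels == l)[0]),
                             set(np.nonzero(gold_labels == l)[0]))
        if not np.isnan(d):
            dices.append(d)
    return float(np.mean(dices)) if dices else float("nan")


def atlas_count_sweep(
    db: AtlasDatabase,
    labels: set[int],
    cfg: ExperimentConfig,
    counts: Sequence[int],
    n_random_repeats: int = 10,
    seed: int | None = None,
    encoders: dict[str, EncodedAtlas] | None = None,
) -> pd.DataFrame:
    """LOSOCV mean Dice per reference-set size: top-ranked vs random subsets.

    For each held-out subject the per-reference predictions are computed
    once; top-ranked subsets are prefixes of the similarity ranking,
    random subsets are drawn without replacement with a seeded
    generator.  Manual labels are supra-threshold and inside the mask,
    so Dice restricted to candidate voxels is exact.

    Returns a tidy frame (target, count, strategy, repeat, mean_dice).
    """
    counts = sorted(set(int(c) for c in counts))
    if counts and counts[-1] > len(db) - 1:
        raise ValueError(f"count {counts[-1]} exceeds database size - 1 = {len(db) - 1}")
    mask = build_collective_mask(db, labels)
    if encoders is None:
        encoders = train_all_encoders(db, mask, labels, cfg)
    label_list = sorted(int(l) for l in labels)
    full = [0] + label_list
    rng = np.random.default_rng(cfg.forest.seed if seed is None else seed)
    rows = []
    for atlas in db:
        sid = atlas.subject_id
        refs = db.without(sid)
        cand = candidate_voxels(atlas.activation, mask, cfg.z_threshold)
        gold_c = atlas.labels.labels[tuple(cand.T)] if len(cand) else np.zeros(0, np.int64)
        ranked = [r for r, _ in rank_atlases(atlas.activation, refs, mask,
                                             metric=cfg.similarity_metric, n_bins=cfg.nmi_bins)]
        preds = {
            rid: _candidate_prediction(encoders[rid], cand, full) for rid in ranked
        } if len(cand) else {rid: np.zeros((0, len(full))) for rid in ranked}

        def subset_dice(ids: list[str]) -> float:
            # canonical summation order: fusion stays bitwise permutation-invariant
            mean = np.mean([preds[r] for r in sorted(ids)], axis=0)
            voted = vote_classes(mean, full) if len(cand) else np.zeros(0, np.int64)
            return _dice_at_candidates(voted, gold_c, label_list)

        for count in counts:
            rows.append(
                {"target": sid, "count": count, "strategy": "ranked", "repeat": 0,
                 "mean_dice": subset_dice(ranked[:count])}
            )
            for rep in range(n_random_repeats):
                chosen = list(rng.choice(ranked, size=count, replace=False))
                rows.append(
                    {"target": sid, "count": count, "strategy": "random", "repeat": rep,
                     "mean_dice": subset_dice(chosen)}
                )
    return pd.DataFrame(rows)


def summarize_sweep(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean Dice per (count, strategy) across targets and repeats."""
    return (
        frame.groupby(["count", "strategy"])["mean_dice"].mean().unstack("strategy").reset_index()
    )


def forest_param_grid(
    db: AtlasDatabase,
    labels: set[int],
    cfg: ExperimentConfig,
    t_values: Sequence[int],
    d_values: Sequence[int],
) -> pd.DataFrame:
    """LOSOCV mean Dice of the multi-atlas method per (T, D) cell.

    Encoders are retrained per cell (they depend on the forest
    parameters).  Returns a matrix indexed by T with D as columns.
    """
    if not len(t_values) or not len(d_values):
        raise ValueError("t_values and d_values must be non-empty")
    out = np.empty((len(t_values), len(d_values)))
    for i, t in enumerate(t_values):
        for j, d in enumerate(d_values):
            cell_cfg = cfg.with_forest(int(t), int(d))
            recs = losocv(db, labels, cell_cfg, methods=("mal",))
            dices = [r.dice for r in recs if not np.isnan(r.dice)]
            out[i, j] = float(np.mean(dices))
    return pd.DataFrame(out, index=pd.Index(t_values, name="n_trees"),
                        columns=pd.Index(d_values, name="max_depth"))


def rank_accuracy_spearman(
    db: AtlasDatabase,
    labels: set[int],
    cfg: ExperimentConfig,
    encoders: dict[str, EncodedAtlas] | None = None,
) -> list[float]:
    """Per-target Spearman correlation between atlas rank and single-atlas Dice.

    For every held-out target, each reference atlas alone labels the
    target (its voted forest prediction) and is scored by mean Dice
    over the fROIs; the Spearman correlation of rank (1 = most similar)
    with that accuracy is returned per target.  Feasible atlas
    selection shows up as a negative correlation.
    """
    mask = build_collective_mask(db, labels)
    if encoders is None:
        encoders = train_all_encoders(db, mask, labels, cfg)
    label_list = sorted(int(l) for l in labels)
    full = [0] + label_list
    out = []
    for atlas in db:
        refs = db.without(atlas.subject_id)
        cand = candidate_voxels(atlas.activation, mask, cfg.z_threshold)
        if len(cand) == 0:
            continue
        gold_c = atlas.labels.labels[tuple(cand.T)]
        ranked = rank_atlases(atlas.activation, refs, mask,
                              metric=cfg.similarity_metric, n_bins=cfg.nmi_bins)
        accs = []
        for rid, _ in ranked:
            p = _candidate_prediction(encoders[rid], cand, full)
            accs.append(_dice_at_candidates(vote_classes(p, full), gold_c, label_list))
        rho = stats.spearmanr(np.arange(1, len(ranked) + 1), accs).statistic
        out.append(float(rho))
    return out


def steiger_z(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable 1.

    Fisher-transforms r12 and r13 and corrects for their covariance via
    r23 (Steiger's Z1* with the pooled rbar).  Returns (Z, two-sided p).
    Z is exactly 0 when r12 == r13.
    """
    if n < 4:
        raise ValueError("Steiger's Z needs n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if r12 == r13:
        return 0.0, 1.0
    with np.errstate(divide="ignore"):
        z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = 0.5 * (r12 + r13)
    num = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
    s = num / (1.0 - rbar**2) ** 2
    z = (z12 - z13) * np.sqrt((n - 3.0) / (2.0 - 2.0 * s))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def mean_region_intensity(act: ActivationMap, labelmap: LabelMap, label: int) -> float:
    """Mean Z value inside a labeled region; NaN when the region is empty."""
    region = labelmap.region(label)
    if not region.any():
        return float("nan")
    return float(act.values[region].mean())


def intensity_concordance(
    manual_means: Sequence[float],
    auto_means_1: Sequence[float],
    auto_means_2: Sequence[float],
) -> tuple[float, float, float, float]:
    """Compare two automated methods' intensity agreement with manual fROIs.

    Given per-subject mean activation intensities from manually
    delineated regions and from two automated methods, returns
    (r1, r2, Z, p): Pearson correlations of each automated series with
    the manual series and Steiger's Z (two-sided p) for the difference
    of the two dependent correlations.  Subjects with an undefined
    (NaN) mean in any series are excluded pairwise.
    """
    m = np.asarray(manual_means, dtype=np.float64)
    a1 = np.asarray(auto_means_1, dtype=np.float64)
    a2 = np.asarray(auto_means_2, dtype=np.float64)
    if not (len(m) == len(a1) == len(a2)):
        raise ValueError("the three series must have equal length")
    keep = np.isfinite(m) & np.isfinite(a1) & np.isfinite(a2)
    m, a1, a2 = m[keep], a1[keep], a2[keep]
    n = len(m)
    if n < 4:
        raise ValueError("intensity concordance needs at least 4 complete subjects")
    if m.std() == 0 or a1.std() == 0 or a2.std() == 0:
        raise ValueError("constant intensity series: correlation undefined")
    r1 = float(np.corrcoef(m, a1)[0, 1])
    r2 = float(np.corrcoef(m, a2)[0, 1])
    if np.allclose(a1, a2):
        return r1, r2, 0.0, 1.0
    r23 = float(np.corrcoef(a1, a2)[0, 1])
    z, p = steiger_z(r1, r2, r23, n)
    return r1, r2, z, p
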