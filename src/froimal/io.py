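"""NIfTI, JSON-sidecar, and configuration plumbing.

Activation maps are stored as float64 NIfTI-1 volumes, label maps as
integer NIfTI-1 volumes with a JSON sidecar holding the label names.
A database directory contains per-subject pairs plus a manifest.  Every
artifact the CLI writes is accompanied by the resolved experiment
configuration and its hash, so identical configs provably produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    ActivationMap,
    Atlas,
    AtlasDatabase,
    ExperimentConfig,
    ForestParams,
    LabelMap,
    VolumeGrid,
)

_MANIFEST = "manifest.json"


def _grid_from_image(img, identifier: str = "") -> VolumeGrid:
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    return VolumeGrid(tuple(int(s) for s in img.shape), np.asarray(img.affine, dtype=np.float64),
                      identifier=identifier)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_activation_map(amap: ActivationMap, path: str | Path) -> None:
    img = nib.Nifti1Image(amap.values.astype(np.float64), amap.grid.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def load_activation_map(path: str | Path, subject_id: str | None = None) -> ActivationMap:
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_from_image(img, identifier=path.name)
    values = np.asarray(img.get_fdata(), dtype=np.float64)
    if subject_id is None:
        subject_id = path.name.split(".")[0]
        if subject_id.endswith("_zstat"):  # invert the database naming scheme
            subject_id = subject_id[: -len("_zstat")]
    return ActivationMap(grid, values, subject_id=subject_id)


def save_label_map(lm: LabelMap, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(lm.labels.astype(np.int32), lm.grid.affine)
    img.header.set_data_dtype(np.int32)
    nib.save(img, str(path))
    sidecar = {"label_names": {str(k): v for k, v in lm.label_names.items()}}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_from_image(img, identifier=path.name)
    labels = np.asarray(img.get_fdata()).astype(np.int64)
    names = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        names = {int(k): str(v) for k, v in payload.get("label_names", {}).items()}
    return LabelMap(grid, labels, names)


def save_prob_map_4d(probs: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Per-class fused probability volumes as one 4D NIfTI (class = 4th axis)."""
    img = nib.Nifti1Image(np.asarray(probs, dtype=np.float64), affine)
    nib.save(img, str(path))


def save_database(
    db: AtlasDatabase,
    directory: str | Path,
    ground_truth: dict[str, LabelMap] | None = None,
) -> Path:
    """Write per-subject activation/label NIfTI pairs plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for atlas in db:
        sid = atlas.subject_id
        act_name, lab_name = f"{sid}_zstat.nii.gz", f"{sid}_labels.nii.gz"
        save_activation_map(atlas.activation, directory / act_name)
        save_label_map(atlas.labels, directory / lab_name)
        entry = {"id": sid, "activation": act_name, "labels": lab_name}
        if ground_truth and sid in ground_truth:
            gt_name = f"{sid}_truth.nii.gz"
            save_label_map(ground_truth[sid], directory / gt_name)
            entry["ground_truth"] = gt_name
        entries.append(entry)
    manifest = {
        "format": "froimal-atlas-database",
        "version": 1,
        "grid": {
            "shape": list(db.grid.shape),
            "affine": db.grid.affine.tolist(),
            "identifier": db.grid.identifier,
        },
        "subjects": entries,
    }
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=2))
    return directory


def load_database(
    directory: str | Path, z_threshold: float = 2.3
) -> tuple[AtlasDatabase, dict[str, LabelMap]]:
    """Read a database directory; returns (database, ground-truth maps)."""
    directory = Path(directory)
    manifest = json.loads((directory / _MANIFEST).read_text())
    if manifest.get("format") != "froimal-atlas-database":
        raise ValueError(f"{directory}: not a froimal atlas database")
    atlases = []
    truths: dict[str, LabelMap] = {}
    for entry in manifest["subjects"]:
        sid = entry["id"]
        act = load_activation_map(directory / entry["activation"], subject_id=sid)
        lab = load_label_map(directory / entry["labels"])
        atlases.append(Atlas(act, lab, z_threshold=z_threshold))
        if "ground_truth" in entry:
            truths[sid] = load_label_map(directory / entry["ground_truth"])
    return AtlasDatabase(atlases), truths


# -- experiment configuration ------------------------------------------


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["mpm_thresholds"] = list(d["mpm_thresholds"])
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    forest = d.pop("forest", {})
    return ExperimentConfig(forest=ForestParams(**forest), **d)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2, sort_keys=True))


def load_config(path: str | Path) -> ExperimentConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


def config_hash(cfg: ExperimentConfig) -> str:
    canon = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]


def write_provenance(out_path: str | Path, cfg: ExperimentConfig, extra: dict | None = None) -> None:
    """JSON sidecar recording the resolved config and its hash next to an artifact."""
    payload = {"config": config_to_dict(cfg), "config_hash": config_hash(cfg)}
    if extra:
        payload.update(extra)
    out_path = Path(out_path)
    sidecar = out_path.with_name(out_path.name + ".provenance.json")
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
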