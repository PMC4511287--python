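"""Readers/writers for the pipeline's file formats.

NIfTI-1 (BOLD runs, masks, stat maps, ground-truth volumes) via nibabel
with the TR recorded in the header; events as tab-separated
``onset  duration  trial_type`` files; motion as 6-column TSV (three
translations mm, three rotations deg); questionnaire tables as CSV;
respiration as 2-column TSV; experiment/pipeline configs as YAML.
Internally everything is 0-based voxel indexing; world mm coordinates go
through the stored affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from taskneg.glm import StatMap
from taskneg.preprocess import BoldRun
from taskneg.protocol import Epoch, ExperimentTimeline

__all__ = [
    "write_bold", "read_bold", "write_volume", "read_volume",
    "write_stat_map", "read_stat_map",
    "write_events", "read_events", "write_motion", "read_motion",
    "write_respiration", "read_respiration", "load_config", "save_config",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


class IoError(ValueError):
    pass


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_bold(path: str | Path, run: BoldRun) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(run.voxel_size))
    img.header.set_zooms((*run.voxel_size, run.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path: str | Path, tr: float | None = None,
              subject: str = "", run_id: str = "") -> BoldRun:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
    except Exception as e:  # malformed/truncated file: no partial object
        raise IoError(f"cannot read NIfTI {path}: {e}") from e
    if data.ndim != 4:
        raise IoError(f"{path}: expected a 4D BOLD image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise IoError(f"{path}: TR missing from header; pass tr= explicitly")
        tr = header_tr
    return BoldRun(data=data, voxel_size=tuple(float(z) for z in zooms[:3]),
                   tr=tr, subject=subject, run=run_id)


def write_volume(path: str | Path, data: np.ndarray, voxel_size=(3.0, 3.0, 3.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
    except Exception as e:
        raise IoError(f"cannot read NIfTI {path}: {e}") from e
    if data.ndim != 3:
        raise IoError(f"{path}: expected a 3D volume")
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def write_stat_map(path: str | Path, smap: StatMap, voxel_size=(3.0, 3.0, 3.0)) -> None:
    """Stat map as NIfTI plus a JSON sidecar with kind/df/contrast."""
    path = Path(path)
    write_volume(path, smap.values, voxel_size)
    write_volume(path.with_name(path.name.replace(".nii", "_mask.nii")),
                 smap.mask.astype(np.float32), voxel_size)
    sidecar = {
        "kind": smap.kind,
        "df": int(smap.df),
        "contrast": None if smap.contrast is None else list(map(float, smap.contrast)),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stat_map(path: str | Path) -> StatMap:
    path = Path(path)
    values, vs = read_volume(path)
    side = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    if mask_path.exists():
        mask = read_volume(mask_path)[0].astype(bool)
    else:
        mask = np.ones(values.shape, dtype=bool)
    contrast = side.get("contrast")
    return StatMap(values=values, kind=side["kind"], df=side["df"],
                   contrast=None if contrast is None else np.asarray(contrast),
                   mask=mask)


def write_events(path: str | Path, timeline: ExperimentTimeline) -> None:
    with open(path, "w") as f:
        f.write("onset\tduration\ttrial_type\n")
        for ep in timeline.epochs:
            f.write(f"{ep.onset:.3f}\t{ep.duration:.3f}\t{ep.condition}\n")


def read_events(path: str | Path, tr: float, n_volumes: int | None = None) -> ExperimentTimeline:
    df = pd.read_csv(path, sep="\t")
    need = {"onset", "duration", "trial_type"}
    if not need.issubset(df.columns):
        raise IoError(f"{path}: events file needs columns {sorted(need)}")
    epochs = tuple(Epoch(str(r.trial_type), float(r.onset), float(r.duration))
                   for r in df.itertuples())
    if n_volumes is None:
        end = max(ep.offset for ep in epochs) if epochs else 0.0
        n_volumes = int(round(end / tr))
    return ExperimentTimeline(epochs=epochs, tr=tr, n_volumes=n_volumes)


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    pd.DataFrame(np.asarray(motion), columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_motion(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise IoError(f"{path}: motion trace must have 6 columns")
    return df.to_numpy(dtype=float)


def write_respiration(path: str | Path, trace: pd.DataFrame) -> None:
    trace[["time", "flow"]].to_csv(path, sep="\t", index=False)


def read_respiration(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"time", "flow"}.issubset(df.columns):
        raise IoError(f"{path}: respiration trace needs time and flow columns")
    return df


# ---------------------------------------------------------------------------
# Pipeline config

REQUIRED_SECTIONS = ("experiment", "simulate", "preprocess", "glm",
                     "cluster", "distribution")


def validate_config(cfg: dict) -> dict:
    """Validate a pipeline config: required sections present and every
    stochastic stage carrying an explicit seed.  Returns the config."""
    if not isinstance(cfg, dict):
        raise IoError("config must be a mapping")
    for sec in REQUIRED_SECTIONS:
        if sec not in cfg:
            raise IoError(f"config missing section {sec!r}")
    for sec in ("experiment", "simulate", "cluster"):
        if "seed" not in cfg[sec]:
            raise IoError(f"config section {sec!r} requires an explicit seed")
    exp = cfg["experiment"]
    for key in ("conditions", "n_blocks", "block_s", "rest_s", "tr_s"):
        if key not in exp:
            raise IoError(f"experiment config missing {key!r}")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return validate_config(yaml.safe_load(f))


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
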