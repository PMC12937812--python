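"""Disk formats for sessions, models and analysis outputs.

Volumes, masks and statistic maps are written as NIfTI-1 (nominal
3.5 x 3.5 x 4 mm voxels, matching the emulated acquisition); schedules,
tap events, traces and score tables as CSV; ground truth, model
metadata and configs as JSON/YAML sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .classifier import ClassifierModel
from .synthetic import (Block, BlockSchedule, MaskSet, TapStream,
                        VolumeSeries)

__all__ = [
    "save_volume", "load_volume", "save_mask", "load_mask",
    "save_schedule", "load_schedule", "save_tap_streams",
    "load_tap_streams", "save_model", "load_model",
]

VOXEL_SIZE_MM = (3.5, 3.5, 4.0)


def _affine() -> np.ndarray:
    return np.diag(list(VOXEL_SIZE_MM) + [1.0])


def save_volume(run: VolumeSeries, path) -> None:
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), _affine())
    img.header.set_zooms(VOXEL_SIZE_MM + (run.tr_s,))
    nib.save(img, str(path))


def load_volume(path, run_index: int = 1) -> VolumeSeries:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return VolumeSeries(data=np.asarray(img.dataobj, dtype=float),
                        tr_s=tr, run_index=run_index)


def save_mask(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine()), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_masks(masks: MaskSet, directory) -> None:
    directory = Path(directory)
    save_mask(masks.brain_mask, directory / "brain_mask.nii")
    save_mask(masks.visual_exclusion_mask,
              directory / "visual_exclusion_mask.nii")
    save_mask(masks.analysis_mask, directory / "analysis_mask.nii")


def load_masks(directory) -> MaskSet:
    directory = Path(directory)
    return MaskSet(
        brain_mask=load_mask(directory / "brain_mask.nii"),
        visual_exclusion_mask=load_mask(
            directory / "visual_exclusion_mask.nii"),
        analysis_mask=load_mask(directory / "analysis_mask.nii"))


def save_schedule(schedule: BlockSchedule, path) -> None:
    rows = [dict(block_id=i, condition=b.condition, onset_s=b.onset_s,
                 duration_s=b.duration_s)
            for i, b in enumerate(schedule.blocks)]
    frame = pd.DataFrame(rows)
    frame.attrs["run_kind"] = schedule.run_kind
    with open(path, "w") as fh:
        fh.write(f"# run_kind={schedule.run_kind} tr_s={schedule.tr_s}\n")
        frame.to_csv(fh, index=False)


def load_schedule(path) -> BlockSchedule:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        frame = pd.read_csv(fh)
    blocks = [Block(r.condition, float(r.onset_s), float(r.duration_s))
              for r in frame.itertuples()]
    return BlockSchedule(blocks=blocks, run_kind=meta["run_kind"],
                         tr_s=float(meta["tr_s"]))


def save_tap_streams(streams, path) -> None:
    rows = []
    for s in streams:
        for t in s.tap_times_s:
            rows.append(dict(block_id=s.block_id,
                             instructed_rate_hz=s.instructed_rate_hz,
                             onset_s=s.onset_s, duration_s=s.duration_s,
                             tap_time_s=t))
        if s.tap_times_s.size == 0:       # keep empty blocks on record
            rows.append(dict(block_id=s.block_id,
                             instructed_rate_hz=s.instructed_rate_hz,
                             onset_s=s.onset_s, duration_s=s.duration_s,
                             tap_time_s=np.nan))
    pd.DataFrame(rows).to_csv(path, index=False)


def load_tap_streams(path) -> list[TapStream]:
    frame = pd.read_csv(path)
    streams = []
    for block_id, grp in frame.groupby("block_id", sort=False):
        times = grp["tap_time_s"].dropna().to_numpy()
        streams.append(TapStream(
            block_id=str(block_id),
            instructed_rate_hz=float(grp["instructed_rate_hz"].iloc[0]),
            onset_s=float(grp["onset_s"].iloc[0]),
            duration_s=float(grp["duration_s"].iloc[0]),
            tap_times_s=np.sort(times)))
    return streams


def save_model(model: ClassifierModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(model.weights.astype(np.float32), _affine()),
             str(directory / "weights.nii"))
    save_masks(model.masks, directory)
    with open(directory / "model.json", "w") as fh:
        json.dump({"bias": model.bias,
                   "training_meta": model.training_meta}, fh, indent=2)


def load_model(directory) -> ClassifierModel:
    directory = Path(directory)
    weights = np.asarray(
        nib.load(str(directory / "weights.nii")).dataobj, dtype=float)
    with open(directory / "model.json") as fh:
        meta = json.load(fh)
    return ClassifierModel(weights=weights, bias=float(meta["bias"]),
                           masks=load_masks(directory),
                           training_meta=meta["training_meta"])
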