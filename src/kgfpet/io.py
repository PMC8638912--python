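"""Container I/O: NPZ round trips and NIfTI export.

NPZ is the lossless working format (all metadata embedded); NIfTI export is
provided for viewing dynamic image/sinogram stacks in standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .containers import DynamicImageSet, DynamicSinogramSet
from .schedule import FrameSchedule

__all__ = [
    "write_sinogram_set",
    "read_sinogram_set",
    "write_image_set",
    "read_image_set",
    "export_nifti",
]


class FormatError(ValueError):
    """Raised when a container file is missing required datasets."""


def write_sinogram_set(s: DynamicSinogramSet, path: Union[str, Path]) -> None:
    np.savez_compressed(
        path,
        P=s.P,
        frame_start=s.schedule.frame_start,
        frame_duration=s.schedule.frame_duration,
        n_bins=s.n_bins,
        n_angles=s.n_angles,
        provenance=np.array(s.provenance),
        seed=np.array(-1 if s.seed is None else s.seed),
        meta=np.array(json.dumps(s.meta)),
    )


def read_sinogram_set(path: Union[str, Path]) -> DynamicSinogramSet:
    with np.load(path, allow_pickle=False) as f:
        required = {"P", "frame_start", "frame_duration", "n_bins", "n_angles"}
        missing = required - set(f.files)
        if missing:
            raise FormatError(f"{path}: missing datasets {sorted(missing)}")
        seed = int(f["seed"]) if "seed" in f.files else -1
        return DynamicSinogramSet(
            P=f["P"],
            n_bins=int(f["n_bins"]),
            n_angles=int(f["n_angles"]),
            schedule=FrameSchedule(f["frame_start"], f["frame_duration"]),
            provenance=str(f["provenance"]) if "provenance" in f.files else "unknown",
            seed=None if seed < 0 else seed,
            meta=json.loads(str(f["meta"])) if "meta" in f.files else {},
        )


def write_image_set(im: DynamicImageSet, path: Union[str, Path]) -> None:
    np.savez_compressed(
        path,
        X=im.X,
        grid_shape=np.array(im.grid_shape),
        frame_start=im.schedule.frame_start,
        frame_duration=im.schedule.frame_duration,
        label_map=im.label_map if im.label_map is not None else np.array([]),
    )


def read_image_set(path: Union[str, Path]) -> DynamicImageSet:
    with np.load(path, allow_pickle=False) as f:
        required = {"X", "grid_shape", "frame_start", "frame_duration"}
        missing = required - set(f.files)
        if missing:
            raise FormatError(f"{path}: missing datasets {sorted(missing)}")
        labels = f["label_map"] if "label_map" in f.files else np.array([])
        return DynamicImageSet(
            X=f["X"],
            grid_shape=tuple(f["grid_shape"]),
            schedule=FrameSchedule(f["frame_start"], f["frame_duration"]),
            label_map=None if labels.size == 0 else labels,
        )


def export_nifti(
    obj: Union[DynamicImageSet, DynamicSinogramSet], path: Union[str, Path]
) -> None:
    """Write a 4-D NIfTI (x, y, 1, frame) view of a dynamic stack (float32)."""
    if isinstance(obj, DynamicImageSet):
        frames = [obj.frame_image(i) for i in range(obj.n_frames)]
    else:
        frames = [obj.frame_sinogram(i) for i in range(obj.n_frames)]
    vol = np.stack(frames, axis=-1)[:, :, None, :].astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def load_nifti_stack(path: Union[str, Path]) -> np.ndarray:
    """Read back a 4-D NIfTI stack as an (n_pixels, N) matrix."""
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)
    if vol.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D stack, got shape {vol.shape}")
    H, W, _, N = vol.shape
    return vol[:, :, 0, :].reshape(H * W, N)
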