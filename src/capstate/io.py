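"""File formats: NIfTI series/masks/maps, TSV tables, JSON logs.

Conventions: NIfTI series are (rows, cols, 1, T) with time last and TR in
pixdim[4]; frame indices are 0-based internally and 1-based in
human-readable tables (stated in every table header); QPP windows are
half-open [start, start + length).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .config import Group
from .synthetic import SubjectRecording

__all__ = [
    "write_series",
    "read_series",
    "write_mask",
    "read_mask",
    "write_map",
    "write_motion_tsv",
    "read_motion_tsv",
    "write_labels_tsv",
    "read_labels_tsv",
    "write_qpp_tsv",
    "read_qpp_tsv",
    "write_manifest",
    "read_manifest",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _to_volume(recording: SubjectRecording) -> np.ndarray:
    rows, cols = recording.mask.shape
    vol = np.zeros((rows, cols, 1, recording.n_frames), dtype=np.float32)
    grid = np.zeros((rows, cols), dtype=np.float32)
    for t in range(recording.n_frames):
        grid[:] = 0.0
        grid[recording.mask] = recording.frames[t]
        vol[:, :, 0, t] = grid
    return vol


def write_series(recording: SubjectRecording, path) -> None:
    """Write a recording as a 4D NIfTI-1 (.nii/.nii.gz) with TR in the header."""
    img = nib.Nifti1Image(_to_volume(recording), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(recording.tr_seconds)))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_series(
    path,
    mask: np.ndarray,
    subject_id: Optional[str] = None,
    group: Group = Group.WT,
    tr_seconds: Optional[float] = None,
    motion_regressors: Optional[np.ndarray] = None,
) -> SubjectRecording:
    """Read a 4D NIfTI series and apply the mask.

    TR comes from the header's 4th zoom unless overridden; a missing TR
    (zoom 0) with no override is an error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:  # (rows, cols, T) tolerated
        data = data[:, :, np.newaxis, :]
    if data.ndim != 4 or data.shape[:2] != mask.shape:
        raise ValueError(
            f"series shape {data.shape} incompatible with mask shape {mask.shape}"
        )
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) >= 4 else 0.0
        if tr_seconds <= 0:
            raise ValueError(f"{path}: no TR in header and no override given")
    frames = data[:, :, 0, :][mask].T.astype(float)  # (T, V)
    return SubjectRecording(
        subject_id=subject_id or Path(str(path)).stem.split(".")[0],
        group=Group(group),
        frames=frames,
        tr_seconds=tr_seconds,
        mask=mask,
        motion_regressors=motion_regressors,
    )


def write_mask(mask: np.ndarray, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(bool)


def write_map(values: np.ndarray, mask: np.ndarray, path) -> None:
    """Write a per-voxel map (length V, mask order) as a 2D NIfTI image."""
    grid = np.zeros(mask.shape, dtype=np.float32)
    grid[mask] = values
    nib.save(nib.Nifti1Image(grid, affine=np.eye(4)), str(path))


def write_motion_tsv(motion: np.ndarray, path) -> None:
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_motion_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_labels_tsv(
    labels: np.ndarray, subject_of_frame: Sequence[str], path
) -> None:
    """Frame-wise cluster labels; frame and cluster columns are 1-based."""
    df = pd.DataFrame(
        {
            "frame": np.arange(1, len(labels) + 1),  # 1-based
            "subject": list(subject_of_frame),
            "cluster": np.asarray(labels) + 1,  # 1-based
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["cluster0"] = df["cluster"] - 1  # back to 0-based
    return df


def write_qpp_tsv(windows: Sequence[Tuple[int, int]], path) -> None:
    """QPP windows as 1-based inclusive start frames + length."""
    pd.DataFrame(
        {
            "start_frame": [s + 1 for s, _ in windows],
            "length_frames": [l for _, l in windows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_qpp_tsv(path) -> List[Tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(int(s) - 1, int(l)) for s, l in zip(df["start_frame"], df["length_frames"])]


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
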