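"""File formats: TSV event/survey/feature tables and NIfTI-1 volumes."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    ev["start"] = pd.to_datetime(ev["start"])
    ev["end"] = pd.to_datetime(ev["end"])
    return ev


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def write_mask_nifti(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_motion_txt(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, motion, fmt="%.8f")


def read_motion_txt(path: str | Path) -> np.ndarray:
    return np.loadtxt(path).reshape(-1, 6)
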