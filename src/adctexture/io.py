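"""File formats and run provenance.

Volumes travel as NIfTI (one 4-D file per DWI series, uint8 masks),
b-values as whitespace-separated text (FSL .bval dialect), feature and
sensitivity tables as TSV with a ``#``-prefixed provenance header
(tool version, master seed, config hash).  Only voxel-grid geometry is
used by the analysis; a diagonal RAS+ affine scaled by the voxel size is
written on export.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preproc import ADCVolume, DWISeries

__all__ = [
    "save_dwi", "load_dwi", "save_mask", "load_mask",
    "save_adc", "load_adc", "read_bvals", "write_bvals",
    "write_table", "read_table", "config_hash",
]


def _affine(voxel_size: float, slice_thickness: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, slice_thickness, 1.0])


def write_bvals(path, b_values) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def read_bvals(path) -> np.ndarray:
    return np.asarray(Path(path).read_text().split(), dtype=float)


def save_dwi(dwi: DWISeries, nifti_path, bval_path) -> None:
    """Write a DWI series as a 4-D NIfTI (x, y, z, b) plus a .bval text file."""
    data = np.moveaxis(dwi.signals, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32),
                          _affine(dwi.voxel_size, dwi.slice_thickness))
    nib.save(img, str(nifti_path))
    write_bvals(bval_path, dwi.b_values)


def load_dwi(nifti_path, bval_path) -> DWISeries:
    img = nib.load(str(nifti_path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    zooms = img.header.get_zooms()
    return DWISeries(data, read_bvals(bval_path),
                     voxel_size=float(zooms[0]), slice_thickness=float(zooms[2]))


def save_mask(mask: np.ndarray, path, voxel_size: float,
              slice_thickness: float = 3.0) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                          _affine(voxel_size, slice_thickness))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_adc(adc: ADCVolume, path, slice_thickness: float = 3.0) -> None:
    img = nib.Nifti1Image(adc.values.astype(np.float32),
                          _affine(adc.voxel_size, slice_thickness))
    nib.save(img, str(path))


def load_adc(path) -> ADCVolume:
    img = nib.load(str(path))
    return ADCVolume(np.asarray(img.dataobj, dtype=float),
                     voxel_size=float(img.header.get_zooms()[0]))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, provenance: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV with ``# key: value`` provenance header lines."""
    buf = _io.StringIO()
    for key, val in (provenance or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
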