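"""NIfTI / TSV / JSON I/O helpers shared by the CLI and pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(data, path, voxel_size=3.0) -> None:
    """Write an array as NIfTI with an isotropic affine (mm voxel size)."""
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    affine = np.diag(list(vs) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_confounds_tsv(path) -> np.ndarray:
    """Read a confound table (TSV with a header row) as an n_t x k array."""
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)
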