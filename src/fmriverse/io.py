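"""NIfTI / TSV / JSON readers and writers for the pipeline artifacts.

Volumes are written as NIfTI-1 with an identity-scaled affine; statistic
maps carry a JSON sidecar with the statistic kind, degrees of freedom and
mask path, so they round-trip losslessly through :class:`StatMap`.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .glm import StatMap
from .group import ThresholdedMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_statmap",
    "load_statmap",
    "save_thresholded",
    "load_thresholded",
]


def save_volume(data: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_statmap(statmap: StatMap, path: str | Path) -> None:
    path = Path(path)
    save_volume(statmap.values, path)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    save_volume(statmap.mask.astype(np.float32), mask_path)
    meta = {
        "stat_kind": statmap.stat_kind,
        "df": statmap.df,
        "mask": mask_path.name,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def load_statmap(path: str | Path) -> StatMap:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    values = load_volume(path)
    mask = load_volume(path.with_name(meta["mask"])) > 0.5
    df = meta["df"]
    if isinstance(df, list):
        df = tuple(df)
    return StatMap(values, meta["stat_kind"], df, mask)


def save_thresholded(thr: ThresholdedMap, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    save_volume(thr.positive_mask.astype(np.float32), f"{prefix}_positive.nii.gz")
    save_volume(thr.negative_mask.astype(np.float32), f"{prefix}_negative.nii.gz")
    save_volume(thr.analysis_mask.astype(np.float32), f"{prefix}_analysis_mask.nii.gz")
    Path(f"{prefix}_recipe.json").write_text(json.dumps(thr.recipe, default=float))


def load_thresholded(prefix: str | Path) -> ThresholdedMap:
    prefix = Path(prefix)
    return ThresholdedMap(
        positive_mask=load_volume(f"{prefix}_positive.nii.gz") > 0.5,
        negative_mask=load_volume(f"{prefix}_negative.nii.gz") > 0.5,
        recipe=json.loads(Path(f"{prefix}_recipe.json").read_text()),
        analysis_mask=load_volume(f"{prefix}_analysis_mask.nii.gz") > 0.5,
    )
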