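"""File formats: NIfTI images/masks, contour CSV, manifests, feature tables.

Images travel as NIfTI (2D stored as single-slice 3D, pixel spacing in the
header zooms); contours as CSV with columns ``case_id, contour, vertex_index,
x_mm, y_mm``; cohort manifests and feature tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image_prep import ContourSet, MyocardialMask, T1Map


def write_nifti(path: str | Path, pixels: np.ndarray, spacing: tuple[float, float]) -> None:
    data = np.asarray(pixels, dtype=np.float32)[:, :, None]
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((spacing[0], spacing[1], 1.0))
    nib.save(img, str(path))


def read_t1map(path: str | Path, case_id: str = "") -> T1Map:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError("expected a 2D or single-slice 3D image")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()[:2]
    return T1Map(data, (float(zooms[0]), float(zooms[1])), case_id or Path(path).stem)


def write_mask(path: str | Path, mask: MyocardialMask) -> None:
    write_nifti(path, mask.mask.astype(np.float32), mask.spacing)


def read_mask(path: str | Path) -> MyocardialMask:
    t = read_t1map(path)
    return MyocardialMask(t.pixels > 0.5, t.spacing)


def write_contours(path: str | Path, contours: dict[str, ContourSet]) -> None:
    rows = []
    for case_id, cs in contours.items():
        for name, poly in (("endo", cs.endo), ("epi", cs.epi)):
            for i, (x, y) in enumerate(poly):
                rows.append(
                    {
                        "case_id": case_id,
                        "contour": name,
                        "vertex_index": i,
                        "x_mm": x,
                        "y_mm": y,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours(path: str | Path) -> dict[str, ContourSet]:
    df = pd.read_csv(path)
    out: dict[str, ContourSet] = {}
    for case_id, grp in df.groupby("case_id", sort=False):
        polys = {}
        for name, sub in grp.groupby("contour"):
            sub = sub.sort_values("vertex_index")
            polys[name] = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
        out[str(case_id)] = ContourSet(endo=polys["endo"], epi=polys["epi"])
    return out


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_json(path: str | Path, obj: object) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path: str | Path) -> object:
    return json.loads(Path(path).read_text())
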