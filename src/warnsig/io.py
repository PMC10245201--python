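"""File formats: phenotype/matrix CSVs, landmark CSVs, PNG images and masks.

All CSVs are UTF-8, comma-separated, "." decimal, with a header row; files
written by the pipeline start with a ``# manifest: <hash>`` comment line so
every output carries its provenance. Masks are indexed PNGs (0 background,
1 head, 2 dorsum, 3 hindlimb).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .distances import CharacteristicMatrix, GlobalMatrix
from .errors import ValidationError
from .types import REGIONS

MASK_INDEX = {"head": 1, "dorsum": 2, "limb": 3}


def _comment(manifest_ref: str | None) -> str:
    return f"# manifest: {manifest_ref}\n" if manifest_ref else ""


def write_table(table: pd.DataFrame, path, manifest_ref: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_comment(manifest_ref))
        table.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_matrix(mat, path, manifest_ref: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_comment(manifest_ref))
        mat.to_frame().to_csv(fh)


def read_global_matrix(path) -> GlobalMatrix:
    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    return GlobalMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def read_characteristic_matrix(path, characteristic: str,
                               normalized: bool = False) -> CharacteristicMatrix:
    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    return CharacteristicMatrix(list(df.index.astype(str)),
                                df.to_numpy(dtype=float), characteristic,
                                normalized=normalized)


def write_json(obj, path, manifest_ref: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if manifest_ref is not None and isinstance(obj, dict):
        obj = {"manifest": manifest_ref, **obj}
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n",
                    encoding="utf-8")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_head_rasters(rasters: dict[str, np.ndarray], path,
                       manifest_ref: str | None = None) -> None:
    """Flattened binary head rasters, one row per individual."""
    ids = list(rasters)
    flat = np.stack([np.asarray(rasters[i]).ravel().astype(int) for i in ids])
    df = pd.DataFrame(flat, columns=[f"c{j}" for j in range(flat.shape[1])])
    df.insert(0, "individual_id", ids)
    write_table(df, path, manifest_ref)


def read_head_rasters(path) -> dict[str, np.ndarray]:
    df = read_table(path)
    ids = df["individual_id"].astype(str)
    flat = df.drop(columns="individual_id").to_numpy(dtype=int)
    g = int(round(np.sqrt(flat.shape[1])))
    side = g if g * g == flat.shape[1] else None
    out = {}
    for i, row in zip(ids, flat):
        out[i] = row.reshape(side, side).astype(bool) if side else row.astype(bool)
    return out


# ---------------------------------------------------------------------------
# Images, landmarks, masks


def write_image(raster: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(raster, dtype=float) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def read_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    return arr


def write_landmarks(landmarks: dict[str, tuple[float, float]], path) -> None:
    df = pd.DataFrame([{"name": k, "x": x, "y": y}
                       for k, (x, y) in landmarks.items()])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_landmarks(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, comment="#")
    return {str(r["name"]): (float(r["x"]), float(r["y"]))
            for _, r in df.iterrows()}


def write_masks(masks: dict[str, np.ndarray], path) -> None:
    """Region masks as a single indexed PNG (0 bg / 1 head / 2 dorsum / 3 limb)."""
    regions = list(masks.values())
    idx = np.zeros(regions[0].shape, dtype=np.uint8)
    for region, m in masks.items():
        if region not in MASK_INDEX:
            raise ValidationError(f"unknown region {region!r}")
        idx[m.astype(bool)] = MASK_INDEX[region]
    img = Image.fromarray(idx, mode="P")
    img.putpalette([0, 0, 0, 255, 0, 0, 0, 255, 0, 0, 0, 255] + [0] * 756)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img.save(path)


def read_masks(path) -> dict[str, np.ndarray]:
    idx = np.asarray(Image.open(path))
    return {region: idx == MASK_INDEX[region] for region in REGIONS}
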