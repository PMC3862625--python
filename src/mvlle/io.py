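"""Matrix and image I/O with provenance metadata.

Feature matrices and embeddings travel in one of two forms:

* ``.npz`` container — lossless binary round trip of the float64 payload
  plus a JSON metadata record (named dimensions, creating config hash,
  seed, creation time);
* ``.csv`` — UTF-8, comma-separated, ``.`` decimal point, one header row
  of column names; for interchange with external tools.

Labels are single-column CSV; images are 8-bit grayscale PNG/PGM/TIFF
read through Pillow.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "MatrixContainer",
    "config_hash",
    "write_matrix",
    "read_matrix",
    "write_csv_matrix",
    "read_csv_matrix",
    "read_image",
    "write_image",
    "write_labels",
    "read_labels",
]


@dataclass
class MatrixContainer:
    payload: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.payload = np.asarray(self.payload, dtype=float)
        self.meta.setdefault("shape", list(self.payload.shape))
        if list(self.payload.shape) != list(self.meta["shape"]):
            raise ValueError(
                f"metadata shape {self.meta['shape']} does not match payload "
                f"shape {list(self.payload.shape)}"
            )


def config_hash(config: Any) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _meta(dims: Sequence[str] | None, cfg_hash: str | None, seed: int | None) -> dict:
    return {
        "dims": list(dims) if dims else None,
        "config_hash": cfg_hash,
        "seed": seed,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    dims: Sequence[str] | None = None,
    cfg_hash: str | None = None,
    seed: int | None = None,
) -> Path:
    """Write a matrix to an .npz container (or .csv if the suffix says so)."""
    path = Path(path)
    m = np.asarray(matrix, dtype=float)
    if path.suffix == ".csv":
        write_csv_matrix(m, path)
        return path
    meta = _meta(dims, cfg_hash, seed)
    meta["shape"] = list(m.shape)
    np.savez(path, payload=m, meta=json.dumps(meta))
    return path


def read_matrix(path: str | Path) -> MatrixContainer:
    path = Path(path)
    if path.suffix == ".csv":
        return MatrixContainer(payload=read_csv_matrix(path))
    with np.load(path, allow_pickle=False) as z:
        payload = z["payload"]
        meta = json.loads(str(z["meta"]))
    if list(payload.shape) != list(meta.get("shape", payload.shape)):
        raise ValueError(
            f"{path}: payload shape {payload.shape} does not match recorded "
            f"metadata shape {meta.get('shape')}"
        )
    return MatrixContainer(payload=payload, meta=meta)


def write_csv_matrix(
    matrix: np.ndarray, path: str | Path, columns: Sequence[str] | None = None
) -> Path:
    path = Path(path)
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    columns = list(columns) if columns else [f"c{i}" for i in range(m.shape[1])]
    if len(columns) != m.shape[1]:
        raise ValueError("one column name per matrix column required")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(columns) + "\n")
        for row in m:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")
    return path


def read_csv_matrix(path: str | Path) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        rows = []
        for ln, line in enumerate(fh, start=2):
            vals = line.rstrip("\n").split(",")
            if len(vals) != len(header):
                raise ValueError(
                    f"{path}:{ln}: row has {len(vals)} fields but header "
                    f"declares {len(header)}"
                )
            rows.append([float(v) for v in vals])
    return np.array(rows, dtype=float)


def read_image(path: str | Path) -> np.ndarray:
    """8-bit grayscale raster from PNG/PGM/TIFF (converted if needed)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\n")
        for v in np.asarray(labels).ravel():
            fh.write(f"{int(v)}\n")
    return path


def read_labels(path: str | Path) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        return np.array([int(line.strip()) for line in fh if line.strip()])
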