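"""Deterministic on-disk formats: checkpoints, manifests, image directories.

Checkpoints use a custom container (JSON header + concatenated raw array
bytes) rather than a zip archive: zip members embed timestamps, and the
reproducibility contract requires byte-identical checkpoints from identical
runs.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import InvalidInputError

_MAGIC = b"DGCNCKPT"


def save_arrays(path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Write named arrays plus a JSON metadata blob, bit-deterministically."""
    entries = []
    blobs = []
    offset = 0
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        raw = arr.tobytes()
        entries.append(
            {"name": name, "dtype": arr.dtype.str, "shape": list(arr.shape), "offset": offset}
        )
        blobs.append(raw)
        offset += len(raw)
    header = json.dumps({"meta": meta or {}, "arrays": entries}, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        for raw in blobs:
            fh.write(raw)


def load_arrays(path) -> tuple[dict[str, np.ndarray], dict]:
    with open(path, "rb") as fh:
        if fh.read(8) != _MAGIC:
            raise InvalidInputError(f"{path} is not a dgcn checkpoint")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        body = fh.read()
    arrays = {}
    for e in header["arrays"]:
        dt = np.dtype(e["dtype"])
        n = int(np.prod(e["shape"])) if e["shape"] else 1
        start = e["offset"]
        arr = np.frombuffer(body, dtype=dt, count=n, offset=start).reshape(e["shape"])
        arrays[e["name"]] = arr.copy()
    return arrays, header["meta"]


# ---------------------------------------------------------------------------
# image directories and manifests (TSV: relative_path <tab> grade)


def write_image_dir(out_dir, images: list[np.ndarray], grades=None, prefix: str = "img") -> Path:
    """Write images as 8-bit PNGs plus manifest.tsv; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    width = max(4, len(str(len(images))))
    for i, img in enumerate(images):
        arr = np.clip(np.asarray(img), 0.0, 1.0)
        u8 = (arr * 255.0).round().astype(np.uint8)
        rel = f"{prefix}_{i:0{width}d}.png"
        Image.fromarray(u8).save(out / rel)
        rows.append({"relative_path": rel, "grade": -1 if grades is None else int(grades[i])})
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_manifest(manifest_path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, sep="\t")
    missing = {"relative_path", "grade"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest lacks columns {sorted(missing)}")
    return df


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as float64 RGB in [0, 1], channel-last."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def load_image_dir(data_dir, manifest: pd.DataFrame | None = None):
    """Load images (and grades when a manifest is given) from a directory.

    Without a manifest, all *.png/*.jpg/*.jpeg files are loaded in sorted
    order and grades are None.
    """
    data_dir = Path(data_dir)
    if manifest is not None:
        images = [load_image(data_dir / rel) for rel in manifest["relative_path"]]
        return images, manifest["grade"].to_numpy()
    paths = sorted(
        p for p in data_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise InvalidInputError(f"no images found in {data_dir}")
    return [load_image(p) for p in paths], None
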