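"""Archive, table, and preview I/O for pipeline artifacts.

Numeric data travel in ``.npz`` archives (bit-exact round trips), tables in
CSV, summaries in JSON, and optional human-viewable previews in lossless
PNG.  Every loader raises :class:`ArchiveFormatError` on malformed input
rather than propagating a low-level crash.
"""

from __future__ import annotations

import csv
import json
import zipfile
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .mri import SamplingMask


class ArchiveFormatError(ValueError):
    """A file exists but is not a readable artifact archive."""


def save_archive(path, **arrays) -> None:
    np.savez(path, **arrays)


def load_archive(path) -> Dict[str, np.ndarray]:
    try:
        with np.load(path, allow_pickle=False) as data:
            return {k: data[k] for k in data.files}
    except (ValueError, OSError, zipfile.BadZipFile, KeyError) as exc:
        raise ArchiveFormatError(f"cannot read archive {path}: {exc}") from exc


def save_mask(path, mask: SamplingMask) -> None:
    np.savez(path, grid=mask.grid.astype(np.uint8), accel=np.asarray(mask.accel))


def load_mask(path) -> SamplingMask:
    data = load_archive(path)
    try:
        return SamplingMask(grid=data["grid"], accel=float(data["accel"]))
    except KeyError as exc:
        raise ArchiveFormatError(f"mask archive {path} missing field {exc}") from exc


def save_png(path, image: np.ndarray) -> None:
    """Normalized 8-bit grayscale preview (lossless PNG)."""
    import imageio.v3 as iio

    arr = np.asarray(image).real.astype(float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 255).round().astype(np.uint8))


def save_csv(path, rows: Sequence[Dict], fieldnames: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def load_csv(path) -> List[Dict]:
    try:
        with open(path, newline="") as fh:
            return list(csv.DictReader(fh))
    except OSError as exc:
        raise ArchiveFormatError(f"cannot read table {path}: {exc}") from exc


def save_json(path, payload: Dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_json(path) -> Dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ArchiveFormatError(f"cannot read JSON {path}: {exc}") from exc
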