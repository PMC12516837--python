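"""Cohort manifests: CSV + 8-bit PNG tiles on disk.

A manifest row is one tile: ``slide_id, patient_id, label, tile_path,
base_sigma``.  Tile paths are stored relative to the manifest's
directory, so a cohort directory is relocatable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .types import LabeledCohort, SlideBag, TileRecord

__all__ = ["write_manifest", "read_manifest", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ("slide_id", "patient_id", "label", "tile_path", "base_sigma")


def write_manifest(cohort: LabeledCohort, out_dir) -> Path:
    """Write tiles as PNG plus a ``manifest.csv``; returns the CSV path."""
    out_dir = Path(out_dir)
    tiles_dir = out_dir / "tiles"
    tiles_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for bag in cohort.bags:
            for tile in bag.tiles:
                rel = Path("tiles") / f"{tile.tile_id}.png"
                iio.imwrite(out_dir / rel, tile.image)
                writer.writerow(
                    [bag.slide_id, bag.patient_id, bag.label,
                     rel.as_posix(), repr(float(tile.base_sigma))]
                )
    return manifest_path


def read_manifest(path) -> LabeledCohort:
    """Load a cohort from a manifest CSV; bags grouped by slide_id.

    Raises with row context on missing columns, non-binary labels or
    unreadable tile files.
    """
    path = Path(path)
    base = path.parent
    bags: dict[str, SlideBag] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        n_rows = 0
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            n_rows += 1
            try:
                label = int(row["label"])
                if label not in (0, 1):
                    raise ValueError(f"label must be 0/1, got {row['label']!r}")
                tile_path = base / row["tile_path"]
                if not tile_path.exists():
                    raise FileNotFoundError(f"tile file not found: {tile_path}")
                image = np.asarray(iio.imread(tile_path))
                tile = TileRecord(
                    tile_id=Path(row["tile_path"]).stem,
                    image=image,
                    base_sigma=float(row["base_sigma"]),
                )
            except Exception as exc:
                raise type(exc)(f"manifest row {i}: {exc}") from exc
            sid = row["slide_id"]
            if sid not in bags:
                bags[sid] = SlideBag(sid, row["patient_id"], label, [])
            bags[sid].tiles.append(tile)
    if n_rows == 0:
        raise ValueError(f"no slides in manifest {path}")
    return LabeledCohort(list(bags.values()))
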