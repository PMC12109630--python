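"""Import/export of the standard interchange files around the container.

Rasters travel as TIFF/PNG, per-nucleus tables as CSV
(id, row, col, label, prediction), and polygon sets (nuclear boundaries,
gland annotations) as GeoJSON-style JSON with (row, col) vertex lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .patching import GlandAnnotation, NucleusRecord


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)
    return path


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path))


def write_nuclei_csv(
    path: str | Path,
    nuclei: list[NucleusRecord],
    labels: dict[int, str] | None = None,
    predictions: dict[int, float] | None = None,
) -> Path:
    rows = []
    for nuc in nuclei:
        rows.append(
            dict(
                nucleus_id=nuc.nucleus_id,
                row=nuc.center[0],
                col=nuc.center[1],
                label=(labels or {}).get(nuc.nucleus_id, ""),
                prediction=(predictions or {}).get(nuc.nucleus_id, np.nan),
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_nuclei_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"nucleus_id", "row", "col"}
    if not required <= set(df.columns):
        raise ValueError(f"nuclei CSV must have columns {sorted(required)}")
    return df


def write_polygons_json(path: str | Path, polygons: list[np.ndarray]) -> Path:
    payload = {
        "type": "PolygonSet",
        "coordinate_order": "row-col",
        "polygons": [np.asarray(p, dtype=float).tolist() for p in polygons],
    }
    Path(path).write_text(json.dumps(payload))
    return Path(path)


def read_polygons_json(path: str | Path) -> list[np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return [np.asarray(p, dtype=float) for p in payload["polygons"]]


def write_gland_annotation(path: str | Path, glands: GlandAnnotation) -> Path:
    return write_polygons_json(path, glands.polygons)


def read_gland_annotation(path: str | Path) -> GlandAnnotation:
    return GlandAnnotation(read_polygons_json(path))


def write_nucleus_boundaries(path: str | Path, nuclei: list[NucleusRecord]) -> Path:
    payload = {
        "type": "NucleusBoundaries",
        "coordinate_order": "row-col",
        "nuclei": [
            {
                "nucleus_id": int(n.nucleus_id),
                "center": [float(n.center[0]), float(n.center[1])],
                "boundary": n.boundary.tolist(),
            }
            for n in nuclei
        ],
    }
    Path(path).write_text(json.dumps(payload))
    return Path(path)


def read_nucleus_boundaries(path: str | Path) -> list[NucleusRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        NucleusRecord(
            nucleus_id=item["nucleus_id"],
            center=tuple(item["center"]),
            boundary=np.asarray(item["boundary"]),
        )
        for item in payload["nuclei"]
    ]
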