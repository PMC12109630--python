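"""Cell-centric patch extraction, gland/stroma labeling, cohort splitting.

Conventions (used consistently across the package):

* coordinates are 0-based ``(row, col)``; patch extents are half-open;
* an even patch of size ``s`` has its designated center pixel at index
  ``floor(s/2)`` on each axis — the nucleus center lands exactly there;
* the slide is mirror-padded by ``s/2`` before cutting, so border nuclei
  still yield full-size patches without black bands;
* a nucleus belongs to a gland iff its CENTER lies inside (or on the
  boundary of) any annotated gland polygon — the inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .cmg import BiopsyContainer, PatchRecord, DEFAULT_PIXEL_SPACING_UM


@dataclass
class NucleusRecord:
    """One segmented nucleus: integer id, center and boundary in slide frame."""

    nucleus_id: int
    center: tuple[float, float]
    boundary: np.ndarray  # (n, 2) of (row, col)

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=np.float64)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2 or len(self.boundary) < 3:
            raise ValueError(
                f"nucleus {self.nucleus_id}: boundary must be a (n>=3, 2) polygon"
            )


@dataclass
class GlandAnnotation:
    """Set of simple closed polygons delineating annotated glandular regions."""

    polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.polygons = [np.asarray(p, dtype=np.float64) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                raise ValueError("each gland polygon needs >= 3 (row, col) vertices")

    def shapely_polygons(self) -> list[Polygon]:
        polys = []
        for p in self.polygons:
            poly = Polygon(p)
            if not poly.is_valid:
                raise ValueError("gland polygon is not simple")
            polys.append(poly)
        return polys


@dataclass(frozen=True)
class CohortSplit:
    """Biopsy-level train/validation/test partition."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]

    def cohort_of(self, biopsy_id: str) -> str:
        for name, ids in (
            ("train", self.train_ids),
            ("val", self.val_ids),
            ("test", self.test_ids),
        ):
            if biopsy_id in ids:
                return name
        raise KeyError(biopsy_id)


def extract_patch(
    image: np.ndarray, center: tuple[int, int], size: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Cut a size x size patch centered on ``center`` (mirror-padded at borders).

    Returns ``(patch, slide_offset)`` with
    ``slide_offset = center - size // 2`` per axis;
    ``patch[size//2, size//2] == image[center]``.
    """
    if size <= 0 or size % 2:
        raise ValueError(f"patch size must be a positive even integer, got {size}")
    h, w = image.shape[:2]
    r, c = int(round(center[0])), int(round(center[1]))
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} outside {h}x{w} image bounds")
    half = size // 2
    pad = ((half, half), (half, half)) + ((0, 0),) * (image.ndim - 2)
    padded = np.pad(image, pad, mode="symmetric")
    patch = padded[r : r + size, c : c + size].copy()
    return patch, (r - half, c - half)


def label_nucleus(center: tuple[float, float], glands: GlandAnnotation) -> str:
    """``gland`` iff the center lies inside or on any gland polygon, else ``stroma``."""
    pt = Point(center[0], center[1])
    for poly in glands.shapely_polygons():
        if poly.covers(pt):
            return "gland"
    return "stroma"


def build_biopsy_container(
    image: np.ndarray,
    nuclei: list[NucleusRecord],
    glands: GlandAnnotation,
    size: int,
    biopsy_id: str = "biopsy",
    pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM,
) -> BiopsyContainer:
    """One PatchRecord per nucleus, in nucleus order, labels from the annotation.

    Nuclear boundaries are transformed to patch frame; vertices that fall
    outside the patch (boundary straddling the patch edge) are clipped to
    the patch extent and the record is flagged ``clipped``.
    """
    channels = 1 if image.ndim == 2 else image.shape[2]
    shapely_polys = glands.shapely_polygons()  # validate once up front
    records = []
    for nuc in nuclei:
        try:
            patch, offset = extract_patch(image, nuc.center, size)
            label = "gland" if any(
                p.covers(Point(nuc.center[0], nuc.center[1])) for p in shapely_polys
            ) else "stroma"
        except ValueError as err:
            raise ValueError(f"nucleus {nuc.nucleus_id}: {err}") from err
        local = nuc.boundary - np.asarray(offset, dtype=np.float64)
        clipped = bool(local.size) and bool(
            (local < 0).any() or (local > size - 1).any()
        )
        local = np.clip(local, 0.0, np.nextafter(float(size), 0.0) - 1e-3)
        records.append(
            PatchRecord(
                nucleus_id=nuc.nucleus_id,
                pixels=patch,
                boundary=local,
                slide_offset=offset,
                label=label,
                clipped=clipped,
            )
        )
    container = BiopsyContainer(
        biopsy_id=biopsy_id,
        slide_shape=image.shape[:2],
        patch_size=size,
        pixel_spacing_um=pixel_spacing_um,
        channels=channels,
        records=records,
    )
    container.validate()
    return container


def split_by_biopsy(
    biopsy_ids: set[str] | list[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> CohortSplit:
    """Deterministic case-level split with largest-remainder rounding.

    Splitting is always by biopsy, never by cell, so no nucleus of one
    biopsy can appear in two cohorts.
    """
    ids = sorted(set(biopsy_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 biopsy ids to split into three cohorts")
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr <= 0):
        raise ValueError("fractions must be three positive numbers")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fr.sum()}")
    n = len(ids)
    raw = fr * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    # largest remainder; ties broken in train, val, test order
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    train = frozenset(shuffled[: counts[0]])
    val = frozenset(shuffled[counts[0] : counts[0] + counts[1]])
    test = frozenset(shuffled[counts[0] + counts[1] :])
    return CohortSplit(train_ids=train, val_ids=val, test_ids=test)
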