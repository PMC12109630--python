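"""Cell-centric per-biopsy container (CMG-style) format.

A CMG container holds every nucleus-centric patch of one biopsy — the
image tile, the nuclear boundary polygon in patch frame, the tile's
offset in the slide frame, the annotation label and an optional model
probability — appended in a single file that can reconstruct the
original biopsy image with its segmentation boundaries.

The byte layout is versioned and documented in ``docs/cmg_format.md``;
the format, not this code, is normative.  Records are fixed-layout and
written sequentially after the header, so appending new records never
rewrites existing ones (only the header's record count is updated in
place).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MAGIC = b"CMGC"
VERSION = 1
HEADER_SIZE = 48
DEFAULT_PIXEL_SPACING_UM = 0.329

_DTYPE_CODES = {0: np.uint8, 1: np.float32}
_DTYPE_TO_CODE = {np.dtype(np.uint8): 0, np.dtype(np.float32): 1}
_LABEL_CODES = {"stroma": 0, "gland": 1, "unknown": 2}
_CODE_LABELS = {v: k for k, v in _LABEL_CODES.items()}
LABELS = frozenset(_LABEL_CODES)

_HEADER_STRUCT = struct.Struct("<4sHBBIIIdQH10x")  # = 48 bytes
_REC_STRUCT = struct.Struct("<qiiBBdI")  # nucleus_id, off_r, off_c, label, flags, pred, n_vertices

_FLAG_HAS_PRED = 1
_FLAG_CLIPPED = 2


class CMGError(ValueError):
    """Base error for container validation and I/O problems."""


class CMGFormatError(CMGError):
    """Malformed or truncated container file."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class CMGVersionError(CMGError):
    """Container written by an unsupported format version."""


@dataclass
class PatchRecord:
    """One nucleus-centric patch: pixels, boundary, location, label, prediction.

    ``pixels`` is ``(size, size)`` or ``(size, size, channels)``;
    ``boundary`` is an ``(n, 2)`` float array of (row, col) vertices in
    the PATCH frame, each within ``[0, size)``; ``slide_offset`` is the
    (row, col) of the patch's top-left corner in the SLIDE frame and may
    be negative for border nuclei (mirror-padding policy).
    """

    nucleus_id: int
    pixels: np.ndarray
    boundary: np.ndarray
    slide_offset: tuple[int, int]
    label: str = "unknown"
    prediction: float | None = None
    clipped: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.boundary = np.asarray(self.boundary, dtype=np.float32)

    def validate(self, patch_size: int, channels: int) -> None:
        expected = (patch_size, patch_size) if channels == 1 else (patch_size, patch_size, channels)
        if self.pixels.shape not in (expected, (patch_size, patch_size, channels)):
            raise CMGError(
                f"record {self.nucleus_id}: pixels shape {self.pixels.shape} "
                f"!= {patch_size}x{patch_size}x{channels}"
            )
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise CMGError(f"record {self.nucleus_id}: boundary must be (n, 2)")
        if self.boundary.size and (
            self.boundary.min() < 0 or self.boundary.max() >= patch_size
        ):
            raise CMGError(
                f"record {self.nucleus_id}: boundary vertices outside [0, {patch_size})"
            )
        if self.label not in LABELS:
            raise CMGError(f"record {self.nucleus_id}: label {self.label!r} not in {sorted(LABELS)}")
        if self.prediction is not None and not (0.0 <= self.prediction <= 1.0):
            raise CMGError(
                f"record {self.nucleus_id}: prediction {self.prediction} outside [0, 1]"
            )

    def boundary_slide_frame(self) -> np.ndarray:
        """Boundary vertices in slide coordinates (derived, never stored)."""
        return self.boundary + np.asarray(self.slide_offset, dtype=np.float32)

    def equals(self, other: "PatchRecord") -> bool:
        return (
            self.nucleus_id == other.nucleus_id
            and self.slide_offset == other.slide_offset
            and self.label == other.label
            and self.clipped == other.clipped
            and (
                (self.prediction is None and other.prediction is None)
                or (
                    self.prediction is not None
                    and other.prediction is not None
                    and self.prediction == other.prediction
                )
            )
            and self.pixels.dtype == other.pixels.dtype
            and np.array_equal(self.pixels, other.pixels)
            and np.array_equal(self.boundary, other.boundary)
        )


@dataclass
class BiopsyContainer:
    """All patch records of one biopsy plus slide metadata."""

    biopsy_id: str
    slide_shape: tuple[int, int]
    patch_size: int
    pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM
    channels: int = 1
    records: list[PatchRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dtype(self) -> np.dtype:
        if self.records:
            return self.records[0].pixels.dtype
        return np.dtype(np.uint8)

    def validate(self) -> None:
        if self.patch_size <= 0 or self.patch_size % 2:
            raise CMGError(f"patch_size must be a positive even integer, got {self.patch_size}")
        if self.channels not in (1, 3):
            raise CMGError(f"channels must be 1 or 3, got {self.channels}")
        h, w = self.slide_shape
        half = self.patch_size // 2
        seen: set[int] = set()
        for rec in self.records:
            rec.validate(self.patch_size, self.channels)
            if rec.nucleus_id in seen:
                raise CMGError(f"duplicate nucleus_id {rec.nucleus_id} in container")
            seen.add(rec.nucleus_id)
            r, c = rec.slide_offset
            if not (-half <= r <= h - half and -half <= c <= w - half):
                raise CMGError(
                    f"record {rec.nucleus_id}: slide_offset {rec.slide_offset} places the "
                    f"patch outside the padded {h}x{w} slide frame"
                )
            if rec.pixels.dtype not in _DTYPE_TO_CODE:
                raise CMGError(
                    f"record {rec.nucleus_id}: unsupported pixel dtype {rec.pixels.dtype}"
                )
            if rec.pixels.dtype != self.dtype:
                raise CMGError("all records in a container must share a pixel dtype")

    def with_records(self, records: list[PatchRecord]) -> "BiopsyContainer":
        return replace(self, records=records)


def _encode_record(rec: PatchRecord, patch_size: int, channels: int) -> bytes:
    flags = (_FLAG_HAS_PRED if rec.prediction is not None else 0) | (
        _FLAG_CLIPPED if rec.clipped else 0
    )
    head = _REC_STRUCT.pack(
        int(rec.nucleus_id),
        int(rec.slide_offset[0]),
        int(rec.slide_offset[1]),
        _LABEL_CODES[rec.label],
        flags,
        float(rec.prediction) if rec.prediction is not None else 0.0,
        rec.boundary.shape[0],
    )
    verts = np.ascontiguousarray(rec.boundary, dtype=np.float32).tobytes()
    pix = np.ascontiguousarray(
        rec.pixels.reshape(patch_size, patch_size, channels)
    ).tobytes()
    return head + verts + pix


def write_container(container: BiopsyContainer, path: str | Path) -> Path:
    """Write a validated container to ``path``; returns the path."""
    container.validate()
    path = Path(path)
    bid = container.biopsy_id.encode("utf-8")
    if len(bid) > 0xFFFF:
        raise CMGError("biopsy_id too long")
    header = _HEADER_STRUCT.pack(
        MAGIC,
        VERSION,
        _DTYPE_TO_CODE[container.dtype],
        container.channels,
        container.patch_size,
        container.slide_shape[0],
        container.slide_shape[1],
        container.pixel_spacing_um,
        len(container.records),
        len(bid),
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(bid)
        for rec in container.records:
            fh.write(_encode_record(rec, container.patch_size, container.channels))
    return path


def append_records(path: str | Path, records: list[PatchRecord]) -> None:
    """Append records to an existing container file without rewriting it."""
    container = read_container(path, metadata_only=True)
    probe = container.with_records(list(records))
    probe.validate()
    existing_ids = {r.nucleus_id for r in read_container(path).records}
    for rec in records:
        if rec.nucleus_id in existing_ids:
            raise CMGError(f"append would duplicate nucleus_id {rec.nucleus_id}")
    with open(path, "r+b") as fh:
        fh.seek(0, 2)
        for rec in records:
            fh.write(_encode_record(rec, container.patch_size, container.channels))
        fh.seek(28)  # record_count field
        fh.write(struct.pack("<Q", len(existing_ids) + len(records)))


def read_container(path: str | Path, metadata_only: bool = False) -> BiopsyContainer:
    """Read a container file written by :func:`write_container`."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < HEADER_SIZE:
        raise CMGFormatError("file shorter than header", offset=len(data))
    (
        magic,
        version,
        dtype_code,
        channels,
        patch_size,
        slide_h,
        slide_w,
        spacing,
        n_records,
        id_len,
    ) = _HEADER_STRUCT.unpack_from(data, 0)
    if magic != MAGIC:
        raise CMGFormatError(f"bad magic {magic!r}", offset=0)
    if version != VERSION:
        raise CMGVersionError(f"unsupported container version {version} (expected {VERSION})")
    if dtype_code not in _DTYPE_CODES:
        raise CMGFormatError(f"unknown dtype code {dtype_code}", offset=6)
    dtype = np.dtype(_DTYPE_CODES[dtype_code])
    pos = HEADER_SIZE
    if len(data) < pos + id_len:
        raise CMGFormatError("truncated biopsy_id", offset=len(data))
    biopsy_id = data[pos : pos + id_len].decode("utf-8")
    pos += id_len
    container = BiopsyContainer(
        biopsy_id=biopsy_id,
        slide_shape=(slide_h, slide_w),
        patch_size=patch_size,
        pixel_spacing_um=spacing,
        channels=channels,
    )
    if metadata_only:
        return container
    pix_bytes = patch_size * patch_size * channels * dtype.itemsize
    records: list[PatchRecord] = []
    for _ in range(n_records):
        if len(data) < pos + _REC_STRUCT.size:
            raise CMGFormatError("truncated record header", offset=pos)
        nid, off_r, off_c, label_code, flags, pred, n_verts = _REC_STRUCT.unpack_from(data, pos)
        pos += _REC_STRUCT.size
        vert_bytes = n_verts * 2 * 4
        if len(data) < pos + vert_bytes + pix_bytes:
            raise CMGFormatError("truncated record payload", offset=pos)
        boundary = np.frombuffer(data, dtype=np.float32, count=n_verts * 2, offset=pos).reshape(
            n_verts, 2
        )
        pos += vert_bytes
        pixels = np.frombuffer(data, dtype=dtype, count=patch_size * patch_size * channels, offset=pos)
        pos += pix_bytes
        shape = (patch_size, patch_size) if channels == 1 else (patch_size, patch_size, channels)
        if label_code not in _CODE_LABELS:
            raise CMGFormatError(f"unknown label code {label_code}", offset=pos)
        records.append(
            PatchRecord(
                nucleus_id=nid,
                pixels=pixels.reshape(shape).copy(),
                boundary=boundary.copy(),
                slide_offset=(off_r, off_c),
                label=_CODE_LABELS[label_code],
                prediction=pred if flags & _FLAG_HAS_PRED else None,
                clipped=bool(flags & _FLAG_CLIPPED),
            )
        )
    if pos != len(data):
        raise CMGFormatError("trailing bytes after last record", offset=pos)
    container.records = records
    return container


def reconstruct_image(
    container: BiopsyContainer,
    draw_boundaries: bool = False,
    fill: float = 0,
    boundary_value: float | None = None,
) -> np.ndarray:
    """Reassemble the slide image from patches (last writer wins on overlap).

    Each record's pixels are placed at its ``slide_offset``; parts of a
    patch outside the slide frame (border nuclei) are cropped.  With
    ``draw_boundaries`` the nuclear boundary polygons are rasterized on
    top at their slide positions.
    """
    from skimage.draw import polygon_perimeter

    h, w = container.slide_shape
    size = container.patch_size
    shape = (h, w) if container.channels == 1 else (h, w, container.channels)
    canvas = np.full(shape, fill, dtype=container.dtype)
    for rec in container.records:
        r0, c0 = rec.slide_offset
        if r0 + size <= 0 or c0 + size <= 0 or r0 >= h or c0 >= w:
            raise CMGError(
                f"record {rec.nucleus_id}: patch at offset {rec.slide_offset} lies "
                "entirely outside the slide canvas"
            )
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + size, h), min(c0 + size, w)
        canvas[rs:re, cs:ce] = rec.pixels[rs - r0 : re - r0, cs - c0 : ce - c0]
    if draw_boundaries:
        if boundary_value is None:
            boundary_value = 255 if container.dtype == np.uint8 else 1.0
        for rec in container.records:
            verts = rec.boundary_slide_frame()
            if len(verts) < 2:
                continue
            rr, cc = polygon_perimeter(verts[:, 0], verts[:, 1], shape=(h, w), clip=True)
            canvas[rr, cc] = boundary_value
    return canvas
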