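# CMG container format, version 1

One file per biopsy, holding every cell-centric patch record plus the
slide metadata needed to reconstruct the original biopsy image with its
segmentation boundaries. This document is normative; the reader/writer
in `glandcell.cmg` implements it.

All integers are little-endian. Coordinates are 0-based `(row, col)`;
patch extents are half-open; the designated center pixel of an even
patch of size *s* is index `floor(s/2)` on each axis.

## Header (48 bytes, fixed)

| offset | type    | field           | notes                                  |
|-------:|---------|-----------------|----------------------------------------|
| 0      | `4s`    | magic           | ASCII `CMGC`                           |
| 4      | `u16`   | version         | this document: 1                       |
| 6      | `u8`    | dtype code      | 0 = uint8, 1 = float32 (pixel rasters) |
| 7      | `u8`    | channels        | 1 (optical density) or 3 (RGB)         |
| 8      | `u32`   | patch_size      | square patch edge, pixels              |
| 12     | `u32`   | slide_height    | pixels                                 |
| 16     | `u32`   | slide_width     | pixels                                 |
| 20     | `f64`   | pixel_spacing   | micrometres per pixel                  |
| 28     | `u64`   | record_count    | updated in place on append             |
| 36     | `u16`   | biopsy_id_len   | UTF-8 byte length                      |
| 38     | 10 × pad| reserved        | zeros                                  |

The UTF-8 `biopsy_id` follows immediately after the header.

## Records (sequential, appendable)

Records follow the biopsy id back to back. Appending new records never
rewrites existing ones; only `record_count` is patched in place.

Per record:

| type        | field        | notes                                         |
|-------------|--------------|-----------------------------------------------|
| `i64`       | nucleus_id   | unique within the container                   |
| `i32`,`i32` | slide_offset | (row, col) of patch top-left in slide frame; may be negative for border nuclei (slide is conceptually mirror-padded by `patch_size/2`) |
| `u8`        | label        | 0 = stroma, 1 = gland, 2 = unknown            |
| `u8`        | flags        | bit 0: prediction present; bit 1: boundary was clipped to the patch |
| `f64`       | prediction   | gland probability in [0, 1]; 0 when absent    |
| `u32`       | n_vertices   | boundary vertex count                         |
| `f32` × 2n  | boundary     | (row, col) vertices in PATCH frame, each in `[0, patch_size)` |
| dtype × s²c | pixels       | row-major, channel-last                       |

Boundary polygons are stored once, in patch frame; slide-frame
coordinates are always derived as `vertex + slide_offset` and never
stored (single source of truth).

## Reconstruction semantics

Placing each record's pixels at its slide offset (cropping parts outside
the canvas) reassembles the biopsy; overlapping patches are expected
(neighboring nuclei) and resolve last-writer-wins. When the patches
were cut from one source image, every covered pixel is restored exactly.

## Errors

Readers must reject: wrong magic and truncated payloads (format error,
reporting the byte offset) and unknown versions (explicit version
error). Trailing bytes after the last record are a format error.
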