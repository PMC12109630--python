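"""Synthetic Feulgen-like tissue scenes with known gland/stroma truth.

The generator stands in for patient biopsies that cannot be shared: it
renders dark ellipsoidal nuclei on a pale background, glands as rings of
round nuclei around an empty lumen, and scattered elongated stromal
nuclei, then emits exactly the inputs the patching module consumes
(image, nucleus records, gland polygons) plus the hidden truth labels.

A second ingredient emulates the annotation defect the two-round
semi-supervised procedure corrects: one-sided misses, where a fraction
``q`` of true gland nuclei are labeled stroma (never the reverse).

Scenes are rendered at a default spacing of 1.316 um/px (4x coarser than
the 0.329 um/px scanner sampling), so a 64-px desk patch covers the same
~84 um field of view as a full-scale 256-px patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon
from skimage.draw import ellipse as draw_ellipse

from .patching import GlandAnnotation, NucleusRecord

DEMO_PIXEL_SPACING_UM = 0.329 * 4


class PlacementError(RuntimeError):
    """Raised when a scene is too crowded to place all requested nuclei."""


@dataclass
class SceneSpec:
    """Parameters of one rendered biopsy scene.

    Lengths are in pixels, intensities in 8-bit grayscale units.
    ``gland_axes`` / ``stroma_axes`` are (major, minor) SEMI-axis ranges;
    stromal nuclei default to a ~2.5:1 elongation against the near-round
    gland nuclei.  Gland interiors (lumina) are left unoccupied.
    """

    canvas_shape: tuple[int, int] = (384, 384)
    n_glands: int = 4
    gland_radius_range: tuple[float, float] = (26.0, 42.0)
    nuclei_per_gland_ring: tuple[int, int] = (10, 16)
    gland_layers: int = 1
    n_stroma: int = 110
    gland_axes: tuple[tuple[float, float], tuple[float, float]] = ((4.5, 6.0), (3.5, 4.8))
    stroma_axes: tuple[tuple[float, float], tuple[float, float]] = ((5.5, 8.0), (1.8, 3.0))
    background: float = 215.0
    nuclear_density_range: tuple[float, float] = (80.0, 140.0)
    blur_sigma: float = 0.8
    noise_sigma: float = 4.0
    pixel_spacing_um: float = DEMO_PIXEL_SPACING_UM
    rgb: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_glands < 0 or self.n_stroma < 0 or self.gland_layers < 1:
            raise ValueError("counts must be non-negative and gland_layers >= 1")
        for lo, hi in (
            self.gland_radius_range,
            self.gland_axes[0],
            self.gland_axes[1],
            self.stroma_axes[0],
            self.stroma_axes[1],
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("radius/axis ranges must be positive and ordered")
        if self.nuclei_per_gland_ring[0] < 1:
            raise ValueError("need at least one nucleus per gland ring")


def small_gland_preset(seed: int = 0, **overrides) -> SceneSpec:
    """Scene dominated by very small glands (few nuclei, tight radius).

    Small glands are where recognition errors concentrate, so tests
    exercise this regime explicitly.
    """
    base = SceneSpec(
        n_glands=6,
        gland_radius_range=(13.0, 19.0),
        nuclei_per_gland_ring=(6, 9),
        n_stroma=120,
        seed=seed,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class AnnotationNoiseSpec:
    """One-sided annotation misses: gland truth relabeled stroma with rate q."""

    miss_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.miss_fraction <= 1.0:
            raise ValueError(f"miss_fraction must be in [0, 1], got {self.miss_fraction}")


@dataclass
class Scene:
    """A rendered scene: image, nucleus records, gland annotation, truth labels."""

    image: np.ndarray
    nuclei: list[NucleusRecord]
    glands: GlandAnnotation
    labels: dict[int, str]
    spec: SceneSpec = field(repr=False, default=None)


def _ellipse_polygon(
    center: tuple[float, float], a: float, b: float, phi: float, n: int = 16
) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    dr = a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
    dc = a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi)
    return np.column_stack([center[0] + dr, center[1] + dc])


def _circle_polygon(center: tuple[float, float], radius: float, n: int = 32) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def render_scene(spec: SceneSpec) -> Scene:
    """Render a scene deterministically under ``spec.seed``.

    Gland nuclei sit on rings around empty lumina, strictly inside their
    gland polygon; stromal nuclei are placed strictly outside every gland
    polygon.  The image is background minus rasterized nuclear densities,
    blurred and with additive Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_shape
    retry_budget = 400

    gland_major_hi = spec.gland_axes[0][1]
    ring_step = 2 * gland_major_hi + 1.0  # radial spacing between layers
    gland_centers: list[np.ndarray] = []
    gland_radii: list[float] = []
    for _ in range(spec.n_glands):
        placed = False
        for _attempt in range(retry_budget):
            r_ring = rng.uniform(*spec.gland_radius_range)
            outer = r_ring + (spec.gland_layers - 1) * ring_step + gland_major_hi + 3.0
            margin = outer + 2.0
            if 2 * margin >= min(h, w):
                continue
            center = rng.uniform([margin, margin], [h - margin, w - margin])
            ok = all(
                np.hypot(*(center - gc)) > outer + gr + 10.0
                for gc, gr in zip(gland_centers, gland_radii)
            )
            if ok:
                gland_centers.append(center)
                gland_radii.append(outer)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place gland {len(gland_centers)} in a {h}x{w} canvas; "
                "lower n_glands or gland_radius_range"
            )

    nuclei: list[NucleusRecord] = []
    labels: dict[int, str] = {}
    gland_polygons: list[np.ndarray] = []
    ellipses: list[tuple] = []  # (center, a, b, phi)
    nid = 0

    for center, outer in zip(gland_centers, gland_radii):
        base_ring = outer - gland_major_hi - 3.0 - (spec.gland_layers - 1) * ring_step
        gland_polygons.append(_circle_polygon(tuple(center), outer, n=32))
        for layer in range(spec.gland_layers):
            r_ring = base_ring + layer * ring_step
            n_ring = int(rng.integers(spec.nuclei_per_gland_ring[0], spec.nuclei_per_gland_ring[1] + 1))
            n_ring = max(n_ring, 1)
            angles = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
            angles = angles + rng.normal(0.0, 0.35 / max(n_ring, 1), size=n_ring)
            for theta in angles:
                rr = r_ring + rng.normal(0.0, 1.0)
                pos = center + rr * np.array([np.cos(theta), np.sin(theta)])
                a = rng.uniform(*spec.gland_axes[0])
                b = rng.uniform(*spec.gland_axes[1])
                phi = theta + rng.normal(0.0, 0.25)  # radial orientation
                nuclei.append(
                    NucleusRecord(nid, tuple(pos), _ellipse_polygon(tuple(pos), a, b, phi))
                )
                ellipses.append((pos, a, b, phi))
                labels[nid] = "gland"
                nid += 1

    shapely_glands = [Polygon(p).buffer(2.0) for p in gland_polygons]
    stroma_centers: list[np.ndarray] = []
    edge = spec.stroma_axes[0][1] + 2.0
    for _ in range(spec.n_stroma):
        placed = False
        for _attempt in range(retry_budget):
            pos = rng.uniform([edge, edge], [h - edge, w - edge])
            if any(g.covers(Point(pos[0], pos[1])) for g in shapely_glands):
                continue
            if any(np.hypot(*(pos - sc)) < 8.0 for sc in stroma_centers):
                continue
            stroma_centers.append(pos)
            a = rng.uniform(*spec.stroma_axes[0])
            b = rng.uniform(*spec.stroma_axes[1])
            phi = rng.uniform(0.0, np.pi)
            nuclei.append(NucleusRecord(nid, tuple(pos), _ellipse_polygon(tuple(pos), a, b, phi)))
            ellipses.append((pos, a, b, phi))
            labels[nid] = "stroma"
            nid += 1
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place stromal nucleus {len(stroma_centers)}; lower n_stroma"
            )

    image = np.full((h, w), spec.background, dtype=np.float64)
    for pos, a, b, phi in ellipses:
        rr, cc = draw_ellipse(pos[0], pos[1], a, b, shape=(h, w), rotation=-phi)
        density = rng.uniform(*spec.nuclear_density_range)
        image[rr, cc] -= density  # absorbance adds where nuclei overlap
    if spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 255.0).astype(np.uint8)
    if spec.rgb:
        # thionin-like blue-violet tint: nuclei absorb mostly in red/green
        od = (spec.background - image.astype(np.float64)) / 255.0
        rgb = np.stack(
            [
                np.clip(image * (1.0 - 0.25 * od), 0, 255),
                np.clip(image * (1.0 - 0.45 * od), 0, 255),
                np.clip(image.astype(np.float64) + 12 * od, 0, 255),
            ],
            axis=-1,
        ).astype(np.uint8)
        image = rgb

    return Scene(
        image=image,
        nuclei=nuclei,
        glands=GlandAnnotation(gland_polygons),
        labels=labels,
        spec=spec,
    )


def inject_annotation_misses(
    labels: dict[int, str], noise: AnnotationNoiseSpec
) -> tuple[dict[int, str], frozenset[int]]:
    """Flip exactly ``round(q * n_gland)`` gland labels to stroma.

    Flips are chosen uniformly under ``noise.seed`` and are strictly
    one-sided: stroma labels are never touched.  Returns the corrupted
    labels and the flipped-id set (the hidden truth for evaluation).
    """
    rng = np.random.default_rng(noise.seed)
    gland_ids = sorted(i for i, lab in labels.items() if lab == "gland")
    n_flip = int(round(noise.miss_fraction * len(gland_ids)))
    flipped = frozenset(
        int(i) for i in rng.choice(gland_ids, size=n_flip, replace=False)
    ) if n_flip else frozenset()
    corrupted = {
        i: ("stroma" if i in flipped else lab) for i, lab in labels.items()
    }
    return corrupted, flipped
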