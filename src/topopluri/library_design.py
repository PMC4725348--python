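"""In-silico micro-topography library: primitives, features, masks, chip layout.

A topography *feature* is a square bounding box (10, 20 or 28 um on a side)
containing one or more geometric primitives -- circles, equilateral triangles
and rectangles ("lines") -- extruded to a constant height of 10 um.  Each
feature tiles a 290 x 290 um area inside a 300 um micro-well (a *TopoUnit*),
and a chip is a 66 x 66 grid of such wells carrying every design in duplicate,
with the remaining wells left as flat controls.

The library here is generated, not read from fabrication files: designs are
sampled randomly (primitive count, kind, size, orientation and position) and
de-duplicated by a canonical hash of the rasterized feature mask, so the same
seed always yields the same library.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Allowed side lengths of the feature bounding square, um.
FEAT_SIZES = (10.0, 20.0, 28.0)
#: Extrusion height of every feature, um (constant across the library).
FEATURE_HEIGHT_UM = 10.0
#: Chip is a GRID_SIDE x GRID_SIDE array of micro-wells.
GRID_SIDE = 66
N_WELLS = GRID_SIDE * GRID_SIDE
#: Center-to-center pitch of the micro-wells, um.
WELL_PITCH_UM = 300.0
#: Side of the tiled (feature-covered) area inside each well, um.
TILED_AREA_UM = 290.0
#: Sentinel design id for flat-control wells.
FLAT_CONTROL = -1
#: Default rasterization resolution, um per pixel (10 um feature -> 50 x 50).
DEFAULT_RESOLUTION = 0.2

PRIMITIVE_KINDS = ("circle", "triangle", "line")

_SIZE_PARAM_COUNT = {"circle": 1, "triangle": 1, "line": 2}


class LibraryGenerationError(RuntimeError):
    """Raised when random design generation exhausts its retry budget."""


@dataclass(frozen=True)
class Primitive:
    """One elementary shape inside a feature bounding square.

    ``size_params`` are, by kind:

    - ``circle``:   ``(diameter,)`` in um
    - ``triangle``: ``(shortest_side,)`` -- equilateral, so every side equals
      the shortest side
    - ``line``:     ``(length, width)`` of the rectangle, length >= width

    ``position`` is the shape center (circle center / triangle centroid /
    rectangle center) in um within the bounding square; ``rotation`` is in
    degrees, counter-clockwise.
    """

    kind: str
    size_params: tuple[float, ...]
    position: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        expected = _SIZE_PARAM_COUNT[self.kind]
        if len(self.size_params) != expected:
            raise ValueError(
                f"{self.kind} primitive takes {expected} size parameter(s), "
                f"got {len(self.size_params)}"
            )
        if any(s <= 0 for s in self.size_params):
            raise ValueError("primitive sizes must be > 0")
        object.__setattr__(self, "size_params", tuple(float(s) for s in self.size_params))
        object.__setattr__(self, "position", (float(self.position[0]), float(self.position[1])))
        object.__setattr__(self, "rotation", float(self.rotation))

    # --- geometry -----------------------------------------------------

    def _triangle_vertex_offsets(self) -> np.ndarray:
        """Vertex offsets from the centroid, after rotation (shape (3, 2))."""
        side = self.size_params[0]
        circumradius = side / math.sqrt(3.0)
        base = np.deg2rad(np.array([90.0, 210.0, 330.0]) + self.rotation)
        return circumradius * np.column_stack([np.cos(base), np.sin(base)])

    def extent_offsets(self) -> tuple[float, float, float, float]:
        """(min_dx, max_dx, min_dy, max_dy) of the shape relative to center."""
        if self.kind == "circle":
            r = self.size_params[0] / 2.0
            return (-r, r, -r, r)
        if self.kind == "triangle":
            off = self._triangle_vertex_offsets()
            return (off[:, 0].min(), off[:, 0].max(), off[:, 1].min(), off[:, 1].max())
        length, width = self.size_params
        theta = math.radians(self.rotation)
        hx = abs(math.cos(theta)) * length / 2 + abs(math.sin(theta)) * width / 2
        hy = abs(math.sin(theta)) * length / 2 + abs(math.cos(theta)) * width / 2
        return (-hx, hx, -hy, hy)

    def fits_within(self, feat_size: float, tol: float = 1e-9) -> bool:
        """Whether the whole shape lies inside ``[0, feat_size]^2``."""
        cx, cy = self.position
        min_dx, max_dx, min_dy, max_dy = self.extent_offsets()
        return (
            cx + min_dx >= -tol
            and cx + max_dx <= feat_size + tol
            and cy + min_dy >= -tol
            and cy + max_dy <= feat_size + tol
        )

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-shape test (boundary inclusive)."""
        cx, cy = self.position
        dx = np.asarray(x, dtype=float) - cx
        dy = np.asarray(y, dtype=float) - cy
        if self.kind == "circle":
            r = self.size_params[0] / 2.0
            return dx * dx + dy * dy <= r * r
        if self.kind == "line":
            length, width = self.size_params
            theta = math.radians(self.rotation)
            c, s = math.cos(theta), math.sin(theta)
            u = c * dx + s * dy
            v = -s * dx + c * dy
            return (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
        # triangle: inside iff on the same side of all three (CCW) edges
        verts = self._triangle_vertex_offsets()
        inside = np.ones(np.shape(dx), dtype=bool)
        for i in range(3):
            ax, ay = verts[i]
            bx, by = verts[(i + 1) % 3]
            cross = (bx - ax) * (dy - ay) - (by - ay) * (dx - ax)
            inside &= cross >= -1e-12
        return inside

    def area(self) -> float:
        """Analytic shape area, um^2."""
        if self.kind == "circle":
            return math.pi * self.size_params[0] ** 2 / 4.0
        if self.kind == "triangle":
            return math.sqrt(3.0) / 4.0 * self.size_params[0] ** 2
        return self.size_params[0] * self.size_params[1]


@dataclass(frozen=True)
class TopographyDesign:
    """One library member: primitives composed in a bounding square."""

    design_id: int
    feat_size: float
    primitives: tuple[Primitive, ...]
    feature_height: float = FEATURE_HEIGHT_UM

    def __post_init__(self) -> None:
        if float(self.feat_size) not in FEAT_SIZES:
            raise ValueError(f"feat_size must be one of {FEAT_SIZES}, got {self.feat_size}")
        if len(self.primitives) < 1:
            raise ValueError("a design needs at least one primitive")
        if self.feature_height != FEATURE_HEIGHT_UM:
            raise ValueError(f"feature_height is fixed at {FEATURE_HEIGHT_UM} um")
        for prim in self.primitives:
            if not prim.fits_within(self.feat_size):
                raise ValueError(
                    f"design {self.design_id}: {prim.kind} primitive does not fit "
                    f"inside the {self.feat_size} um bounding square"
                )
        object.__setattr__(self, "primitives", tuple(self.primitives))
        object.__setattr__(self, "feat_size", float(self.feat_size))


@dataclass(frozen=True)
class FeatureMask:
    """Binary raster of one feature at a given resolution (um/pixel)."""

    pixels: np.ndarray
    resolution: float
    feat_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("mask must be a square 2-D grid")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "pixels", px)

    @property
    def n(self) -> int:
        return self.pixels.shape[0]

    @property
    def covered_fraction(self) -> float:
        return float(self.pixels.mean())


def render_feature_mask(
    design: TopographyDesign, resolution: float = DEFAULT_RESOLUTION
) -> FeatureMask:
    """Rasterize the union of a design's primitives onto a binary grid.

    A pixel is 1 iff its *center* lies inside any primitive (no
    anti-aliasing); the grid side is ``round(feat_size / resolution)``, which
    must reproduce ``feat_size`` to within half a pixel.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n = int(round(design.feat_size / resolution))
    if n < 1 or abs(n * resolution - design.feat_size) > resolution / 2 + 1e-12:
        raise ValueError(
            f"resolution {resolution} does not divide feat_size {design.feat_size} "
            "to within half a pixel"
        )
    centers = (np.arange(n) + 0.5) * resolution
    xg, yg = np.meshgrid(centers, centers, indexing="xy")
    mask = np.zeros((n, n), dtype=bool)
    for prim in design.primitives:
        mask |= prim.contains(xg, yg)
    return FeatureMask(pixels=mask.astype(np.uint8), resolution=resolution, feat_size=design.feat_size)


def canonical_hash(design: TopographyDesign, resolution: float = DEFAULT_RESOLUTION) -> str:
    """Canonical design fingerprint: hash of the rasterized mask.

    The mask is the union of the primitives, so the hash is invariant under
    reordering of the primitive list.
    """
    mask = render_feature_mask(design, resolution)
    h = hashlib.sha256()
    h.update(f"{design.feat_size:.6f}|{resolution:.6f}|".encode())
    h.update(np.packbits(mask.pixels).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Random library generation
# ---------------------------------------------------------------------------

def _sample_primitive(rng: np.random.Generator, feat_size: float, budget: list[int]) -> Primitive:
    """Draw one primitive uniformly: kind, size(s), rotation, then the center
    uniformly over the exact region where the rotated shape fits the square."""
    while True:
        if budget[0] <= 0:
            raise LibraryGenerationError(
                "retry budget exhausted while sampling a primitive that fits the "
                f"{feat_size} um bounding square (containment constraint)"
            )
        budget[0] -= 1
        kind = PRIMITIVE_KINDS[rng.integers(len(PRIMITIVE_KINDS))]
        if kind == "line":
            a, b = rng.uniform(1.0, feat_size, size=2)
            size_params = (max(a, b), min(a, b))
        else:
            size_params = (float(rng.uniform(1.0, feat_size)),)
        rotation = float(rng.uniform(0.0, 360.0))
        probe = Primitive(kind, size_params, (feat_size / 2, feat_size / 2), rotation)
        min_dx, max_dx, min_dy, max_dy = probe.extent_offsets()
        lo_x, hi_x = -min_dx, feat_size - max_dx
        lo_y, hi_y = -min_dy, feat_size - max_dy
        if hi_x < lo_x or hi_y < lo_y:  # shape too large at this rotation
            continue
        cx = float(rng.uniform(lo_x, hi_x))
        cy = float(rng.uniform(lo_y, hi_y))
        return Primitive(kind, size_params, (cx, cy), rotation)


def generate_library(
    n_designs: int,
    seed: int,
    feat_sizes: Sequence[float] = FEAT_SIZES,
    max_primitives: int = 5,
    retry_budget: int = 1000,
    resolution: float = DEFAULT_RESOLUTION,
) -> list[TopographyDesign]:
    """Generate ``n_designs`` pairwise-distinct random designs.

    Per design: the bounding-square size is drawn uniformly from
    ``feat_sizes``; the primitive count uniformly from {1..max_primitives};
    each primitive's kind uniformly over circle/triangle/line, its size(s)
    uniformly on [1 um, feat_size], its rotation uniformly on [0, 360) and its
    center uniformly subject to containment.  Distinctness is enforced by the
    canonical mask hash; a duplicate design is re-drawn.  Deterministic for a
    fixed seed.
    """
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    rng = np.random.default_rng(seed)
    designs: list[TopographyDesign] = []
    seen: set[str] = set()
    duplicate_retries = 0
    while len(designs) < n_designs:
        feat_size = float(feat_sizes[rng.integers(len(feat_sizes))])
        n_prims = int(rng.integers(1, max_primitives + 1))
        budget = [retry_budget]
        prims = tuple(_sample_primitive(rng, feat_size, budget) for _ in range(n_prims))
        design = TopographyDesign(design_id=len(designs), feat_size=feat_size, primitives=prims)
        key = canonical_hash(design, resolution)
        if key in seen or not render_feature_mask(design, resolution).pixels.any():
            duplicate_retries += 1
            if duplicate_retries > retry_budget:
                raise LibraryGenerationError(
                    "retry budget exhausted while enforcing design distinctness "
                    "(canonical mask hash collision)"
                )
            continue
        seen.add(key)
        designs.append(design)
    return designs


# ---------------------------------------------------------------------------
# Chip layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipLayout:
    """66 x 66 grid of micro-wells: design id per well (FLAT_CONTROL = flat)."""

    design_id: np.ndarray  # (66, 66) int
    replicate: np.ndarray  # (66, 66) int, 0/1 for design wells, -1 for flat
    well_pitch: float = WELL_PITCH_UM
    tiled_area_side: float = TILED_AREA_UM

    def __post_init__(self) -> None:
        d = np.asarray(self.design_id, dtype=int)
        r = np.asarray(self.replicate, dtype=int)
        if d.shape != (GRID_SIDE, GRID_SIDE) or r.shape != (GRID_SIDE, GRID_SIDE):
            raise ValueError(f"layout grids must be {GRID_SIDE} x {GRID_SIDE}")
        object.__setattr__(self, "design_id", d)
        object.__setattr__(self, "replicate", r)

    @property
    def n_flat(self) -> int:
        return int((self.design_id == FLAT_CONTROL).sum())

    @property
    def n_topography_wells(self) -> int:
        return N_WELLS - self.n_flat

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(N_WELLS), GRID_SIDE)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "design_id": self.design_id.ravel(),
                "replicate": self.replicate.ravel(),
            }
        )

    def wells_of(self, design_id: int) -> list[tuple[int, int]]:
        rr, cc = np.nonzero(self.design_id == design_id)
        return list(zip(rr.tolist(), cc.tolist()))


def layout_chip(designs: Sequence[TopographyDesign], seed: int) -> ChipLayout:
    """Place every design exactly twice at seed-determined wells; the rest of
    the 66 x 66 grid stays flat control."""
    n = len(designs)
    if 2 * n > N_WELLS:
        raise ValueError(f"{n} designs need {2 * n} wells but the chip has {N_WELLS}")
    rng = np.random.default_rng(seed)
    design_flat = np.full(N_WELLS, FLAT_CONTROL, dtype=int)
    replicate_flat = np.full(N_WELLS, -1, dtype=int)
    positions = rng.permutation(N_WELLS)[: 2 * n]
    ids = np.repeat([d.design_id for d in designs], 2)
    reps = np.tile([0, 1], n)
    design_flat[positions] = ids
    replicate_flat[positions] = reps
    return ChipLayout(
        design_id=design_flat.reshape(GRID_SIDE, GRID_SIDE),
        replicate=replicate_flat.reshape(GRID_SIDE, GRID_SIDE),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def design_to_dict(design: TopographyDesign) -> dict:
    return {
        "design_id": design.design_id,
        "feat_size": design.feat_size,
        "feature_height": design.feature_height,
        "primitives": [
            {
                "kind": p.kind,
                "size_params": list(p.size_params),
                "position": list(p.position),
                "rotation": p.rotation,
            }
            for p in design.primitives
        ],
    }


def design_from_dict(d: Mapping) -> TopographyDesign:
    prims = tuple(
        Primitive(
            kind=p["kind"],
            size_params=tuple(p["size_params"]),
            position=tuple(p["position"]),
            rotation=p.get("rotation", 0.0),
        )
        for p in d["primitives"]
    )
    return TopographyDesign(
        design_id=int(d["design_id"]),
        feat_size=float(d["feat_size"]),
        primitives=prims,
        feature_height=float(d.get("feature_height", FEATURE_HEIGHT_UM)),
    )


def designs_to_json(designs: Iterable[TopographyDesign]) -> str:
    return json.dumps([design_to_dict(d) for d in designs], indent=None, sort_keys=True)


def designs_from_json(text: str) -> list[TopographyDesign]:
    return [design_from_dict(d) for d in json.loads(text)]


def save_designs(designs: Iterable[TopographyDesign], path) -> None:
    with open(path, "w") as fh:
        fh.write(designs_to_json(designs))


def load_designs(path) -> list[TopographyDesign]:
    with open(path) as fh:
        return designs_from_json(fh.read())
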