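"""Voxel geometry of a triaxial-ellipsoid fruit and its stone.

The fruit is idealised as a triaxial ellipsoid with semi-length ``H``,
semi-large-diameter ``W`` and semi-small-diameter ``w``, containing a
concentric ellipsoidal stone.  The volume is discretised on a uniform
Cartesian voxel grid: a voxel belongs to the fruit iff its centre lies inside
the ellipsoid.  Exterior voxel faces carry the surface exchange (radiation,
convection, transpiration) and are split into a fixed sunny and a fixed
shaded hemisphere.  Because a staircase surface systematically overestimates
the true area, all exterior face areas are rescaled by one global factor so
that their sum equals the analytic ellipsoid surface area.

Growth is represented by keeping the number of voxels constant and scaling
every linear dimension, so volume and area scale exactly as s**3 and s**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Ellipsoid",
    "StoneGeometry",
    "FruitMesh",
    "InvalidGeometryError",
    "MeshingError",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "build_fruit_mesh",
    "grow_mesh",
]

# tissue labels
STONE = 0
PULP = 1
BOUNDARY = 2

#: exponent of the Thomsen surface-area approximation (max error 1.061 %)
THOMSEN_P = 1.6075


class InvalidGeometryError(ValueError):
    """Raised for non-positive semi-axes or a stone that is not inside the fruit."""


class MeshingError(RuntimeError):
    """Raised when no stable voxel spacing reaches the requested cell count."""


@dataclass(frozen=True)
class Ellipsoid:
    """Triaxial ellipsoid; semi-axes in metres.

    ``H`` is the semi-length, ``W`` the semi-large-diameter and ``w`` the
    semi-small-diameter.  The conventional ordering ``H >= W >= w`` is only
    advisory: a violation warns but does not fail.
    """

    H: float
    W: float
    w: float

    def __post_init__(self) -> None:
        if not (self.H > 0 and self.W > 0 and self.w > 0):
            raise InvalidGeometryError(
                f"semi-axes must be positive, got {(self.H, self.W, self.w)}"
            )
        if not (self.H >= self.W >= self.w):
            warnings.warn(
                f"semi-axes not ordered H >= W >= w: {(self.H, self.W, self.w)}",
                stacklevel=2,
            )

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return (self.H, self.W, self.w)

    def scaled(self, s: float) -> "Ellipsoid":
        return Ellipsoid(self.H * s, self.W * s, self.w * s)


@dataclass(frozen=True)
class StoneGeometry:
    """Concentric ellipsoidal stone, semi-axes in metres (may be zero: no stone)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise InvalidGeometryError("stone semi-axes must be non-negative")

    @classmethod
    def from_ratios(
        cls, fruit: Ellipsoid, ratios: tuple[float, float, float]
    ) -> "StoneGeometry":
        """Stone semi-axes as fixed fractions of the fruit semi-axes.

        The empirical stone/fruit regressions are cultivar-specific; the
        ratios are therefore plain configuration.
        """
        return cls(fruit.H * ratios[0], fruit.W * ratios[1], fruit.w * ratios[2])

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def is_inside(self, fruit: Ellipsoid) -> bool:
        return self.a < fruit.H and self.b < fruit.W and self.c < fruit.w

    def scaled(self, s: float) -> "StoneGeometry":
        return StoneGeometry(self.a * s, self.b * s, self.c * s)


def ellipsoid_volume(e: Ellipsoid) -> float:
    """Exact volume (4/3)·π·H·W·w of the triaxial ellipsoid, in m³."""
    return 4.0 / 3.0 * np.pi * e.H * e.W * e.w


def ellipsoid_surface_area(e: Ellipsoid, p: float = THOMSEN_P) -> float:
    """Thomsen approximation of the ellipsoid surface area (m²).

    ``A ≈ 4π·[((ab)^p + (ac)^p + (bc)^p)/3]^(1/p)`` with p = 1.6075; exact for
    spheres, within 1.061 % of the true area for any triaxial ellipsoid.
    """
    a, b, c = e.H, e.W, e.w
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * np.pi * s ** (1.0 / p)


@dataclass
class FruitMesh:
    """Uniform voxel mesh of the fruit, with tissue labels and exterior faces.

    All geometric fields are stored at the construction scale and multiplied
    by the cumulative growth factor ``scale`` on access, so that growing by
    ``a`` then ``b`` is bit-identical to growing once by ``a*b``.

    Exterior faces carry ``face_cell`` (owning cell index), ``face_normal``
    (outward axis-aligned unit vector), ``face_side`` (True = sunny) and a
    globally rescaled area whose sum equals the analytic surface area.
    """

    fruit0: Ellipsoid
    stone0: StoneGeometry
    peel_thickness: float
    sun_normal: np.ndarray  # unit normal of the sunny/shaded split plane
    dx0: float
    centres0: np.ndarray  # (N, 3) at construction scale
    labels: np.ndarray  # (N,) int8, STONE/PULP/BOUNDARY
    faces_per_cell: np.ndarray  # (N,) int
    face_cell: np.ndarray  # (M,)
    face_normal: np.ndarray  # (M, 3)
    face_side: np.ndarray  # (M,) bool, True = sunny
    area_factor: float  # global staircase correction
    scale: float = 1.0
    _face_area0: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._face_area0 = np.full(
            self.face_cell.shape[0], self.dx0 * self.dx0 * self.area_factor
        )

    # -- scaled geometry -------------------------------------------------
    @property
    def dx(self) -> float:
        return self.dx0 * self.scale

    @property
    def n_cells(self) -> int:
        return self.centres0.shape[0]

    @property
    def n_faces(self) -> int:
        return self.face_cell.shape[0]

    @property
    def centres(self) -> np.ndarray:
        return self.centres0 * self.scale

    @property
    def cell_volume(self) -> float:
        return self.dx ** 3

    @property
    def face_area(self) -> np.ndarray:
        return self._face_area0 * (self.scale * self.scale)

    @property
    def fruit(self) -> Ellipsoid:
        return self.fruit0.scaled(self.scale)

    @property
    def stone(self) -> StoneGeometry:
        return self.stone0.scaled(self.scale)

    @property
    def peel_fraction(self) -> np.ndarray:
        """Peel volume fraction of each cell, min(1, t·S_exposed/Δx³).

        With uniform exposed faces of raw area Δx² this reduces to
        ``t·n_faces/Δx``; the peel thickness is an absolute length, so the
        fraction shrinks as the fruit (and Δx) grows.
        """
        return np.minimum(1.0, self.peel_thickness * self.faces_per_cell / self.dx)

    @property
    def total_surface_area(self) -> float:
        return float(self.face_area.sum())

    @property
    def total_volume(self) -> float:
        return self.n_cells * self.cell_volume

    def neighbour_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices (ia, ib) of interior face-sharing cell pairs, each once."""
        if not hasattr(self, "_pairs"):
            key = _lattice_keys(self.centres0, self.dx0)
            order = np.argsort(key["flat"])
            self._pairs = _find_pairs(key, order)
        return self._pairs

    def centre_cell(self) -> int:
        """Index of the cell nearest the fruit centre."""
        return int(np.argmin(np.einsum("ij,ij->i", self.centres0, self.centres0)))


def _lattice_keys(centres0: np.ndarray, dx0: float) -> dict:
    ijk = np.rint(centres0 / dx0 - 0.5).astype(np.int64)
    ijk -= ijk.min(axis=0)
    dims = ijk.max(axis=0) + 2  # +2 leaves headroom for +1 shifts
    flat = (ijk[:, 0] * dims[1] + ijk[:, 1]) * dims[2] + ijk[:, 2]
    return {"ijk": ijk, "dims": dims, "flat": flat}


def _find_pairs(key: dict, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dims, flat = key["dims"], key["flat"]
    sorted_flat = flat[order]
    ia_all, ib_all = [], []
    for axis, stride in zip(
        range(3), (dims[1] * dims[2], dims[2], 1)
    ):
        target = flat + stride
        pos = np.searchsorted(sorted_flat, target)
        pos = np.clip(pos, 0, sorted_flat.size - 1)
        hit = sorted_flat[pos] == target
        ia_all.append(np.nonzero(hit)[0])
        ib_all.append(order[pos[hit]])
    return np.concatenate(ia_all), np.concatenate(ib_all)


def build_fruit_mesh(
    fruit: Ellipsoid,
    stone: StoneGeometry,
    peel_thickness: float,
    target_cells: int = 800,
    sun_normal: np.ndarray | tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> FruitMesh:
    """Voxelise the fruit on a uniform Cartesian grid.

    Parameters
    ----------
    fruit, stone
        Outer and inner (concentric) ellipsoids.
    peel_thickness
        Peel thickness in metres; must be smaller than the small semi-axis.
        Surface cells get a peel volume fraction rather than a separate layer
        because the voxel pitch exceeds the peel thickness.
    target_cells
        Minimum number of voxels (>= 800); the spacing is reduced until the
        count is reached.
    sun_normal
        Normal of the plane through the fruit centre separating the fixed
        sunny hemisphere (positive side) from the shaded one.
    """
    if target_cells < 800:
        raise ValueError("target_cells must be >= 800")
    if not (peel_thickness > 0 and peel_thickness < fruit.w):
        raise InvalidGeometryError("peel thickness must be in (0, small semi-axis)")
    if max(stone.semi_axes) > 0 and not stone.is_inside(fruit):
        raise InvalidGeometryError("stone must lie strictly inside the fruit")
    sun_normal = np.asarray(sun_normal, dtype=float)
    nrm = np.linalg.norm(sun_normal)
    if nrm == 0:
        raise ValueError("sun_normal must be a non-zero vector")
    sun_normal = sun_normal / nrm

    volume = ellipsoid_volume(fruit)
    dx = (volume / target_cells) ** (1.0 / 3.0)
    for _ in range(400):
        centres, inside = _grid_inside(fruit, dx)
        if inside.sum() > target_cells:  # "more than" the requested count
            break
        dx *= 0.985
    else:  # pragma: no cover - 400 shrink steps always suffice
        raise MeshingError(f"could not reach {target_cells} cells")

    centres3 = centres[inside]
    n = centres3.shape[0]

    # exterior faces: inside cell whose +/- axis neighbour is outside
    shape = inside.shape
    idx = np.full(shape, -1, dtype=np.int64)
    idx[inside] = np.arange(n)
    face_cell, face_axis, face_sign = [], [], []
    for axis in range(3):
        for sign in (+1, -1):
            nb = np.roll(inside, -sign, axis=axis)
            # rolling wraps; edge planes of the padded grid are all outside
            edge = [slice(None)] * 3
            edge[axis] = -1 if sign > 0 else 0
            nb[tuple(edge)] = False
            exposed = inside & ~nb
            cells = idx[exposed]
            face_cell.append(cells)
            face_axis.append(np.full(cells.size, axis))
            face_sign.append(np.full(cells.size, sign))
    face_cell = np.concatenate(face_cell)
    face_axis = np.concatenate(face_axis)
    face_sign = np.concatenate(face_sign)
    m = face_cell.size
    face_normal = np.zeros((m, 3))
    face_normal[np.arange(m), face_axis] = face_sign

    area_factor = ellipsoid_surface_area(fruit) / (m * dx * dx)

    # sunny/shaded: which side of the sun plane the face centroid lies on
    centroids = centres3[face_cell] + 0.5 * dx * face_normal
    face_side = centroids @ sun_normal > 0.0

    faces_per_cell = np.bincount(face_cell, minlength=n)

    labels = np.full(n, PULP, dtype=np.int8)
    if max(stone.semi_axes) > 0:
        sa = np.array(stone.semi_axes)
        r2 = np.einsum("ij,ij->i", centres3 / sa, centres3 / sa)
        labels[r2 <= 1.0] = STONE
    labels[faces_per_cell > 0] = BOUNDARY

    return FruitMesh(
        fruit0=fruit,
        stone0=stone,
        peel_thickness=peel_thickness,
        sun_normal=sun_normal,
        dx0=dx,
        centres0=centres3,
        labels=labels,
        faces_per_cell=faces_per_cell,
        face_cell=face_cell,
        face_normal=face_normal,
        face_side=face_side,
        area_factor=area_factor,
    )


def _grid_inside(fruit: Ellipsoid, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric cell-centre grid covering the ellipsoid and the inside mask."""
    half = [int(np.ceil(ax / dx)) + 1 for ax in fruit.semi_axes]
    axes = [(np.arange(-h, h) + 0.5) * dx for h in half]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centres = np.stack([X, Y, Z], axis=-1)
    sa = np.array(fruit.semi_axes)
    r2 = (X / sa[0]) ** 2 + (Y / sa[1]) ** 2 + (Z / sa[2]) ** 2
    return centres, r2 <= 1.0


def grow_mesh(mesh: FruitMesh, linear_scale: float) -> FruitMesh:
    """Scale every linear mesh dimension by ``linear_scale``, topology fixed.

    Cell count, tissue labels and face connectivity are unchanged; Δx,
    centres, face areas and volumes scale as s, s, s² and s³; peel fractions
    follow from the unchanged absolute peel thickness and the new Δx.
    """
    if not linear_scale > 0:
        raise ValueError("linear_scale must be positive")
    out = replace(mesh, scale=mesh.scale * linear_scale)
    if hasattr(mesh, "_pairs"):  # topology is scale-invariant
        out._pairs = mesh._pairs
    return out
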