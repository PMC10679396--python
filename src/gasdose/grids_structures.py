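"""Voxel grids, scalar volumes, planar structures and binary masks.

All geometry is expressed in physical millimetres on axial, axis-aligned
grids (z is the slice axis).  The voxel with index (i, j, k) has its centre
at ``origin + (i*dx, j*dy, k*dz)``.  Structures are stored as closed planar
polygons (one or more per axial slice) and are rasterized onto a grid with a
voxel-centre-in-polygon test under the even-odd fill rule, so that two
overlapping polygons on the same slice carve a hole where they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "Structure",
    "StructureSet",
    "BinaryMask",
    "rasterize_structure",
    "mask_intersection",
    "mask_union",
    "mask_volume_cc",
    "mask_centroid",
]

_VALID_UNITS = ("HU", "RED", "Gy")


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: origin and spacing in mm, shape in voxels."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must each have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be strictly positive, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def contains_point(self, point: Sequence[float]) -> bool:
        """True if *point* (mm) lies within the half-voxel-padded grid extent."""
        for ax in range(3):
            lo = self.origin[ax] - 0.5 * self.spacing[ax]
            hi = self.origin[ax] + (self.shape[ax] - 0.5) * self.spacing[ax]
            if not (lo <= point[ax] <= hi):
                return False
        return True

    def nearest_index(self, point: Sequence[float]) -> tuple[int, int, int]:
        idx = []
        for ax in range(3):
            i = int(round((point[ax] - self.origin[ax]) / self.spacing[ax]))
            idx.append(min(max(i, 0), self.shape[ax] - 1))
        return tuple(idx)


@dataclass
class ScalarVolume:
    """A scalar field on a :class:`VoxelGrid`; unit is one of HU, RED, Gy."""

    grid: VoxelGrid
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.unit in ("RED", "Gy") and self.values.min() < 0:
            raise ValueError(f"{self.unit} values must be >= 0")
        if self.unit == "HU" and self.values.min() < -1024:
            raise ValueError("HU values must be >= -1024")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy(), self.unit)


@dataclass
class Structure:
    """A named structure: closed planar polygons on axial planes.

    ``contours`` is a list of ``(z_mm, vertices)`` pairs where *vertices* is an
    (n, 2) array of in-plane (x, y) mm coordinates, n >= 3.  A repeated final
    vertex (explicit closure) is tolerated and dropped.
    """

    name: str
    contours: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for z, verts in self.contours:
            verts = np.asarray(verts, dtype=np.float64)
            if verts.ndim != 2 or verts.shape[1] != 2:
                raise ValueError(f"contour vertices must be (n, 2), got {verts.shape}")
            if verts.shape[0] >= 2 and np.allclose(verts[0], verts[-1]):
                verts = verts[:-1]
            if verts.shape[0] < 3:
                raise ValueError(
                    f"structure {self.name!r}: polygon needs >= 3 distinct vertices"
                )
            cleaned.append((float(z), verts))
        self.contours = cleaned


class StructureSet:
    """An ordered collection of uniquely named :class:`Structure` objects."""

    def __init__(self, structures: Iterable[Structure] = ()) -> None:
        self._structures: dict[str, Structure] = {}
        for s in structures:
            self.add(s)

    def add(self, structure: Structure) -> None:
        if structure.name in self._structures:
            raise ValueError(f"duplicate structure name {structure.name!r}")
        self._structures[structure.name] = structure

    def __getitem__(self, name: str) -> Structure:
        return self._structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self._structures

    def __iter__(self) -> Iterator[Structure]:
        return iter(self._structures.values())

    def __len__(self) -> int:
        return len(self._structures)

    @property
    def names(self) -> list[str]:
        return list(self._structures)


@dataclass
class BinaryMask:
    """Boolean membership per voxel of a :class:`VoxelGrid`."""

    grid: VoxelGrid
    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError(
                f"member shape {self.member.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())


def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized over points.

    Uses the half-open edge convention (an edge covers its lower-y vertex and
    excludes its upper-y vertex), which makes membership unambiguous for
    points level with a vertex and invariant under vertex-order reversal.
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = verts.shape[0]
    for a in range(n):
        x1, y1 = verts[a]
        x2, y2 = verts[(a + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        # x-coordinate where the edge crosses the horizontal through py
        x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside


def rasterize_structure(structure: Structure, grid: VoxelGrid) -> BinaryMask:
    """Voxelize a planar structure: member iff the voxel centre is inside the
    slice's polygon(s) under the even-odd rule.

    Raises ValueError if a contour plane cannot be matched to a grid slice
    within half a slice spacing.
    """
    member = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    px, py = np.meshgrid(xs, ys, indexing="ij")
    oz, dz = grid.origin[2], grid.spacing[2]
    for z, verts in structure.contours:
        kf = (z - oz) / dz
        k = int(round(kf))
        if k < 0 or k >= grid.shape[2] or abs(z - (oz + k * dz)) > dz / 2 + 1e-9:
            raise ValueError(
                f"contour plane z={z:.3f} mm of structure {structure.name!r} "
                f"does not align with any grid slice within dz/2"
            )
        # bounding-box restriction keeps the per-edge test cheap
        xmin, ymin = verts.min(axis=0)
        xmax, ymax = verts.max(axis=0)
        i0 = max(int(np.searchsorted(xs, xmin - 1e-9)) - 1, 0)
        i1 = min(int(np.searchsorted(xs, xmax + 1e-9)) + 1, grid.shape[0])
        j0 = max(int(np.searchsorted(ys, ymin - 1e-9)) - 1, 0)
        j1 = min(int(np.searchsorted(ys, ymax + 1e-9)) + 1, grid.shape[1])
        if i0 >= i1 or j0 >= j1:
            continue
        sub = _points_in_polygon(px[i0:i1, j0:j1], py[i0:i1, j0:j1], verts)
        member[i0:i1, j0:j1, k] ^= sub
    return BinaryMask(grid, member)


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.grid != b.grid:
        raise ValueError("masks are defined on different grids")


def mask_intersection(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise AND of two masks on the same grid."""
    _check_same_grid(a, b)
    return BinaryMask(a.grid, a.member & b.member)


def mask_union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise OR of two masks on the same grid."""
    _check_same_grid(a, b)
    return BinaryMask(a.grid, a.member | b.member)


def mask_volume_cc(mask: BinaryMask) -> float:
    """Mask volume in cubic centimetres (member count x voxel volume)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def mask_centroid(mask: BinaryMask) -> tuple[float, float, float]:
    """Arithmetic mean of member voxel centres, in mm patient coordinates."""
    if not mask.member.any():
        raise ValueError("empty structure")
    idx = np.argwhere(mask.member)
    mean_idx = idx.mean(axis=0)
    return tuple(
        float(mask.grid.origin[ax] + mask.grid.spacing[ax] * mean_idx[ax])
        for ax in range(3)
    )
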