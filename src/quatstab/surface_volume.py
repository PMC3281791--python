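"""Solvent-accessible surface area, grid molecular volume and cavity detection.

SASA uses the Shrake-Rupley method: each atom's van der Waals sphere is
inflated by the probe radius and sampled with a deterministic golden-section
spiral; the accessible area is the exposed fraction of sample points times
the inflated sphere area. Volumes count grid cells whose centers fall inside
any inflated atom sphere; the grid is anchored to absolute multiples of the
spacing so lattice translations are exactly invariant. Cavities are the
interior connected components (6-connectivity) of the empty grid after a
flood fill from the bounding-box boundary — the probe-inflated analogue of
rolling a solvent sphere over the outside of the molecule.

Element-based van der Waals radii (Bondi): C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, H 1.20; 1.70 for anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import AtomSite

__all__ = [
    "RadiusSet",
    "SurfaceResult",
    "VolumeResult",
    "Cavity",
    "BONDI",
    "sphere_points",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "grid_volume",
    "detect_cavities",
]


@dataclass(frozen=True)
class RadiusSet:
    """Element -> van der Waals radius (Å), with a default for unknowns."""

    radii: dict[str, float] = field(default_factory=dict)
    default: float = 1.70

    def __post_init__(self) -> None:
        if self.default <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")

    def of(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)

    def for_atoms(self, atoms) -> np.ndarray:
        return np.array([self.of(a.element) for a in atoms], dtype=float)


BONDI = RadiusSet({"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}, default=1.70)


@dataclass
class SurfaceResult:
    per_atom_area: np.ndarray
    per_residue_area: dict
    total_area: float
    probe: float
    n_points: int


@dataclass
class VolumeResult:
    volume: float
    grid_spacing: float
    probe: float
    occupied_cells: int


@dataclass
class Cavity:
    volume: float
    cell_count: int
    centroid: np.ndarray


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere sampling (golden-section spiral)."""
    if n <= 0:
        raise ValueError("n_points must be positive")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_coords(atoms) -> np.ndarray:
    if len(atoms) and isinstance(atoms[0], AtomSite):
        return np.array([a.coords for a in atoms], dtype=float)
    return np.asarray(atoms, dtype=float).reshape(len(atoms), 3)


def shrake_rupley_sasa(
    atoms,
    radii: RadiusSet = BONDI,
    probe: float = 1.4,
    n_points: int = 960,
    residue_keys=None,
) -> SurfaceResult:
    """Per-atom and total solvent-accessible surface area (Å²).

    ``residue_keys`` (optional, one hashable per atom) groups the per-atom
    areas into ``per_residue_area``.
    """
    if len(atoms) == 0:
        raise ValueError("no atoms")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords = _atom_coords(atoms)
    r = radii.for_atoms(atoms) + probe if isinstance(atoms[0], AtomSite) else (
        np.full(len(atoms), radii.default) + probe
    )
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = float(r.max())
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        nbrs = [j for j in tree.query_ball_point(coords[i], r=r[i] + rmax) if j != i]
        pts = coords[i] + r[i] * unit
        if nbrs:
            nb = np.asarray(nbrs, dtype=int)
            close = nb[np.linalg.norm(coords[nb] - coords[i], axis=1) < r[i] + r[nb]]
            exposed = np.ones(n_points, dtype=bool)
            for j in close:
                d2 = np.sum((pts - coords[j]) ** 2, axis=1)
                exposed &= d2 >= r[j] * r[j]
            frac = exposed.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * r[i] * r[i]

    per_res: dict = {}
    if residue_keys is not None:
        if len(residue_keys) != len(atoms):
            raise ValueError("residue_keys must parallel atoms")
        for key, area in zip(residue_keys, per_atom):
            per_res[key] = per_res.get(key, 0.0) + float(area)
    return SurfaceResult(per_atom, per_res, float(per_atom.sum()), probe, n_points)


def buried_surface_area(
    group_a,
    group_b,
    radii: RadiusSet = BONDI,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, float]:
    """(BSA, interface area) for two disjoint atom groups.

    BSA = ASA(A) + ASA(B) - ASA(A U B); the interface area is reported as
    BSA/2 (the per-side convention used by interface servers, so a buried
    area of ~4760 Å² corresponds to an interface of ~2380 Å²).
    """
    ids_a = {id(a) for a in group_a}
    if any(id(b) in ids_a for b in group_b):
        raise ValueError("atom groups overlap")
    asa_a = shrake_rupley_sasa(group_a, radii, probe, n_points).total_area
    asa_b = shrake_rupley_sasa(group_b, radii, probe, n_points).total_area
    asa_ab = shrake_rupley_sasa(list(group_a) + list(group_b), radii, probe, n_points).total_area
    bsa = asa_a + asa_b - asa_ab
    return bsa, bsa / 2.0


# ---------------------------------------------------------------------------
# grid volume and cavities

def _grid_occupancy(coords, r, spacing, margin_cells=0):
    """Boolean occupancy grid on the absolute lattice x = i * spacing.

    Returns (grid, imin) where grid[i,j,k] is True when the cell center
    (imin + [i,j,k]) * spacing lies within r of some atom.
    """
    imin = np.floor((coords - r[:, None]).min(axis=0) / spacing).astype(int) - margin_cells
    imax = np.ceil((coords + r[:, None]).max(axis=0) / spacing).astype(int) + margin_cells
    shape = tuple(imax - imin + 1)
    grid = np.zeros(shape, dtype=bool)
    for c, rad in zip(coords, r):
        lo = np.floor((c - rad) / spacing).astype(int) - imin
        hi = np.ceil((c + rad) / spacing).astype(int) - imin
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(shape) - 1)
        if np.any(hi < lo):
            continue
        ax = [(np.arange(lo[d], hi[d] + 1) + imin[d]) * spacing - c[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2)
        sub = grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub |= d2 <= rad * rad
        grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = sub
    return grid, imin


def grid_volume(
    atoms,
    radii: RadiusSet = BONDI,
    spacing: float = 1.0,
    probe: float = 0.0,
) -> VolumeResult:
    """Molecular volume: count of lattice cells whose centers lie within
    (vdW radius + probe) of any atom, times spacing³."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(atoms) == 0:
        raise ValueError("no atoms")
    coords = _atom_coords(atoms)
    r = radii.for_atoms(atoms) + probe
    grid, _ = _grid_occupancy(coords, r, spacing)
    n = int(grid.sum())
    return VolumeResult(volume=n * spacing**3, grid_spacing=spacing, probe=probe, occupied_cells=n)


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def detect_cavities(
    atoms,
    radii: RadiusSet = BONDI,
    spacing: float = 1.0,
    probe: float = 1.4,
    min_cells: int = 3,
) -> list[Cavity]:
    """Interior voids unreachable by the probe from outside.

    Cells within (radius + probe) of an atom are solid; empty cells are
    flood-filled from the bounding-box boundary; remaining empty connected
    components (6-connectivity) of at least ``min_cells`` cells are reported
    as cavities, largest first.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(atoms) == 0:
        return []
    coords = _atom_coords(atoms)
    r = radii.for_atoms(atoms) + probe
    grid, imin = _grid_occupancy(coords, r, spacing, margin_cells=2)
    empty = ~grid
    labels, n_labels = ndimage.label(empty, structure=_SIX_CONN)
    if n_labels == 0:
        return []
    # labels present on the boundary faces are connected to the outside
    boundary = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary.update(np.unique(labels[tuple(sl)]))
    boundary.discard(0)
    cavities: list[Cavity] = []
    for lab in range(1, n_labels + 1):
        if lab in boundary:
            continue
        idx = np.argwhere(labels == lab)
        if len(idx) < min_cells:
            continue
        centroid = (idx.mean(axis=0) + imin) * spacing
        cavities.append(Cavity(volume=len(idx) * spacing**3, cell_count=len(idx), centroid=centroid))
    cavities.sort(key=lambda c: (-c.volume, tuple(c.centroid)))
    return cavities
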