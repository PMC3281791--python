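"""Ground-truth synthetic structures.

Every generator is a pure function of its parameters plus a seed, so tests
can replay identical fixtures without shipping coordinate files:

* sphere bodies with known volume and a known interior cavity (or provably
  none) for the volume/cavity computations;
* ideal alpha-helical backbones with the textbook i -> i+4 carbonyl-amide
  hydrogen-bond pattern;
* two-chain complexes with exactly the requested numbers of cross-chain
  salt bridges, hydrogen bonds, disulfides and apolar contacts, everything
  else kept beyond a clearance distance;
* rigid/noisy chain copies with known superposition behaviour;
* a D2-arranged four-chain toy tetramer with tight dimers and smaller
  tetramer-forming interfaces, plus a mixed-composition dimer with an
  optionally all-apolar planted interface for the hydrophobic P-value.

These fixtures emulate the geometry of the detectors' inputs, not protein
chemistry: side chains are reduced to the atoms the detectors inspect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomSite, ChainModel, ONE_TO_THREE, ResidueSite, StructureModel
from .surface_volume import sphere_points

__all__ = [
    "PlantSpec",
    "make_sphere_body",
    "make_helix_chain",
    "make_planted_complex",
    "rigid_perturb",
    "make_toy_tetramer",
    "make_patchy_dimer",
]

_C_RADIUS = 1.70
_PROBE = 1.4


@dataclass
class PlantSpec:
    """Requested cross-chain interaction counts for a planted complex."""

    n_salt_bridges: int = 0
    n_hbonds: int = 0
    n_disulfides: int = 0
    n_apolar_contacts: int = 0
    interface_apolar_fraction: float = 0.0
    clearance: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_salt_bridges, self.n_hbonds, self.n_disulfides, self.n_apolar_contacts) < 0:
            raise ValueError("interaction counts must be non-negative")
        if not 0.0 <= self.interface_apolar_fraction <= 1.0:
            raise ValueError("interface_apolar_fraction must be in [0, 1]")
        if self.clearance <= 4.0:
            raise ValueError("clearance must exceed the largest detection cutoff (4.0 Å)")


# ---------------------------------------------------------------------------
# sphere bodies

def _chunk_into_residues(coords, chain_id: str, element: str = "C", res_name: str = "SPH",
                         hetero: bool = True, chunk: int = 50) -> ChainModel:
    residues = []
    for start in range(0, len(coords), chunk):
        block = coords[start:start + chunk]
        atoms = [
            AtomSite(name=f"{element}{i + 1}", element=element, coords=c, is_hetero=hetero)
            for i, c in enumerate(block)
        ]
        residues.append(ResidueSite(res_name, start // chunk + 1, "", atoms))
    return ChainModel(chain_id, residues, is_polymer=not hetero)


def make_sphere_body(kind: str, inner_radius: float, thickness: float = 3.0, seed: int = 0) -> StructureModel:
    """Pseudo-atom (carbon) sphere bodies.

    ``solid_cluster``: a jittered cubic lattice filling a ball of radius
    ``inner_radius``; the lattice pitch (1.5 Å) guarantees every interior
    point lies within a carbon vdW radius of some atom, so there are no
    voids of any size. ``hollow_shell``: concentric spherical atom layers
    whose inner vdW surface sits at ``inner_radius``, enclosing a single
    interior region; a probe of radius p can occupy a concentric ball of
    radius about ``inner_radius - p``.
    """
    if inner_radius <= 0 or thickness <= 0:
        raise ValueError("radii must be positive")
    rng = np.random.default_rng(seed)
    if kind == "solid_cluster":
        pitch = 1.5
        n = int(np.ceil(inner_radius / pitch))
        axis = np.arange(-n, n + 1) * pitch
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= inner_radius]
        pts = pts + rng.uniform(-0.05, 0.05, pts.shape)
    elif kind == "hollow_shell":
        if thickness < 2 * _PROBE:
            raise ValueError(f"shell thickness {thickness} Å < 2 x probe radius would leak")
        layer_step = 1.2
        radii = np.arange(inner_radius + _C_RADIUS, inner_radius + _C_RADIUS + thickness + 1e-9, layer_step)
        layers = []
        for r in radii:
            n_pts = max(12, int(np.ceil(4.0 * np.pi * r * r / 1.4**2)))
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            layers.append(sphere_points(n_pts) @ rot.T * r)
        pts = np.vstack(layers)
    else:
        raise ValueError(f"unknown sphere body kind {kind!r}")
    chain = _chunk_into_residues(pts, "A")
    return StructureModel(entry_id=f"SYN-{kind.upper()}", chains=[chain])


# ---------------------------------------------------------------------------
# ideal helix

def _dihedral_place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: point d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_BONDS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def make_helix_chain(n_res: int, sequence: str | None = None, chain_id: str = "A") -> ChainModel:
    """Ideal alpha-helical backbone (phi -57°, psi -47°) with N, CA, C, O atoms.

    A 15-residue helix shows exactly 11 carbonyl O(i) -> amide N(i+4)
    contacts under 3.5 Å, the canonical helical hydrogen-bond ladder.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues for a helix")
    seq = sequence if sequence is not None else "A" * n_res
    if len(seq) != n_res:
        raise ValueError("sequence length must equal n_res")

    n = [np.zeros(3)]
    ca = [np.array([_BONDS["N-CA"], 0.0, 0.0])]
    ang = np.deg2rad(_ANGLES["N-CA-C"])
    c = [ca[0] + _BONDS["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        n.append(_dihedral_place(n[i - 1], ca[i - 1], c[i - 1], _BONDS["C-N"], _ANGLES["CA-C-N"], _PSI))
        ca.append(_dihedral_place(ca[i - 1], c[i - 1], n[i], _BONDS["N-CA"], _ANGLES["C-N-CA"], _OMEGA))
        c.append(_dihedral_place(c[i - 1], n[i], ca[i], _BONDS["CA-C"], _ANGLES["N-CA-C"], _PHI))
    o = [_dihedral_place(n[i], ca[i], c[i], _BONDS["C-O"], _ANGLES["CA-C-O"], _PSI + 180.0)
         for i in range(n_res)]

    residues = []
    for i in range(n_res):
        resname = ONE_TO_THREE.get(seq[i].upper(), "ALA")
        atoms = [
            AtomSite("N", "N", n[i]),
            AtomSite("CA", "C", ca[i]),
            AtomSite("C", "C", c[i]),
            AtomSite("O", "O", o[i]),
        ]
        residues.append(ResidueSite(resname, i + 1, "", atoms))
    return ChainModel(chain_id, residues, is_polymer=True)


# ---------------------------------------------------------------------------
# planted complexes

# (resname1, atom1, resname2, atom2, pair distance Å) per planted kind;
# distances sit mid-interval below each detector's cutoff
_TEMPLATES = {
    "salt_bridge": ("ASP", "OD2", "O", "LYS", "NZ", "N", 3.0),
    "hbond": ("SER", "OG", "O", "SER", "OG", "O", 2.9),
    "disulfide": ("CYS", "SG", "S", "CYS", "SG", "S", 2.05),
    "vdw": ("LEU", "CD1", "C", "LEU", "CD1", "C", 3.8),
}


def make_planted_complex(spec: PlantSpec) -> StructureModel:
    """Two chains with exactly the requested cross-chain interactions.

    Each planted pair occupies its own station along x (pitch = clearance
    + 4 Å), with the two functional atoms facing each other across the
    interface plane at the template distance and the residue anchors (CA)
    pulled 5.5 Å back on either side, so no unplanned cross-chain atom pair
    comes within any detection cutoff. ``interface_apolar_fraction`` adds
    up to 10 extra apolar contact pairs (each one vdW contact) to make the
    interface hydrophobic without changing the specific planted counts.
    """
    rng = np.random.default_rng(spec.seed)
    kinds = (
        ["salt_bridge"] * spec.n_salt_bridges
        + ["hbond"] * spec.n_hbonds
        + ["disulfide"] * spec.n_disulfides
        + ["vdw"] * (spec.n_apolar_contacts + int(round(spec.interface_apolar_fraction * 10)))
    )
    if not kinds:
        kinds = []
    pitch = spec.clearance + 4.0
    res_a, res_b = [], []
    for k, kind in enumerate(kinds):
        rn1, an1, el1, rn2, an2, el2, dist = _TEMPLATES[kind]
        x = k * pitch + rng.uniform(-1.0, 1.0)
        z = rng.uniform(-2.0, 2.0)
        res_a.append(ResidueSite(rn1, k + 1, "", [
            AtomSite("CA", "C", np.array([x, 5.5, z])),
            AtomSite(an1, el1, np.array([x, dist / 2.0, z])),
        ]))
        res_b.append(ResidueSite(rn2, k + 1, "", [
            AtomSite("CA", "C", np.array([x, -5.5, z])),
            AtomSite(an2, el2, np.array([x, -dist / 2.0, z])),
        ]))
    chains = [ChainModel("A", res_a, True), ChainModel("B", res_b, True)]
    return StructureModel(entry_id="PLANT", chains=chains)


# ---------------------------------------------------------------------------
# perturbed copies

def rigid_perturb(
    chain: ChainModel,
    rotation_angles=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ChainModel:
    """Rotate (xyz Euler angles, degrees, about the chain centroid), translate,
    then add per-coordinate Gaussian noise of the given sigma."""
    if not chain.residues:
        raise ValueError("empty chain")
    rng = np.random.default_rng(seed)
    rot = Rotation.from_euler("xyz", rotation_angles, degrees=True).as_matrix()
    t = np.asarray(translation, dtype=float)
    coords = np.array([a.coords for r in chain.residues for a in r.atoms])
    centroid = coords.mean(axis=0)
    out_res = []
    for res in chain.residues:
        atoms = []
        for a in res.atoms:
            x = rot @ (a.coords - centroid) + centroid + t
            if noise_sigma > 0:
                x = x + rng.normal(0.0, noise_sigma, 3)
            atoms.append(AtomSite(a.name, a.element, x, a.occupancy, a.b_factor, a.alt_loc, a.is_hetero))
        out_res.append(ResidueSite(res.name, res.seq_id, res.icode, atoms))
    return ChainModel(chain.chain_id, out_res, chain.is_polymer)


# ---------------------------------------------------------------------------
# toy assemblies

def make_toy_tetramer(seed: int = 0) -> StructureModel:
    """Four identical carbon blocks in a D2-like arrangement.

    The A/B and C/D pairs meet over a large face with a small gap (tight
    dimers); A/C and B/D meet over a smaller face with a wider gap
    (tetramer interfaces); the diagonal pairs barely touch. All gaps exceed
    twice the carbon vdW radius, so grid volumes are exactly additive.
    """
    rng = np.random.default_rng(seed)
    pitch = 1.8
    nx, ny, nz = 7, 4, 4
    ax = np.arange(nx) * pitch
    ay = np.arange(ny) * pitch
    az = np.arange(nz) * pitch
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    block = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    block = block + rng.uniform(-0.05, 0.05, block.shape)

    dx = (nx - 1) * pitch + 4.6   # A->C offset: smaller face, wider gap
    dy = (ny - 1) * pitch + 4.2   # A->B offset: big face, narrow gap
    offsets = {"A": (0, 0), "B": (0, dy), "C": (dx, 0), "D": (dx, dy)}
    chains = []
    for cid, (ox, oy) in offsets.items():
        pts = block + np.array([ox, oy, 0.0])
        residues = []
        for i, p in enumerate(pts):
            residues.append(ResidueSite("UNK", i + 1, "", [AtomSite("C1", "C", p)]))
        chains.append(ChainModel(cid, residues, is_polymer=True))
    return StructureModel(entry_id="TOYTET", chains=chains)


def make_patchy_dimer(
    n_surface: int = 1000,
    bulk_apolar_fraction: float = 0.5,
    interface_apolar: bool = True,
    seed: int = 0,
) -> StructureModel:
    """Two touching atom-shell spheres of mixed polar/apolar composition.

    Surface atoms are apolar (Leu CD1, carbon) with probability
    ``bulk_apolar_fraction`` and polar (Ser OG, oxygen) otherwise; when
    ``interface_apolar`` is set, the small facing caps are forced
    all-apolar, planting a hydrophobic interface on an otherwise mixed
    surface. The caps are kept narrow and deeply buried so an equal-area
    random surface patch rarely fits inside one — the planted interface is
    genuinely anomalous under the patch null.
    """
    rng = np.random.default_rng(seed)
    radius = 14.0
    gap = 3.3
    pts = sphere_points(n_surface) * radius
    centers = {"A": np.zeros(3), "B": np.array([2 * radius + gap, 0.0, 0.0])}
    facing = {"A": 1.0, "B": -1.0}
    chains = []
    for cid, center in centers.items():
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        local = pts @ rot.T
        apolar = rng.random(n_surface) < bulk_apolar_fraction
        if interface_apolar:
            cap = local[:, 0] * facing[cid] > radius - 2.2
            apolar = apolar | cap
        residues = []
        for i in range(n_surface):
            if apolar[i]:
                res, atom, el = "LEU", "CD1", "C"
            else:
                res, atom, el = "SER", "OG", "O"
            residues.append(ResidueSite(res, i + 1, "", [AtomSite(atom, el, local[i] + center)]))
        chains.append(ChainModel(cid, residues, is_polymer=True))
    return StructureModel(entry_id="PATCHY", chains=chains)
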