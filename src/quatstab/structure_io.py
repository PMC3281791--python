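"""Coordinate model and structure I/O.

Parses PDB/mmCIF files (via gemmi) into a small uniform hierarchy
(:class:`StructureModel` -> :class:`ChainModel` -> :class:`ResidueSite` ->
:class:`AtomSite`), captures deposited biological-assembly transforms, and
writes a PDB subset back out.

Conventions applied on read:

* first model only, for multi-model files;
* alternate locations resolved to the highest-occupancy conformer
  (ties broken by alphabetical alt-loc id);
* hydrogens dropped (the X-ray entries this package targets contain none and
  every downstream cutoff is heavy-atom based);
* waters and non-polymer hetero groups (cofactors, ions) kept in the model
  but flagged ``is_hetero`` so that area/volume/contact computations can
  exclude them.
"""

from __future__ import annotations

import copy
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "ResidueSite",
    "ChainModel",
    "StructureModel",
    "AssemblyTransform",
    "StructureParseError",
    "read_structure",
    "build_assembly",
    "extract_sequence",
    "write_pdb",
    "collect_atoms",
    "three_to_one",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class AtomSite:
    """One atom: name, element, position (Å) and crystallographic metadata."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueSite:
    """One residue (3-letter code, author numbering) and its atoms."""

    name: str
    seq_id: int
    icode: str = ""
    atoms: list[AtomSite] = field(default_factory=list)

    def get(self, atom_name: str) -> AtomSite | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.icode)


@dataclass
class ChainModel:
    """A chain: ordered residues plus a polymer flag."""

    chain_id: str
    residues: list[ResidueSite] = field(default_factory=list)
    is_polymer: bool = True

    def polymer_residues(self) -> list[ResidueSite]:
        return [r for r in self.residues if not all(a.is_hetero for a in r.atoms)]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class AssemblyTransform:
    """Rigid motion x' = R x + t applied to a list of chains to build an assembly."""

    rotation: np.ndarray
    translation: np.ndarray
    apply_to: list[str]
    op_id: str = ""

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def validate(self) -> None:
        r = self.rotation
        if abs(np.linalg.det(r) - 1.0) > 1e-6 or np.max(np.abs(r @ r.T - np.eye(3))) > 1e-6:
            raise ValueError(f"assembly operator {self.op_id!r}: rotation is not proper orthonormal")


@dataclass
class StructureModel:
    """A parsed entry: chains, space group, deposited assembly operators, SEQRES."""

    entry_id: str
    chains: list[ChainModel] = field(default_factory=list)
    space_group: str = ""
    assembly_transforms: list[AssemblyTransform] = field(default_factory=list)
    seqres: dict[str, list[str]] = field(default_factory=dict)

    def get_chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def polymer_chains(self) -> list[ChainModel]:
        return [c for c in self.chains if c.is_polymer]

    def subset(self, chain_ids) -> "StructureModel":
        """A shallow model containing only the named chains."""
        chains = [self.get_chain(cid) for cid in chain_ids]
        return StructureModel(self.entry_id, chains, self.space_group, [], dict(self.seqres))


# ---------------------------------------------------------------------------
# reading

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip()
    if el and el != "X":
        return el
    # fall back to the leading alphabetic character of the atom name
    guess = next((ch for ch in atom.name if ch.isalpha()), "")
    warnings.warn(f"atom {atom.name!r}: unknown element, inferred {guess!r} from name")
    if not guess:
        raise StructureParseError(f"atom {atom.name!r}: element cannot be inferred")
    return guess.upper()


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties alphabetical."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        else:
            key = (-atom.occ, atom.altloc or "~")
            prev_key = (-prev.occ, prev.altloc or "~")
            if key < prev_key:
                by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path : str or Path
        Coordinate file.
    format : {"auto", "pdb", "mmcif"}
        Dialect; ``auto`` detects from content/extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected pdb/mmcif/auto") from None
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path.name}: no coordinate model found")
    st.setup_entities()

    model = st[0]
    chains: list[ChainModel] = []
    seqres: dict[str, list[str]] = {}
    for gchain in model:
        residues: list[ResidueSite] = []
        any_polymer = False
        for gres in gchain:
            polymer = gres.entity_type == gemmi.EntityType.Polymer
            any_polymer = any_polymer or polymer
            atoms: list[AtomSite] = []
            for gatom in _resolve_altlocs(gres):
                el = _element_of(gatom)
                if el in ("H", "D"):
                    continue
                atoms.append(
                    AtomSite(
                        name=gatom.name,
                        element=el,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        b_factor=gatom.b_iso,
                        alt_loc=(gatom.altloc or "").strip(),
                        is_hetero=not polymer,
                    )
                )
            if atoms:
                residues.append(ResidueSite(gres.name, gres.seqid.num, gres.seqid.icode.strip(), atoms))
        if not residues:
            continue
        residues.sort(key=lambda r: r.key)
        chains.append(ChainModel(gchain.name, residues, is_polymer=any_polymer))
        ent = st.get_entity_of(gchain.get_polymer())
        if ent is not None and ent.full_sequence:
            seqres[gchain.name] = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]

    transforms = _assembly_transforms(st, {c.chain_id for c in chains if c.is_polymer})
    return StructureModel(
        entry_id=(st.name or path.stem).upper(),
        chains=chains,
        space_group=st.spacegroup_hm or "",
        assembly_transforms=transforms,
        seqres=seqres,
    )


def _assembly_transforms(st: gemmi.Structure, polymer_ids: set[str]) -> list[AssemblyTransform]:
    """Operators of the deposited assembly; prefer the first tetramer-producing one."""
    candidates = []
    for asm in st.assemblies:
        ops: list[AssemblyTransform] = []
        n_chain_copies = 0
        for gen in asm.generators:
            chain_names = [n for n in gen.chains if n in polymer_ids]
            if not chain_names:
                # mmCIF generators may reference subchains instead of chains
                chain_names = sorted(polymer_ids)
            for i, op in enumerate(gen.operators):
                tr = op.transform
                rot = np.array(tr.mat.tolist(), dtype=float)
                vec = np.array(tr.vec.tolist(), dtype=float)
                ops.append(AssemblyTransform(rot, vec, chain_names, op_id=op.name or f"{asm.name}-{i + 1}"))
                n_chain_copies += len(chain_names)
        if ops:
            candidates.append((n_chain_copies, ops))
    if not candidates:
        return []
    for n, ops in candidates:
        if n == 4:
            return ops
    return candidates[0][1]


# ---------------------------------------------------------------------------
# assembly construction

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _fresh_chain_ids(n: int, taken: set[str]):
    out = []
    for cid in _CHAIN_IDS:
        if len(out) == n:
            break
        if cid not in taken:
            out.append(cid)
    while len(out) < n:  # beyond 62 copies: two-letter ids
        out.append(f"{_CHAIN_IDS[len(out) // 62]}{_CHAIN_IDS[len(out) % 62]}")
    return out


def build_assembly(model: StructureModel, transforms: list[AssemblyTransform] | None = None) -> StructureModel:
    """Apply assembly operators, producing one fresh chain per (operator x chain).

    Uses the model's deposited transforms when ``transforms`` is None. Every
    rotation must be a proper orthonormal matrix; coordinates map as
    ``x' = R x + t``.
    """
    if transforms is None:
        transforms = model.assembly_transforms
    if not transforms:
        raise ValueError(f"{model.entry_id}: no assembly transforms available")
    for tr in transforms:
        tr.validate()
        for cid in tr.apply_to:
            model.get_chain(cid)  # raises KeyError on missing chain

    n_new = sum(len(tr.apply_to) for tr in transforms)
    new_ids = iter(_fresh_chain_ids(n_new, set()))
    chains: list[ChainModel] = []
    seqres: dict[str, list[str]] = {}
    for tr in transforms:
        for cid in tr.apply_to:
            src = model.get_chain(cid)
            new = copy.deepcopy(src)
            new.chain_id = next(new_ids)
            for res in new.residues:
                for atom in res.atoms:
                    atom.coords = tr.rotation @ atom.coords + tr.translation
            chains.append(new)
            if cid in model.seqres:
                seqres[new.chain_id] = list(model.seqres[cid])
    return StructureModel(model.entry_id, chains, model.space_group, [], seqres)


# ---------------------------------------------------------------------------
# sequences

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

ONE_TO_THREE = {v: k for k, v in reversed(_THREE_TO_ONE.items())}


def three_to_one(resname: str) -> str:
    """Standard 3-letter -> 1-letter residue code; unknowns map to ``X``."""
    return _THREE_TO_ONE.get(resname.upper(), "X")


def extract_sequence(chain: ChainModel, source: str = "coords", seqres: list[str] | None = None) -> str:
    """One-letter sequence of a polymer chain.

    ``source="coords"`` reads the residues actually resolved in the
    coordinates; ``source="seqres"`` uses the deposited full sequence (pass
    the model's ``seqres[chain_id]`` list).
    """
    if not chain.is_polymer:
        raise ValueError(f"chain {chain.chain_id}: not a polymer")
    if source == "coords":
        residues = chain.polymer_residues()
        if not residues:
            raise ValueError(f"chain {chain.chain_id}: no resolved polymer residues")
        return "".join(three_to_one(r.name) for r in residues)
    if source == "seqres":
        if not seqres:
            raise ValueError(f"chain {chain.chain_id}: no SEQRES sequence supplied")
        return "".join(three_to_one(name) for name in seqres)
    raise ValueError(f"unknown sequence source {source!r}")


# ---------------------------------------------------------------------------
# atom selection helper used across modules

def collect_atoms(
    model_or_chain,
    polymer_only: bool = True,
    chains: list[str] | None = None,
) -> list[AtomSite]:
    """Flat atom list: by default heavy atoms of polymer residues only
    (waters/ligands excluded, matching the analysis conventions)."""
    if isinstance(model_or_chain, ChainModel):
        chain_list = [model_or_chain]
    else:
        chain_list = model_or_chain.chains
        if chains is not None:
            chain_list = [model_or_chain.get_chain(cid) for cid in chains]
    out: list[AtomSite] = []
    for chain in chain_list:
        if polymer_only and not chain.is_polymer:
            continue
        for res in chain.residues:
            for atom in res.atoms:
                if polymer_only and atom.is_hetero:
                    continue
                out.append(atom)
    return out


# ---------------------------------------------------------------------------
# writing

def write_pdb(model: StructureModel, path) -> None:
    """Write the ATOM/HETATM/TER/END subset of PDB format."""
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial % 100000:5d} {name:<4.4s}{atom.alt_loc or ' ':1.1s}"
                    f"{res.name:>3.3s} {chain.chain_id[:1]}{res.seq_id % 10000:4d}{res.icode or ' ':1.1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2.2s}"
                )
        serial += 1
        lines.append(f"TER   {serial % 100000:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
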