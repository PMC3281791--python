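"""Inventories of pairwise interactions: salt bridges, hydrogen bonds,
disulfide bridges and van der Waals contacts, each labeled intra- or
inter-chain.

All cutoffs are strict (``distance < cutoff``) and heavy-atom based; the
crystal structures this package targets carry no hydrogens, so hydrogen
bonds use a purely distance-based donor/acceptor criterion and histidine is
treated as basic regardless of protonation.

Detection precedence is disulfide > salt bridge > H-bond > vdW: an atom pair
contributes to at most one interaction kind.

Counting units: salt bridges and vdW contacts are counted per residue pair
(a bidentate salt bridge — two simultaneous acid/base atom pairs between the
same residues — still counts once, with the bidentate flag set); hydrogen
bonds are counted per qualifying atom pair; disulfides per SG-SG pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureModel, collect_atoms  # noqa: F401  (collect_atoms re-exported)

__all__ = [
    "Interaction",
    "InteractionSet",
    "CUTOFFS",
    "find_salt_bridges",
    "find_hbonds",
    "find_disulfides",
    "find_vdw_contacts",
    "find_all_interactions",
    "interactions_to_tsv",
]

CUTOFFS = {"salt_bridge": 3.5, "hbond": 3.5, "disulfide": 2.5, "vdw": 4.0}

_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
          ("HIS", "ND1"), ("HIS", "NE2")}


@dataclass
class Interaction:
    kind: str
    res1: tuple  # (chain_id, seq_id, resname)
    res2: tuple
    atoms: list[tuple[str, str, float]]  # (atom1, atom2, distance)
    span: str  # "intra" | "inter"
    bidentate: bool = False

    @property
    def min_distance(self) -> float:
        return min(d for _, _, d in self.atoms)


@dataclass
class InteractionSet:
    interactions: list[Interaction] = field(default_factory=list)

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        """(kind, span) -> count in that kind's counting unit."""
        out: dict[tuple[str, str], int] = {}
        for it in self.interactions:
            unit = len(it.atoms) if it.kind == "hbond" else 1
            out[(it.kind, it.span)] = out.get((it.kind, it.span), 0) + unit
        return out

    def count(self, kind: str, span: str | None = None) -> int:
        return sum(v for (k, s), v in self.counts.items() if k == kind and (span is None or s == span))

    @property
    def bidentate_count(self) -> int:
        return sum(1 for it in self.interactions if it.bidentate)

    def filter(self, kind: str | None = None, span: str | None = None) -> "InteractionSet":
        return InteractionSet([
            it for it in self.interactions
            if (kind is None or it.kind == kind) and (span is None or it.span == span)
        ])


# ---------------------------------------------------------------------------

class _AtomTable:
    """Flat arrays over the model's polymer heavy atoms."""

    def __init__(self, model: StructureModel):
        coords, element, name = [], [], []
        res_key, res_pos, chain_id = [], [], []
        self.res_info: list[tuple] = []  # residue index -> (chain_id, seq_id, resname)
        for chain in model.polymer_chains():
            residues = chain.polymer_residues()
            for pos, res in enumerate(residues):
                ridx = len(self.res_info)
                self.res_info.append((chain.chain_id, res.seq_id, res.name))
                for atom in res.atoms:
                    coords.append(atom.coords)
                    element.append(atom.element.upper())
                    name.append(atom.name)
                    res_key.append(ridx)
                    res_pos.append(pos)
                    chain_id.append(chain.chain_id)
        self.coords = np.asarray(coords, dtype=float).reshape(len(coords), 3)
        self.element = np.asarray(element, dtype=object)
        self.name = np.asarray(name, dtype=object)
        self.res_index = np.asarray(res_key, dtype=int)
        self.res_pos = np.asarray(res_pos, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype=object)
        # terminal atoms per chain: first residue's backbone N is a basic
        # candidate (free alpha-amino group), any OXT an acidic one
        self.is_nterm_n = np.zeros(len(coords), dtype=bool)
        for cid in set(chain_id):
            mask = self.chain_id == cid
            if not mask.any():
                continue
            first = self.res_pos[mask].min()
            self.is_nterm_n |= mask & (self.res_pos == first) & (self.name == "N")

    def resname(self, i: int) -> str:
        return self.res_info[self.res_index[i]][2]

    def __len__(self) -> int:
        return len(self.coords)


def _pairs_within(table: _AtomTable, idx1: np.ndarray, idx2: np.ndarray, cutoff: float):
    """Index pairs (strictly) under cutoff between two candidate subsets,
    deduplicated as unordered atom pairs from distinct residues."""
    if len(idx1) == 0 or len(idx2) == 0:
        return []
    tree = cKDTree(table.coords[idx2])
    seen = set()
    out = []
    for a_local, hits in enumerate(tree.query_ball_point(table.coords[idx1], r=cutoff)):
        i = int(idx1[a_local])
        for b_local in hits:
            j = int(idx2[b_local])
            if table.res_index[i] == table.res_index[j]:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            d = float(np.linalg.norm(table.coords[i] - table.coords[j]))
            if d < cutoff:
                seen.add(key)
                out.append((key[0], key[1], d))
    return out


def _span(table: _AtomTable, i: int, j: int) -> str:
    return "intra" if table.chain_id[i] == table.chain_id[j] else "inter"


def _peptide_neighbors(table: _AtomTable, i: int, j: int) -> bool:
    """Residues joined by a peptide bond: same chain, consecutive both in
    position and in author numbering."""
    if table.chain_id[i] != table.chain_id[j]:
        return False
    if abs(int(table.res_pos[i]) - int(table.res_pos[j])) != 1:
        return False
    s1 = table.res_info[table.res_index[i]][1]
    s2 = table.res_info[table.res_index[j]][1]
    return abs(s1 - s2) == 1


def _group_by_residue_pair(table: _AtomTable, atom_pairs, kind: str, bidentate_kind: bool = False):
    groups: dict[tuple[int, int], list] = {}
    for i, j, d in atom_pairs:
        r1, r2 = table.res_index[i], table.res_index[j]
        key = (min(r1, r2), max(r1, r2))
        groups.setdefault(key, []).append((i, j, d))
    out = []
    for (r1, r2), plist in sorted(groups.items()):
        i0, j0, _ = plist[0]
        atoms = [(table.name[i], table.name[j], d) for i, j, d in sorted(plist, key=lambda p: p[2])]
        out.append(Interaction(
            kind=kind,
            res1=table.res_info[r1],
            res2=table.res_info[r2],
            atoms=atoms,
            span=_span(table, i0, j0),
            bidentate=bidentate_kind and len(plist) >= 2,
        ))
    return out


def _detect(model: StructureModel, cutoffs: dict[str, float]) -> dict[str, list[Interaction]]:
    table = _AtomTable(model)
    result: dict[str, list[Interaction]] = {k: [] for k in CUTOFFS}
    if len(table) == 0:
        return result
    claimed_pairs: set[tuple[int, int]] = set()
    claimed_atoms: set[int] = set()

    # 1. disulfides: CYS SG - SG
    resnames = np.array([table.resname(i) for i in range(len(table))], dtype=object)
    sg = np.flatnonzero((table.name == "SG") & (resnames == "CYS"))
    ss_pairs = _pairs_within(table, sg, sg, cutoffs["disulfide"])
    for i, j, d in ss_pairs:
        claimed_pairs.add((i, j))
        claimed_atoms.update((i, j))
    result["disulfide"] = _group_by_residue_pair(table, ss_pairs, "disulfide")

    # 2. salt bridges: acidic carboxylate O (+ OXT) vs basic side-chain N (+ N-term N)
    pairs_rn = list(zip(resnames, table.name))
    acidic = np.flatnonzero(np.array(
        [(rn, nm) in _ACIDIC or nm == "OXT" for rn, nm in pairs_rn], dtype=bool))
    basic = np.flatnonzero(np.array(
        [(rn, nm) in _BASIC for rn, nm in pairs_rn], dtype=bool) | table.is_nterm_n)
    sb_pairs = [(i, j, d) for i, j, d in _pairs_within(table, acidic, basic, cutoffs["salt_bridge"])
                if (i, j) not in claimed_pairs]
    for i, j, d in sb_pairs:
        claimed_pairs.add((i, j))
        claimed_atoms.update((i, j))
    result["salt_bridge"] = _group_by_residue_pair(table, sb_pairs, "salt_bridge", bidentate_kind=True)

    # 3. hydrogen bonds: N/O/S heavy atoms, minus claimed pairs and the
    # covalent peptide neighborhood (sequential backbone C-N and its 1-3
    # partner O(i)...N(i+1), which sits at ~2.25 Å in every polypeptide)
    dons = np.flatnonzero(np.isin(table.element, ("N", "O", "S")))
    hb_pairs = []
    for i, j, d in _pairs_within(table, dons, dons, cutoffs["hbond"]):
        if (i, j) in claimed_pairs:
            continue
        if _peptide_neighbors(table, i, j):
            a, b = (i, j) if table.res_pos[i] < table.res_pos[j] else (j, i)
            if (table.name[a], table.name[b]) in (("C", "N"), ("O", "N")):
                continue
        hb_pairs.append((i, j, d))
    for i, j, d in hb_pairs:
        claimed_pairs.add((i, j))
        claimed_atoms.update((i, j))
    result["hbond"] = _group_by_residue_pair(table, hb_pairs, "hbond")

    # 4. vdW: apolar (C, S) heavy atoms not already assigned; covalent
    # neighbors (positionally consecutive residues in a chain) excluded
    apolar = np.flatnonzero(np.isin(table.element, ("C", "S")))
    apolar = apolar[~np.isin(apolar, list(claimed_atoms))]
    vdw_pairs = []
    for i, j, d in _pairs_within(table, apolar, apolar, cutoffs["vdw"]):
        if (i, j) in claimed_pairs:
            continue
        if _peptide_neighbors(table, i, j):
            continue
        vdw_pairs.append((i, j, d))
    result["vdw"] = _group_by_residue_pair(table, vdw_pairs, "vdw")
    return result


def _merged_cutoffs(overrides: dict[str, float] | None) -> dict[str, float]:
    c = dict(CUTOFFS)
    if overrides:
        unknown = set(overrides) - set(c)
        if unknown:
            raise ValueError(f"unknown interaction kinds: {sorted(unknown)}")
        c.update(overrides)
    return c


def find_all_interactions(model: StructureModel, cutoffs: dict[str, float] | None = None) -> InteractionSet:
    """Every interaction of every kind, with the precedence chain applied."""
    det = _detect(model, _merged_cutoffs(cutoffs))
    return InteractionSet(det["disulfide"] + det["salt_bridge"] + det["hbond"] + det["vdw"])


def find_salt_bridges(model: StructureModel, cutoff: float = 3.5) -> InteractionSet:
    """Residue pairs with >= 1 acidic-basic atom pair under the cutoff.

    Acidic atoms: Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT; basic: Lys NZ,
    Arg NE/NH1/NH2, His ND1/NE2, the N-terminal backbone N. Bidentate means
    >= 2 simultaneous atom pairs.
    """
    return InteractionSet(_detect(model, _merged_cutoffs({"salt_bridge": cutoff}))["salt_bridge"])


def find_hbonds(model: StructureModel, cutoff: float = 3.5) -> InteractionSet:
    """Distance-only hydrogen bonds between N/O/S heavy atoms of distinct,
    non-covalently-linked residues; atom pairs already assigned as salt
    bridges or disulfides are excluded."""
    return InteractionSet(_detect(model, _merged_cutoffs({"hbond": cutoff}))["hbond"])


def find_disulfides(model: StructureModel, cutoff: float = 2.5) -> InteractionSet:
    """Cys SG-SG pairs under the cutoff, labeled intra/inter by chain."""
    return InteractionSet(_detect(model, _merged_cutoffs({"disulfide": cutoff}))["disulfide"])


def find_vdw_contacts(model: StructureModel, cutoff: float = 4.0) -> InteractionSet:
    """Residue pairs with >= 1 apolar (C/S) heavy-atom pair under the cutoff,
    after removing atoms already assigned to a specific interaction."""
    return InteractionSet(_detect(model, _merged_cutoffs({"vdw": cutoff}))["vdw"])


def interactions_to_tsv(iset: InteractionSet) -> str:
    """TSV export: kind, chain1, res1, chain2, res2, min_distance, span, bidentate."""
    lines = ["kind\tchain1\tres1\tchain2\tres2\tmin_distance\tspan\tbidentate"]
    for it in iset.interactions:
        c1, s1, n1 = it.res1
        c2, s2, n2 = it.res2
        lines.append(
            f"{it.kind}\t{c1}\t{n1}{s1}\t{c2}\t{n2}{s2}\t{it.min_distance:.3f}\t{it.span}\t{int(it.bidentate)}"
        )
    return "\n".join(lines) + "\n"
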