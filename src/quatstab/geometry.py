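"""Rigid superposition, RMSD, residue correspondence and neighbor search.

The Kabsch least-squares superposition is written out explicitly (SVD with a
determinant correction so reflections are never returned); global sequence
alignment is delegated to Biopython's ``PairwiseAligner`` with the fixed
scoring used throughout this package (match +1, mismatch 0, gap open -5,
gap extend -1); fixed-radius neighbor search wraps a k-d tree but guarantees
the exact strict-inequality pair set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .structure_io import ChainModel, extract_sequence

__all__ = [
    "Correspondence",
    "SuperpositionResult",
    "kabsch_superpose",
    "chain_rmsd",
    "align_sequences",
    "neighbor_pairs",
]


@dataclass
class Correspondence:
    """Monotone residue pairing between two chains, with percent identity."""

    pairs: list[tuple[int, int]]
    identity_pct: float

    def __post_init__(self) -> None:
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i2 > i1 and j2 > j1):
                raise ValueError("correspondence must be strictly increasing in both chains")


@dataclass
class SuperpositionResult:
    """Optimal rigid motion (R, t) mapping the mobile set onto the reference, and its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int


def kabsch_superpose(coords1: np.ndarray, coords2: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``coords2`` (mobile) onto ``coords1`` (reference).

    Returns the proper rotation R and translation t minimising
    ``sum ||coords1_i - (R coords2_i + t)||^2`` and the resulting RMSD.
    Reflections are excluded by flipping the sign of the smallest singular
    direction when ``det < 0`` (standard Kabsch correction).
    """
    x1 = np.asarray(coords1, dtype=float)
    x2 = np.asarray(coords2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 2 or x1.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3 with equal N")
    n = x1.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    c1 = x1.mean(axis=0)
    c2 = x2.mean(axis=0)
    y1 = x1 - c1
    y2 = x2 - c2
    if np.linalg.matrix_rank(y1, tol=1e-8) < 2 or np.linalg.matrix_rank(y2, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")

    h = y2.T @ y1  # cross-covariance
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = c1 - rot @ c2
    moved = x2 @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((x1 - moved) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd, n_pairs=n)


# ---------------------------------------------------------------------------
# sequence alignment

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -1.0
    return a


def align_sequences(seq1: str, seq2: str) -> Correspondence:
    """Global alignment (match +1 / mismatch 0, affine gaps -5/-1).

    ``identity_pct`` is matches over aligned (both-residue) columns x 100.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align empty sequences")
    aln = _aligner().align(seq1, seq2)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for k in range(e1 - s1):
            i, j = s1 + k, s2 + k
            pairs.append((i, j))
            if seq1[i] == seq2[j]:
                matches += 1
    identity = 100.0 * matches / len(pairs) if pairs else 0.0
    return Correspondence(pairs=pairs, identity_pct=identity)


# ---------------------------------------------------------------------------
# chain superposition

def _auto_correspondence(chain1: ChainModel, chain2: ChainModel):
    """Residue pairing: author-numbering match when the constructs agree,
    else global sequence alignment on the resolved sequences."""
    res1 = chain1.polymer_residues()
    res2 = chain2.polymer_residues()
    by_key1 = {r.key: i for i, r in enumerate(res1)}
    by_key2 = {r.key: i for i, r in enumerate(res2)}
    shared = sorted(set(by_key1) & set(by_key2))
    same_names = shared and all(res1[by_key1[k]].name == res2[by_key2[k]].name for k in shared)
    if same_names:
        return [(by_key1[k], by_key2[k]) for k in shared]
    seq1 = extract_sequence(chain1, "coords")
    seq2 = extract_sequence(chain2, "coords")
    return align_sequences(seq1, seq2).pairs


def chain_rmsd(
    chain1: ChainModel,
    chain2: ChainModel,
    atom: str = "CA",
    corr="auto",
) -> SuperpositionResult:
    """RMSD between equivalent atoms (default C-alpha) of two chains after
    optimal superposition.

    ``corr`` is either ``"auto"`` (numbering match for identical constructs,
    sequence alignment otherwise) or an explicit :class:`Correspondence`.
    """
    res1 = chain1.polymer_residues()
    res2 = chain2.polymer_residues()
    pairs = _auto_correspondence(chain1, chain2) if corr == "auto" else corr.pairs
    p1, p2 = [], []
    for i, j in pairs:
        a1 = res1[i].get(atom)
        a2 = res2[j].get(atom)
        if a1 is not None and a2 is not None:
            p1.append(a1.coords)
            p2.append(a2.coords)
    if len(p1) < 3:
        raise ValueError(f"fewer than 3 matched {atom!r} atoms between chains "
                         f"{chain1.chain_id} and {chain2.chain_id}")
    return kabsch_superpose(np.array(p1), np.array(p2))


# ---------------------------------------------------------------------------
# neighbor search

def _coords_of(atoms) -> np.ndarray:
    if len(atoms) == 0:
        return np.zeros((0, 3))
    arr = np.asarray(atoms, dtype=object)
    if hasattr(atoms[0], "coords"):
        return np.array([a.coords for a in atoms], dtype=float)
    return np.asarray(atoms, dtype=float).reshape(len(atoms), 3)


def neighbor_pairs(atoms1, atoms2, cutoff: float) -> list[tuple[int, int, float]]:
    """All index pairs (i, j) with ``||x1_i - x2_j|| < cutoff`` (strict).

    Accepts :class:`AtomSite` lists or plain N x 3 coordinate arrays. When
    both inputs are the same point set, the search is a self-search: pairs
    are unordered (i < j) and self-pairs are excluded. The k-d tree is an
    implementation detail; the returned pair set is exactly the brute-force
    one.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    c1 = _coords_of(atoms1)
    c2 = _coords_of(atoms2)
    if len(c1) == 0 or len(c2) == 0:
        return []
    self_search = atoms1 is atoms2 or (c1.shape == c2.shape and np.array_equal(c1, c2))
    tree = cKDTree(c2)
    out: list[tuple[int, int, float]] = []
    for i, hits in enumerate(tree.query_ball_point(c1, r=cutoff)):
        for j in hits:
            if self_search and j <= i:
                continue
            d = float(np.linalg.norm(c1[i] - c2[j]))
            if d < cutoff:
                out.append((i, j, d))
    return out
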