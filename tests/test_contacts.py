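"""Salt-bridge, H-bond, disulfide and vdW contact detection."""

import numpy as np
import pytest

from quatstab import synthetic_data as syn
from quatstab.contacts import (
    find_all_interactions,
    find_disulfides,
    find_hbonds,
    find_salt_bridges,
    find_vdw_contacts,
    interactions_to_tsv,
)
from quatstab.structure_io import AtomSite, ChainModel, ResidueSite, StructureModel


def two_residue_model(res1, res2, chain2=None):
    """One chain with res1; res2 either same chain or a second chain."""
    if chain2:
        chains = [ChainModel("A", [res1], True), ChainModel("B", [res2], True)]
    else:
        chains = [ChainModel("A", [res1, res2], True)]
    return StructureModel("T", chains)


def residue(name, seq, atoms):
    return ResidueSite(name, seq, "", [AtomSite(n, el, np.array(xyz, float)) for n, el, xyz in atoms])


class TestSaltBridges:
    def test_single_pair_detected(self):
        asp = residue("ASP", 1, [("CA", "C", (0, 8, 0)), ("OD2", "O", (0, 0, 0))])
        lys = residue("LYS", 10, [("CA", "C", (3, -8, 0)), ("NZ", "N", (3.0, 0, 0))])
        iset = find_salt_bridges(two_residue_model(asp, lys))
        assert iset.count("salt_bridge") == 1
        assert not iset.interactions[0].bidentate

    def test_boundary_is_strict(self):
        asp = residue("ASP", 1, [("OD2", "O", (0, 0, 0))])
        lys = residue("LYS", 10, [("NZ", "N", (3.5, 0, 0))])
        assert find_salt_bridges(two_residue_model(asp, lys)).count("salt_bridge") == 0

    def test_bidentate_counted_once_with_flag(self):
        glu = residue("GLU", 1, [("OE1", "O", (0, 0, 0)), ("OE2", "O", (0, 2.2, 0))])
        arg = residue("ARG", 10, [("NH1", "N", (2.9, 0, 0)), ("NH2", "N", (2.9, 2.2, 0))])
        iset = find_salt_bridges(two_residue_model(glu, arg))
        assert iset.count("salt_bridge") == 1
        assert iset.bidentate_count == 1


class TestHbonds:
    def test_backbone_ladder_of_ideal_helix(self, helix15):
        model = StructureModel("HLX", [helix15])
        iset = find_hbonds(model)
        ladder = [
            (it, a)
            for it in iset.interactions
            for a in it.atoms
            if {a[0], a[1]} == {"O", "N"} and abs(it.res1[1] - it.res2[1]) == 4
        ]
        assert len(ladder) == 11  # O(i)...N(i+4) for i = 1..11

    def test_distance_boundary(self):
        r1 = residue("SER", 1, [("OG", "O", (0, 0, 0))])
        r2 = residue("SER", 10, [("OG", "O", (3.6, 0, 0))])
        assert find_hbonds(two_residue_model(r1, r2)).count("hbond") == 0
        r3 = residue("SER", 10, [("OG", "O", (2.9, 0, 0))])
        assert find_hbonds(two_residue_model(r1, r3)).count("hbond") == 1

    def test_peptide_neighbors_excluded(self):
        # O(i)-N(i+1) sits well under 3.5 A in any chain; it is covalent
        # bookkeeping, not a hydrogen bond
        r1 = residue("ALA", 1, [("C", "C", (0, 0, 0)), ("O", "O", (0.6, 1.0, 0))])
        r2 = residue("ALA", 2, [("N", "N", (1.33, 0, 0))])
        model = StructureModel("T", [ChainModel("A", [r1, r2], True)])
        assert find_hbonds(model).count("hbond") == 0


class TestDisulfides:
    def test_interchain_bond(self):
        c1 = residue("CYS", 196, [("SG", "S", (0, 0, 0))])
        c2 = residue("CYS", 233, [("SG", "S", (2.05, 0, 0))])
        iset = find_disulfides(two_residue_model(c1, c2, chain2=True))
        assert iset.count("disulfide", "inter") == 1

    def test_free_cysteines_not_bonded(self):
        c1 = residue("CYS", 1, [("SG", "S", (0, 0, 0))])
        c2 = residue("CYS", 9, [("SG", "S", (4.0, 0, 0))])
        assert find_disulfides(two_residue_model(c1, c2)).count("disulfide") == 0


class TestVdw:
    def test_apolar_pair(self):
        l1 = residue("LEU", 1, [("CD1", "C", (0, 0, 0))])
        l2 = residue("LEU", 10, [("CD1", "C", (3.8, 0, 0))])
        assert find_vdw_contacts(two_residue_model(l1, l2)).count("vdw") == 1
        l3 = residue("LEU", 10, [("CD1", "C", (4.6, 0, 0))])
        assert find_vdw_contacts(two_residue_model(l1, l3)).count("vdw") == 0

    def test_counted_per_residue_pair(self):
        l1 = residue("LEU", 1, [("CD1", "C", (0, 0, 0)), ("CD2", "C", (0, 1.5, 0))])
        l2 = residue("LEU", 10, [("CD1", "C", (3.5, 0, 0)), ("CD2", "C", (3.5, 1.5, 0))])
        assert find_vdw_contacts(two_residue_model(l1, l2)).count("vdw") == 1


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(50))
    def test_exact_recovery_over_seeds(self, seed):
        spec = syn.PlantSpec(3, 2, 1, 4, seed=seed)
        iset = find_all_interactions(syn.make_planted_complex(spec))
        counts = iset.counts
        assert counts.get(("salt_bridge", "inter"), 0) == 3
        assert counts.get(("hbond", "inter"), 0) == 2
        assert counts.get(("disulfide", "inter"), 0) == 1
        assert counts.get(("vdw", "inter"), 0) == 4
        # zero false positives of any kind anywhere
        assert sum(counts.values()) == 10

    def test_all_zero_spec_with_apolar_filler_gives_only_vdw(self):
        spec = syn.PlantSpec(0, 0, 0, 0, interface_apolar_fraction=0.5, seed=1)
        counts = find_all_interactions(syn.make_planted_complex(spec)).counts
        assert set(counts) == {("vdw", "inter")}
        assert counts[("vdw", "inter")] == 5


class TestInvariants:
    def test_atom_pairs_mutually_exclusive_across_kinds(self):
        m = syn.make_planted_complex(syn.PlantSpec(4, 3, 2, 5, seed=13))
        iset = find_all_interactions(m)
        seen = set()
        for it in iset.interactions:
            for a1, a2, _ in it.atoms:
                key = frozenset([(it.res1, a1), (it.res2, a2)])
                assert key not in seen
                seen.add(key)

    def test_counts_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        m = syn.make_planted_complex(syn.PlantSpec(2, 2, 1, 3, seed=21))
        before = find_all_interactions(m).counts
        rot = Rotation.from_euler("xyz", (25, 35, 45), degrees=True).as_matrix()
        for chain in m.chains:  # one global motion applied to the whole model
            for res in chain.residues:
                for a in res.atoms:
                    a.coords = rot @ a.coords + np.array([7.0, -3.0, 11.0])
        assert find_all_interactions(m).counts == before

    def test_counts_invariant_under_chain_order(self):
        m = syn.make_planted_complex(syn.PlantSpec(2, 1, 1, 2, seed=2))
        swapped = StructureModel(m.entry_id, list(reversed(m.chains)))
        assert find_all_interactions(swapped).counts == find_all_interactions(m).counts

    def test_intra_plus_inter_equals_total(self, helix15):
        m = syn.make_planted_complex(syn.PlantSpec(2, 2, 1, 2, seed=3))
        m.chains[0].residues.extend(
            syn.rigid_perturb(helix15, translation=(0, 80, 0)).residues[k] for k in range(15)
        )
        iset = find_all_interactions(m)
        for kind in ("salt_bridge", "hbond", "disulfide", "vdw"):
            assert iset.count(kind) == iset.count(kind, "intra") + iset.count(kind, "inter")


def test_tsv_export_lists_every_interaction():
    m = syn.make_planted_complex(syn.PlantSpec(1, 1, 1, 1, seed=0))
    iset = find_all_interactions(m)
    tsv = interactions_to_tsv(iset)
    lines = tsv.strip().split("\n")
    assert lines[0].startswith("kind\t")
    assert len(lines) == 1 + len(iset.interactions)
    assert any("disulfide" in ln for ln in lines[1:])
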