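"""Accessible-surface, grid-volume and cavity computations."""

import numpy as np
import pytest

from quatstab import synthetic_data as syn
from quatstab.structure_io import AtomSite, collect_atoms
from quatstab.surface_volume import (
    BONDI,
    RadiusSet,
    buried_surface_area,
    detect_cavities,
    grid_volume,
    shrake_rupley_sasa,
)


def atom(el, x, y, z, name="X1"):
    return AtomSite(name, el, np.array([x, y, z], dtype=float))


def random_cluster(n, box, seed, element="C"):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, box, size=(n, 3))
    return [atom(element, *p) for p in pts]


class TestSasa:
    def test_single_atom_closed_form(self):
        # sulfur: r = 1.8, probe 1.4 -> 4 pi (3.2)^2
        res = shrake_rupley_sasa([atom("S", 0, 0, 0)], probe=1.4, n_points=960)
        assert res.total_area == pytest.approx(4 * np.pi * 3.2**2, rel=1e-6)

    def test_fully_enclosed_atom_has_zero_area(self):
        shell = syn.make_sphere_body("hollow_shell", inner_radius=4.0, thickness=3.0, seed=0)
        atoms = collect_atoms(shell, polymer_only=False) + [atom("C", 0, 0, 0)]
        res = shrake_rupley_sasa(atoms, probe=1.4, n_points=240)
        assert res.per_atom_area[-1] == 0.0

    def test_total_equals_sum_of_per_atom(self):
        atoms = random_cluster(30, 12, seed=3)
        res = shrake_rupley_sasa(atoms, n_points=240)
        assert res.total_area == pytest.approx(res.per_atom_area.sum(), abs=1e-6)
        assert np.all(res.per_atom_area >= 0)
        assert np.all(res.per_atom_area <= 4 * np.pi * (1.7 + 1.4) ** 2 + 1e-9)

    def test_converges_to_high_resolution_reference(self):
        # independent check: same geometry at 10,000 points per atom
        atoms = random_cluster(20, 10, seed=1)
        coarse = shrake_rupley_sasa(atoms, n_points=960).total_area
        fine = shrake_rupley_sasa(atoms, n_points=10_000).total_area
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_matches_independent_implementation(self):
        # cross-check against biotite's Shrake-Rupley on identical radii
        struc = pytest.importorskip("biotite.structure")
        atoms = random_cluster(60, 16, seed=8)
        arr = struc.AtomArray(len(atoms))
        arr.coord = np.array([a.coords for a in atoms])
        arr.chain_id = np.full(len(atoms), "A")
        arr.res_id = np.arange(1, len(atoms) + 1)
        arr.res_name = np.full(len(atoms), "UNK")
        arr.atom_name = np.full(len(atoms), "C")
        arr.element = np.full(len(atoms), "C")
        ref = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                         vdw_radii=np.full(len(atoms), 1.7)).sum()
        mine = shrake_rupley_sasa(atoms, n_points=2000).total_area
        assert mine == pytest.approx(ref, rel=0.02)

    def test_distant_groups_are_exactly_additive(self):
        g1 = random_cluster(15, 8, seed=5)
        g2 = [atom(a.element, *(a.coords + np.array([50.0, 0, 0]))) for a in g1]
        s1 = shrake_rupley_sasa(g1, n_points=480).total_area
        s2 = shrake_rupley_sasa(g2, n_points=480).total_area
        s12 = shrake_rupley_sasa(g1 + g2, n_points=480).total_area
        assert s12 == pytest.approx(s1 + s2, abs=1e-9)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa([], n_points=960)
        with pytest.raises(ValueError):
            shrake_rupley_sasa([atom("C", 0, 0, 0)], n_points=0)


class TestBuriedSurfaceArea:
    def test_distant_chains_zero(self):
        g1 = random_cluster(10, 6, seed=2)
        g2 = [atom("C", *(a.coords + np.array([50.0, 0, 0]))) for a in g1]
        bsa, iface = buried_surface_area(g1, g2, n_points=240)
        assert bsa == pytest.approx(0.0, abs=1e-9)
        assert iface == pytest.approx(0.0, abs=1e-9)

    def test_compositional_oracle(self):
        # BSA must equal the three SASA evaluations composed by hand
        m = syn.make_planted_complex(syn.PlantSpec(2, 2, 0, 3, seed=9))
        g1 = collect_atoms(m.get_chain("A"))
        g2 = collect_atoms(m.get_chain("B"))
        bsa, iface = buried_surface_area(g1, g2, n_points=480)
        expected = (
            shrake_rupley_sasa(g1, n_points=480).total_area
            + shrake_rupley_sasa(g2, n_points=480).total_area
            - shrake_rupley_sasa(g1 + g2, n_points=480).total_area
        )
        assert bsa == pytest.approx(expected, abs=1e-9)
        assert iface == pytest.approx(bsa / 2, abs=1e-12)
        assert bsa > 0

    def test_monotone_decay_with_separation(self):
        m = syn.make_planted_complex(syn.PlantSpec(2, 2, 0, 3, seed=9))
        g1 = collect_atoms(m.get_chain("A"))
        base = collect_atoms(m.get_chain("B"))
        values = []
        for shift in (0.0, 2.0, 4.0, 8.0, 30.0):
            g2 = [atom(a.element, *(a.coords - np.array([0.0, shift, 0.0])), name=a.name)
                  for a in base]
            values.append(buried_surface_area(g1, g2, n_points=240)[0])
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_groups_rejected(self):
        g = random_cluster(5, 5, seed=1)
        with pytest.raises(ValueError):
            buried_surface_area(g, g[2:], n_points=120)


class TestGridVolume:
    def test_sphere_closed_form(self):
        rs = RadiusSet({"C": 2.0})
        v = grid_volume([atom("C", 0, 0, 0)], rs, spacing=0.5, probe=0.0)
        assert v.volume == pytest.approx(4 / 3 * np.pi * 8, rel=0.05)
        assert v.volume == v.occupied_cells * 0.5**3

    def test_disjoint_bodies_are_additive(self, solid_cluster):
        atoms = collect_atoms(solid_cluster, polymer_only=False)
        far = [atom(a.element, *(a.coords + np.array([100.0, 0, 0]))) for a in atoms]
        v1 = grid_volume(atoms, spacing=1.0).volume
        v2 = grid_volume(atoms + far, spacing=1.0).volume
        assert v2 == pytest.approx(2 * v1, abs=1e-9)

    def test_lattice_translation_invariance(self):
        atoms = random_cluster(25, 10, seed=4)
        moved = [atom(a.element, *(a.coords + np.array([7.0, -3.0, 2.0]))) for a in atoms]
        v0 = grid_volume(atoms, spacing=1.0)
        v1 = grid_volume(moved, spacing=1.0)
        assert v0.occupied_cells == v1.occupied_cells

    def test_refinement_converges(self):
        atoms = random_cluster(40, 9, seed=6)
        v = [grid_volume(atoms, spacing=s).volume for s in (2.0, 1.0, 0.5, 0.25)]
        diffs = [abs(a - b) for a, b in zip(v, v[1:])]
        assert diffs[1] <= diffs[0] and diffs[2] <= diffs[1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grid_volume([], spacing=1.0)


class TestCavities:
    def test_solid_cluster_has_none(self, solid_cluster):
        atoms = collect_atoms(solid_cluster, polymer_only=False)
        assert detect_cavities(atoms, spacing=1.0, probe=1.4) == []

    def test_hollow_shell_single_cavity_matches_fine_grid(self, hollow_shell):
        atoms = collect_atoms(hollow_shell, polymer_only=False)
        cavs = detect_cavities(atoms, spacing=1.0, probe=1.4)
        assert len(cavs) == 1
        fine = detect_cavities(atoms, spacing=0.25, probe=1.4)
        assert len(fine) == 1
        assert cavs[0].volume == pytest.approx(fine[0].volume, rel=0.10)
        # the probe-eroded interior ball: radius ~ inner_radius - probe
        assert fine[0].volume == pytest.approx(4 / 3 * np.pi * 4.6**3, rel=0.10)
        assert np.linalg.norm(cavs[0].centroid) < 1.0  # centered body

    def test_cavity_volume_consistency(self, hollow_shell):
        atoms = collect_atoms(hollow_shell, polymer_only=False)
        cav = detect_cavities(atoms, spacing=1.0, probe=1.4)[0]
        assert cav.volume == pytest.approx(cav.cell_count * 1.0**3)


def test_radius_set_validation():
    with pytest.raises(ValueError):
        RadiusSet({"C": -1.0})
    assert BONDI.of("c") == 1.70
    assert BONDI.of("ZZ") == BONDI.default
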