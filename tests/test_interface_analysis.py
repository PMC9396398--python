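import itertools

import numpy as np
import pytest

from ankgroove.interface_analysis import (
    buried_surface_area,
    compute_sasa,
    fibonacci_sphere,
    find_hydrogen_bonds,
    find_hydrophobic_contacts,
    _acceptor_atoms,
    _antecedent_atom,
    _donor_atoms,
)
from ankgroove.structure_io import Atom, Residue, Structure
from ankgroove.synthetic_data import (
    GeometryFixtureSpec,
    make_geometry_fixture,
    make_two_sphere_fixture,
)

from conftest import single_atom_structure


class TestFibonacciSphere:
    def test_unit_norm(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_deterministic(self):
        assert np.array_equal(fibonacci_sphere(256), fibonacci_sphere(256))

    def test_centroid_near_origin(self):
        assert np.linalg.norm(fibonacci_sphere(960).mean(axis=0)) < 0.01


class TestComputeSasa:
    def test_isolated_sphere_closed_form(self):
        structure = single_atom_structure(radius=1.9)
        result = compute_sasa(structure, probe_radius=1.4, n_points=960)
        expected = 4.0 * np.pi * 3.3**2  # ~136.85 A^2
        assert result.total == pytest.approx(expected, rel=1e-9)
        assert result.total == pytest.approx(136.85, abs=0.01)

    def test_two_distant_atoms_additive(self):
        fx = make_two_sphere_fixture(1.9, 1.7, 50.0)
        result = compute_sasa(fx.structure, n_points=960)
        iso1 = 4.0 * np.pi * (1.9 + 1.4) ** 2
        iso2 = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert result.total == pytest.approx(iso1 + iso2, rel=1e-9)

    def test_overlap_matches_analytic_cap_formula(self):
        fx = make_two_sphere_fixture(1.7, 1.55, 2.0)
        result = compute_sasa(fx.structure, n_points=960)
        assert result.total == pytest.approx(fx.analytic_total, rel=0.01)

    def test_per_atom_sums_to_total(self, hydrophobic_structure):
        result = compute_sasa(hydrophobic_structure, n_points=256)
        assert sum(result.per_atom.values()) == pytest.approx(result.total, rel=1e-6)
        assert sum(result.per_residue.values()) == pytest.approx(result.total, rel=1e-6)

    def test_all_areas_nonnegative(self, hydrophobic_structure):
        result = compute_sasa(hydrophobic_structure, n_points=256)
        assert all(v >= 0 for v in result.per_atom.values())

    def test_empty_selection_errors(self, hydrophobic_structure):
        with pytest.raises(ValueError, match="empty selection"):
            compute_sasa(hydrophobic_structure, selection=["Z"])

    def test_n_points_minimum(self, hydrophobic_structure):
        with pytest.raises(ValueError):
            compute_sasa(hydrophobic_structure, n_points=32)

    def test_monotonicity_adding_atom(self):
        """Adding an atom never increases any other atom's SASA."""
        rng = np.random.default_rng(42)
        coords = rng.uniform(-3, 3, size=(8, 3))
        def build(k):
            residues = [
                Residue(chain_id="A", number=i + 1, aa="X", resname="UNK",
                        atoms=[Atom(name="X1", element="C", coord=c, vdw_radius=1.7)])
                for i, c in enumerate(coords[:k])
            ]
            return Structure(id="cloud", chains={"A": residues})
        before = compute_sasa(build(7), n_points=960).per_atom
        after = compute_sasa(build(8), n_points=960).per_atom
        for key, area in before.items():
            assert after[key] <= area + 1e-9

    def test_convergence_960_vs_4000(self):
        fx = make_two_sphere_fixture(1.7, 1.55, 2.0)
        coarse = compute_sasa(fx.structure, n_points=960).total
        fine = compute_sasa(fx.structure, n_points=4000).total
        assert abs(fine - coarse) / fine < 0.01


class TestBuriedSurfaceArea:
    def test_far_apart_zero(self, far_apart_structure):
        report = buried_surface_area(far_apart_structure, ["A"], ["B"], n_points=256)
        assert report.bsa_total == 0.0

    def test_recomposition_oracle(self, hydrophobic_structure):
        """BSA equals the difference of independently composed SASA calls."""
        report = buried_surface_area(hydrophobic_structure, ["A"], ["B"], n_points=960)
        sasa_a = compute_sasa(hydrophobic_structure, n_points=960, selection=["A"]).total
        sasa_b = compute_sasa(hydrophobic_structure, n_points=960, selection=["B"]).total
        complex_sasa = compute_sasa(hydrophobic_structure, n_points=960)
        in_complex_a = sum(
            v for (key, _), v in complex_sasa.per_atom.items() if key[0] == "A")
        in_complex_b = complex_sasa.total - in_complex_a
        assert report.bsa_component_a == pytest.approx(sasa_a - in_complex_a, abs=1e-9)
        assert report.bsa_component_b == pytest.approx(sasa_b - in_complex_b, abs=1e-9)
        assert report.bsa_total > 0  # 4 A contact does bury area

    def test_symmetry(self, hydrophobic_structure):
        fwd = buried_surface_area(hydrophobic_structure, ["A"], ["B"], n_points=256)
        rev = buried_surface_area(hydrophobic_structure, ["B"], ["A"], n_points=256)
        assert fwd.bsa_component_a == pytest.approx(rev.bsa_component_b)
        assert fwd.bsa_component_b == pytest.approx(rev.bsa_component_a)
        assert fwd.bsa_total == pytest.approx(rev.bsa_total)

    def test_interface_area_is_half_total(self, hydrophobic_structure):
        report = buried_surface_area(hydrophobic_structure, ["A"], ["B"], n_points=256)
        assert report.interface_area == pytest.approx(report.bsa_total / 2)

    def test_overlapping_components_error(self, hydrophobic_structure):
        with pytest.raises(ValueError, match="overlap"):
            buried_surface_area(hydrophobic_structure, ["A"], ["A"])

    def test_empty_component_error(self, hydrophobic_structure):
        with pytest.raises(ValueError):
            buried_surface_area(hydrophobic_structure, [], ["B"])


class TestHydrogenBonds:
    def test_good_geometry_found(self, hbond_structure):
        bonds = find_hydrogen_bonds(hbond_structure, ["B"], ["A"])
        assert len(bonds) == 1
        (bond,) = bonds
        assert bond.distance == pytest.approx(2.9, abs=1e-6)
        assert bond.angle == pytest.approx(165.0, abs=0.1)
        assert bond.donor[1].name == "N"
        assert bond.acceptor[1].name == "O"

    def test_long_distance_rejected(self):
        structure = make_geometry_fixture(GeometryFixtureSpec("hbond", 4.2, 165.0))
        assert find_hydrogen_bonds(structure, ["B"], ["A"]) == []

    def test_bad_angle_rejected(self):
        structure = make_geometry_fixture(GeometryFixtureSpec("hbond", 2.9, 45.0))
        assert find_hydrogen_bonds(structure, ["B"], ["A"]) == []

    def test_both_directions_scanned(self, hbond_structure):
        # donor lives in B: must be found regardless of argument order
        assert len(find_hydrogen_bonds(hbond_structure, ["A"], ["B"])) == 1

    def test_custom_cutoffs(self):
        structure = make_geometry_fixture(GeometryFixtureSpec("hbond", 4.2, 165.0))
        assert len(find_hydrogen_bonds(structure, ["B"], ["A"], max_da_distance=4.5)) == 1

    def test_no_intra_component_pairs(self, hbond_structure):
        bonds = find_hydrogen_bonds(hbond_structure, ["B"], ["A"])
        for bond in bonds:
            assert bond.donor[0].chain_id != bond.acceptor[0].chain_id

    def test_agrees_with_brute_force(self):
        """Independent O(n^2) geometric scan over a multi-residue fixture."""
        structures = [
            make_geometry_fixture(GeometryFixtureSpec("hbond", d, a))
            for d, a in [(2.6, 170.0), (2.9, 165.0), (3.3, 100.0), (3.4, 92.0),
                         (3.6, 165.0), (2.9, 80.0)]
        ]
        # merge into one structure with many chains (< 200 atoms)
        chains = {}
        for i, s in enumerate(structures):
            offset = np.array([0.0, 0.0, 12.0 * i])
            for cid, residues in s.chains.items():
                new_id = f"{cid}{i}"
                moved = []
                for r in residues:
                    atoms = [Atom(name=a.name, element=a.element,
                                  coord=a.coord + offset, vdw_radius=a.vdw_radius,
                                  is_polar=a.is_polar) for a in r.atoms]
                    moved.append(Residue(chain_id=new_id, number=r.number + 10 * i,
                                         aa=r.aa, resname=r.resname, atoms=atoms))
                chains[new_id] = moved
        merged = Structure(id="merged", chains=chains)
        comp_a = [c for c in chains if c.startswith("B")]
        comp_b = [c for c in chains if c.startswith("A")]

        found = {(b.donor[0].key, b.donor[1].name, b.acceptor[0].key, b.acceptor[1].name)
                 for b in find_hydrogen_bonds(merged, comp_a, comp_b)}

        brute = set()
        res_a = [r for c in comp_a for r in merged.chains[c]]
        res_b = [r for c in comp_b for r in merged.chains[c]]
        for d_res, a_res in itertools.chain(
                itertools.product(res_a, res_b), itertools.product(res_b, res_a)):
            for d_atom in _donor_atoms(d_res):
                for a_atom in _acceptor_atoms(a_res):
                    dist = np.linalg.norm(d_atom.coord - a_atom.coord)
                    if dist > 3.5:
                        continue
                    ante = _antecedent_atom(d_res, d_atom)
                    if ante is not None:
                        v1 = ante.coord - d_atom.coord
                        v2 = a_atom.coord - d_atom.coord
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 90.0:
                            continue
                    brute.add((d_res.key, d_atom.name, a_res.key, a_atom.name))
        assert found == brute
        assert len(found) == 4  # 2.6/170, 2.9/165, 3.3/100, 3.4/92 qualify


class TestHydrophobicContacts:
    def test_close_leucines(self, hydrophobic_structure):
        contacts = find_hydrophobic_contacts(hydrophobic_structure, ["A"], ["B"])
        assert len(contacts) == 1
        (contact,) = contacts
        assert contact.min_heavy_atom_distance == pytest.approx(4.0, abs=1e-6)
        assert contact.n_atom_pairs >= 1

    def test_distant_leucines_empty(self):
        structure = make_geometry_fixture(GeometryFixtureSpec("hydrophobic", 8.0))
        assert find_hydrophobic_contacts(structure, ["A"], ["B"]) == []

    def test_no_hbonds_in_hydrophobic_fixture(self, hydrophobic_structure):
        assert find_hydrogen_bonds(hydrophobic_structure, ["A"], ["B"]) == []

    def test_custom_cutoff(self):
        structure = make_geometry_fixture(GeometryFixtureSpec("hydrophobic", 8.0))
        contacts = find_hydrophobic_contacts(structure, ["A"], ["B"], cutoff=9.0)
        assert len(contacts) == 1
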