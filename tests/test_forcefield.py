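import itertools

import numpy as np
import pytest

from ballcore.build import build_peptide
from ballcore.forcefield import (AmberForceField, ForceFieldError,
                                 ForceFieldParameters, assign_types_and_charges,
                                 build_interactions, compute_energy,
                                 compute_gradient, set_movable_from_selection)
from ballcore.model import Atom, MolecularSystem, Residue
from ballcore.selection import apply_selection

from conftest import make_water


def ethane_like():
    """CH3-CH3 graph with arbitrary (sane) geometry, typed by hand."""
    system = MolecularSystem()
    mol = system.add_molecule()
    c1 = mol.add_atom(Atom("C1", "C", (0.0, 0.0, 0.0)))
    c2 = mol.add_atom(Atom("C2", "C", (1.526, 0.0, 0.0)))
    hs = []
    offsets = [(-0.5, 1.0, 0.0), (-0.5, -0.5, 0.9), (-0.5, -0.5, -0.9)]
    for i, (dx, dy, dz) in enumerate(offsets):
        hs.append(mol.add_atom(Atom(f"H1{i}", "H", (dx, dy, dz))))
    for i, (dx, dy, dz) in enumerate(offsets):
        hs.append(mol.add_atom(Atom(f"H2{i}", "H", (1.526 - dx, -dy, -dz))))
    for a in (c1, c2):
        a.type_name = "CT"
        a.partial_charge = -0.3
    for h in hs:
        h.type_name = "HC"
        h.partial_charge = 0.1
    system.add_bond(c1, c2)
    for h in hs[:3]:
        system.add_bond(c1, h)
    for h in hs[3:]:
        system.add_bond(c2, h)
    return system


def brute_force_counts(system):
    """Oracle: enumerate bonded tuples directly from the bond graph."""
    atoms = list(system.atoms())
    index = {id(a): i for i, a in enumerate(atoms)}
    adj = {i: set() for i in range(len(atoms))}
    for b in system.bonds():
        i, j = index[id(b.atom_a)], index[id(b.atom_b)]
        adj[i].add(j)
        adj[j].add(i)
    stretches = sum(len(v) for v in adj.values()) // 2
    bends = sum(len(v) * (len(v) - 1) // 2 for v in adj.values())
    torsions = set()
    for j in adj:
        for k in adj[j]:
            for i in adj[j] - {k}:
                for l in adj[k] - {j, i}:
                    torsions.add((i, j, k, l) if (i, j, k, l) <= (l, k, j, i)
                                 else (l, k, j, i))
    return stretches, bends, len(torsions)


class TestAssignTypes:
    def test_dipeptide_fully_typed_and_neutral(self, db):
        system = build_peptide("AA", (-57.0, -47.0), db=db)
        for a in system.atoms():
            a.type_name = None
            a.partial_charge = 0.0
        assign_types_and_charges(system, db)
        assert all(a.type_name for a in system.atoms())
        assert sum(a.partial_charge for a in system.atoms()) == pytest.approx(0.0, abs=1e-6)

    def test_water_charges(self, db, water):
        assign_types_and_charges(water, db)
        charges = sorted(a.partial_charge for a in water.atoms())
        assert charges == pytest.approx([-0.834, 0.417, 0.417])
        assert sum(charges) == pytest.approx(0.0, abs=1e-9)

    def test_stray_atom_error_names_it(self, db):
        system = build_peptide("AA", (-57.0, -47.0), db=db)
        system.chains[0].residues[0].add_atom(Atom("ZQ", "C", (40, 40, 40)))
        with pytest.raises(ForceFieldError, match="ZQ"):
            assign_types_and_charges(system, db)


class TestInteractionLists:
    def test_ethane_counts(self, params):
        system = ethane_like()
        lists = build_interactions(system, params)
        assert brute_force_counts(system) == (7, 12, 9)
        assert (len(lists.stretches), len(lists.bends),
                len(lists.torsions)) == (7, 12, 9)

    def test_water_counts(self, water, db, params):
        assign_types_and_charges(water, db)
        lists = build_interactions(water, params)
        assert len(lists.stretches) == 2
        assert len(lists.bends) == 1
        assert len(lists.torsions) == 0
        assert len(lists.nonbonded_full) == 0
        assert len(lists.nonbonded_14) == 0

    def test_butane_one_four_is_scaled(self, params):
        system = MolecularSystem()
        mol = system.add_molecule()
        atoms = [mol.add_atom(Atom(f"C{i}", "C", (1.5 * i, 0.2 * (i % 2), 0.0)))
                 for i in range(4)]
        for a in atoms:
            a.type_name = "CT"
        for i in range(3):
            system.add_bond(atoms[i], atoms[i + 1])
        lists = build_interactions(system, params)
        scaled = {tuple(sorted(p)) for p in map(tuple, lists.nonbonded_14)}
        full = {tuple(sorted(p)) for p in map(tuple, lists.nonbonded_full)}
        assert (0, 3) in scaled
        assert (0, 3) not in full
        assert full == set()

    def test_exclusions_partition(self, db, params):
        system = build_peptide("AG", (-57.0, -47.0), db=db)
        lists = build_interactions(system, params)
        full = {frozenset(map(int, p)) for p in lists.nonbonded_full}
        scaled = {frozenset(map(int, p)) for p in lists.nonbonded_14}
        assert full & scaled == set()
        assert all(p not in lists.excluded for p in full | scaled)

    def test_missing_parameter_names_types(self, params):
        system = MolecularSystem()
        mol = system.add_molecule()
        a = mol.add_atom(Atom("O1", "O", (0, 0, 0)))
        b = mol.add_atom(Atom("O2", "O", (1.2, 0, 0)))
        a.type_name = "O"
        b.type_name = "O"
        system.add_bond(a, b)
        with pytest.raises(ForceFieldError, match="O-O"):
            build_interactions(system, params)

    def test_deterministic(self, db, params):
        system = build_peptide("AG", (-57.0, -47.0), db=db)
        l1 = build_interactions(system, params)
        l2 = build_interactions(system, params)
        assert np.array_equal(l1.stretches, l2.stretches)
        assert np.array_equal(l1.torsions, l2.torsions)
        assert np.array_equal(l1.nonbonded_full, l2.nonbonded_full)


def two_atom_system(t1, t2, r, q1=0.0, q2=0.0, bonded=True):
    system = MolecularSystem()
    mol = system.add_molecule()
    elem = {"CT": "C", "HC": "H", "O2": "O", "N3": "N"}
    a = mol.add_atom(Atom("A1", elem.get(t1, "C"), (0.0, 0.0, 0.0)))
    b = mol.add_atom(Atom("A2", elem.get(t2, "C"), (r, 0.0, 0.0)))
    a.type_name, b.type_name = t1, t2
    a.partial_charge, b.partial_charge = q1, q2
    if bonded:
        system.add_bond(a, b)
    return system


class TestEnergyFormulas:
    def test_single_stretch(self, params):
        # k = 310, r0 = 1.526, r = 1.626 -> E = 310 * 0.1^2 = 3.10
        system = two_atom_system("CT", "CT", 1.626)
        lists = build_interactions(system, params)
        report = compute_energy(system, lists, params)
        assert report.stretch == pytest.approx(3.10, abs=1e-9)
        assert report.total == pytest.approx(3.10, abs=1e-9)

    def test_unit_charges_coulomb(self, params):
        system = two_atom_system("CT", "CT", 1.0, q1=1.0, q2=-1.0, bonded=False)
        params2 = ForceFieldParameters.from_file()
        params2.cutoff = 0.0
        lists = build_interactions(system, params2)
        # suppress vdW so the electrostatic constant stands alone
        lists.eps_i[:] = 0.0
        report = compute_energy(system, lists, params2)
        assert report.electrostatic == pytest.approx(-332.0637, abs=1e-9)

    def test_vdw_minimum_is_minus_epsilon(self, params):
        eps, rmin2, _ = params.types["CT"]
        system = two_atom_system("CT", "CT", 2 * rmin2, bonded=False)
        lists = build_interactions(system, params)
        report = compute_energy(system, lists, params)
        assert report.vdw == pytest.approx(-eps, abs=1e-12)

    def test_torsion_zero_at_antiphase(self, params):
        # V2 term: at n*phi - gamma = 180 the contribution is 0
        system = ethane_like()
        lists = build_interactions(system, params)
        lists.torsion_params = [[(2.0, 2, np.pi)] for _ in lists.torsion_params]
        from ballcore.forcefield import _torsion_geometry
        coords = np.array([a.position for a in system.atoms()])
        phi = _torsion_geometry(coords, lists.torsions)[0]
        # energy = sum 2.0*(1 + cos(2 phi - pi)); verify against direct formula
        report = compute_energy(system, lists, params)
        expected = float(np.sum(2.0 * (1.0 + np.cos(2 * phi - np.pi))))
        assert report.torsion == pytest.approx(expected, abs=1e-9)

    def test_per_term_sum_equals_total(self, db, params):
        system = build_peptide("AGS", (-57.0, -47.0), db=db)
        lists = build_interactions(system, params)
        report = compute_energy(system, lists, params)
        assert report.total == pytest.approx(
            report.stretch + report.bend + report.torsion + report.vdw
            + report.electrostatic, abs=1e-9)

    def test_cutoff_zeroes_far_pairs(self, params):
        system = two_atom_system("CT", "CT", 20.0, q1=0.5, q2=-0.5, bonded=False)
        lists = build_interactions(system, params)
        report = compute_energy(system, lists, params)  # cutoff 12 A
        assert report.total == 0.0
        params2 = ForceFieldParameters.from_file()
        params2.cutoff = 0.0
        report2 = compute_energy(system, lists, params2)
        assert report2.electrostatic != 0.0

    def test_singular_distance_raises(self, params):
        system = two_atom_system("CT", "CT", 1e-9, bonded=False)
        lists = build_interactions(system, params)
        with pytest.raises(ForceFieldError, match="singular"):
            compute_energy(system, lists, params)


class TestGradient:
    def test_zero_at_template_geometry(self, params):
        k, r0 = params.stretch_for("CT", "CT")
        system = two_atom_system("CT", "CT", r0)
        lists = build_interactions(system, params)
        grad = compute_gradient(system, lists, params)
        assert np.abs(grad).max() < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_finite_difference_oracle(self, seed, db, params):
        rng = np.random.default_rng(seed)
        sequences = ["AG", "SA", "GC", "AV"]
        system = build_peptide(sequences[seed], (-57.0, -47.0), db=db)
        ff = AmberForceField(db=db, params=params).setup(system, assign=False)
        coords = np.array([a.position for a in ff.lists.atoms])
        coords += rng.normal(scale=0.02, size=coords.shape)
        grad = ff.gradient(coords)
        h = 1e-5
        scale = max(1.0, np.abs(grad).max())
        for i in rng.choice(len(coords), size=6, replace=False):
            for k in range(3):
                cp, cm = coords.copy(), coords.copy()
                cp[i, k] += h
                cm[i, k] -= h
                fd = (ff.energy(cp).total - ff.energy(cm).total) / (2 * h)
                assert abs(grad[i, k] - fd) / scale < 1e-6

    def test_translation_invariance(self, db, params):
        system = build_peptide("AG", (-57.0, -47.0), db=db)
        ff = AmberForceField(db=db, params=params).setup(system, assign=False)
        coords = np.array([a.position for a in ff.lists.atoms])
        g1 = ff.gradient(coords)
        g2 = ff.gradient(coords + np.array([3.7, -1.2, 9.9]))
        assert np.allclose(g1, g2, atol=1e-9)

    def test_net_force_zero(self, db, params):
        system = build_peptide("AGS", (-57.0, -47.0), db=db)
        ff = AmberForceField(db=db).setup(system, assign=False)
        ff.params.cutoff = 0.0
        grad = ff.gradient()
        assert np.abs(grad.sum(axis=0)).max() < 1e-8

    def test_rigid_motion_energy_invariance(self, db):
        from ballcore.geometry import rotation_about_axis
        system = build_peptide("AGK", (-57.0, -47.0), db=db)
        ff = AmberForceField(db=db).setup(system, assign=False)
        ff.params.cutoff = 0.0
        coords = np.array([a.position for a in ff.lists.atoms])
        e0 = ff.energy(coords).total
        rng = np.random.default_rng(5)
        for _ in range(5):
            rot = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
            moved = coords @ rot.T + rng.normal(size=3)
            assert ff.energy(moved).total == pytest.approx(e0, abs=1e-8)

    def test_doubling_doubles_bonded_energy(self, db, params):
        system = build_peptide("AG", (-57.0, -47.0), db=db)
        e1 = AmberForceField(db=db).setup(system, assign=False).energy()
        double = build_peptide("AG", (-57.0, -47.0), db=db)
        far_chain = build_peptide("AG", (-57.0, -47.0), db=db).chains[0]
        for res in far_chain.residues:
            for a in res.atoms:
                a.position = a.position + np.array([0.0, 0.0, 100.0])
        double.chains.append(far_chain)
        e2 = AmberForceField(db=db).setup(double, assign=False).energy()
        assert e2.stretch == pytest.approx(2 * e1.stretch, abs=1e-9)
        assert e2.bend == pytest.approx(2 * e1.bend, abs=1e-9)
        assert e2.torsion == pytest.approx(2 * e1.torsion, abs=1e-9)

    def test_directional_derivative_consistency(self, db):
        system = build_peptide("SA", (-57.0, -47.0), db=db)
        ff = AmberForceField(db=db).setup(system, assign=False)
        coords = np.array([a.position for a in ff.lists.atoms])
        rng = np.random.default_rng(17)
        for _ in range(5):
            d = rng.normal(size=coords.shape)
            d /= np.linalg.norm(d)
            h = 1e-5
            fd = (ff.energy(coords + h * d).total
                  - ff.energy(coords - h * d).total) / (2 * h)
            analytic = float(np.sum(ff.gradient(coords) * d))
            assert fd == pytest.approx(analytic, rel=1e-5, abs=1e-7)


class TestMovableMask:
    def test_empty_selection_means_all(self, db):
        system = build_peptide("AG", (-57.0, -47.0), db=db)
        system.deselect()
        assert set_movable_from_selection(system).all()

    def test_selection_masks(self, db):
        system = build_peptide("AG", (-57.0, -47.0), db=db)
        apply_selection(system, "element(H)")
        mask = set_movable_from_selection(system)
        atoms = list(system.atoms())
        for a, m in zip(atoms, mask):
            assert m == (a.element == "H")

    def test_all_selected_equals_none_selected(self, db):
        from ballcore.optimize import MinimizerOptions, minimize_conjugate_gradient
        results = []
        for select_all in (False, True):
            system = build_peptide("AG", (-57.0, -47.0), db=db)
            system.deselect()
            if select_all:
                apply_selection(system, "all")
            ff = AmberForceField(db=db).setup(system, assign=False)
            res = minimize_conjugate_gradient(
                system, ff, MinimizerOptions(max_iterations=25))
            results.append((res.final_energy, system.coordinates()))
        assert results[0][0] == pytest.approx(results[1][0], abs=1e-12)
        assert np.array_equal(results[0][1], results[1][1])
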