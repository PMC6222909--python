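"""Energy terms: closed-form values, invariances, gradients, decomposition."""

import math

import numpy as np
import pytest

import bookend as bk
from bookend.constants import COULOMB_K
from bookend.energy import (
    FULLY_INTERACTING,
    AlchemicalState,
    AtomOverlapError,
    NonbondedSettings,
    bookend_delta_u,
    decompose_energy,
    energy_and_gradient,
    recenter,
    sampling_settings,
)
from bookend.systems import (
    Atom,
    AtomType,
    Frame,
    ParameterSet,
    SurrogatePerturbation,
    SystemModel,
    Topology,
    ValidationError,
)

GAS = NonbondedSettings()


def pair_model(eps=1.0, rmin_half=None, q=(0.0, 0.0), groups=("solute", "solvent"),
               box_edge=None, exclude=False):
    """Two-atom nonbonded test system."""
    if rmin_half is None:
        rmin_half = 2 ** (1 / 6) / 2  # sigma = 1 A per atom pair
    t1 = AtomType("A", 1.0, q[0], eps, rmin_half)
    t2 = AtomType("B", 1.0, q[1], eps, rmin_half)
    excl = frozenset({(0, 1)}) if exclude else frozenset()
    topo = Topology([Atom(0, "A", groups[0]), Atom(1, "B", groups[1])], [], [], excl)
    return SystemModel(topo, ParameterSet({"A": t1, "B": t2}), box_edge=box_edge)


def frame_at(r):
    return Frame(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


class TestBonded:
    def test_zero_at_equilibrium(self):
        spec = bk.SoluteSpec("d", charges=[0, 0], bonds=[(0, 1)], bond_k=300.0, bond_b0=1.2)
        m = bk.build_solute(spec, seed=0)
        f = Frame(np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]]))
        assert bk.bonded_energy(m, f) == pytest.approx(0.0, abs=1e-12)

    def test_no_half_prefactor_convention(self):
        # K (b - b0)^2 with K=300 and a 0.1 A stretch gives exactly 3.0
        spec = bk.SoluteSpec("d", charges=[0, 0], bonds=[(0, 1)], bond_k=300.0, bond_b0=1.2)
        m = bk.build_solute(spec, seed=0)
        f = Frame(np.array([[0.0, 0.0, 0.0], [1.3, 0.0, 0.0]]))
        assert bk.bonded_energy(m, f) == pytest.approx(3.0, abs=1e-12)

    def test_rotation_invariance(self, charged_chain):
        f = charged_chain.initial_frame.copy()
        e0 = bk.total_energy(charged_chain, f, FULLY_INTERACTING, GAS)
        theta = 0.83
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        g = f.copy()
        g.coordinates = f.coordinates @ rot.T + np.array([3.0, -2.0, 0.7])
        assert bk.total_energy(charged_chain, g, FULLY_INTERACTING, GAS) == pytest.approx(
            e0, abs=1e-9
        )

    def test_missing_parameter_names_types(self):
        t = AtomType("A", 1, 0, 0.1, 1.0)
        topo = Topology(
            [Atom(0, "A", "solute"), Atom(1, "A", "solute")],
            [(0, 1)],
            [],
            frozenset({(0, 1)}),
        )
        with pytest.raises((KeyError, ValidationError), match="A"):
            SystemModel(topo, ParameterSet({"A": t}, {}, {}))


class TestLennardJones:
    def test_well_depth_at_rmin(self):
        m = pair_model(eps=0.2, rmin_half=1.0)
        assert bk.lj_energy(m, frame_at(2.0), GAS) == pytest.approx(-0.2, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        m = pair_model(eps=0.3, rmin_half=1.0)
        s = NonbondedSettings(r_on=3.0, r_off=4.0)
        assert bk.lj_energy(m, frame_at(4.0), s) == 0.0
        assert bk.lj_energy(m, frame_at(5.5), s) == 0.0

    def test_switch_continuous_at_endpoints(self):
        m = pair_model(eps=0.3, rmin_half=1.0)
        s = NonbondedSettings(r_on=3.0, r_off=4.0)
        for r in (3.0, 4.0):
            below = bk.lj_energy(m, frame_at(r - 1e-7), s)
            above = bk.lj_energy(m, frame_at(r + 1e-7), s)
            assert below == pytest.approx(above, abs=1e-5)
        # S = 1 inside r_on: switched equals unswitched
        assert bk.lj_energy(m, frame_at(2.5), s) == pytest.approx(
            bk.lj_energy(m, frame_at(2.5), GAS), abs=1e-12
        )

    def test_overlap_raises(self):
        m = pair_model(eps=0.2)
        with pytest.raises(AtomOverlapError):
            bk.lj_energy(m, frame_at(1e-9), GAS)


class TestSoftcore:
    def test_lambda_zero_equals_plain_lj(self):
        m = pair_model(eps=0.45, rmin_half=1.3)
        for r in (1.8, 2.6, 4.0):
            assert bk.softcore_lj_energy(
                m, frame_at(r), AlchemicalState(1.0, 0.0), GAS
            ) == pytest.approx(bk.lj_energy(m, frame_at(r), GAS), abs=1e-12)

    def test_lambda_one_is_zero_everywhere(self):
        m = pair_model(eps=0.45)
        for r in (0.0, 0.5, 2.0):
            assert bk.softcore_lj_energy(m, frame_at(r), AlchemicalState(1.0, 1.0), GAS) == 0.0

    def test_closed_form_at_origin(self):
        # u = sigma^2/(delta*lambda*sigma^2) = 4; U = 0.5*4*(4096-64) = 8064
        m = pair_model(eps=1.0)
        e = bk.softcore_lj_energy(
            m, frame_at(0.0), AlchemicalState(1.0, 0.5), NonbondedSettings(softcore_delta=0.5)
        )
        assert e == pytest.approx(8064.0, rel=1e-12)

    def test_continuous_in_lambda(self):
        m = pair_model(eps=1.0)
        f = frame_at(1.1)
        grid = np.linspace(0.0, 1.0, 10001)
        vals = [bk.softcore_lj_energy(m, f, AlchemicalState(1.0, l), GAS) for l in grid]
        assert np.abs(np.diff(vals)).max() < 1e-3

    def test_invalid_delta(self):
        with pytest.raises(ValidationError):
            NonbondedSettings(softcore_delta=0.0)

    def test_protocol_constraint(self):
        with pytest.raises(ValidationError, match="lambda_vdw"):
            AlchemicalState(0.5, 0.5)


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        m = pair_model(eps=0.0, rmin_half=1.0, q=(1.0, -1.0), groups=("solute", "solute"))
        assert bk.coulomb_energy(m, frame_at(1.0)) == pytest.approx(-COULOMB_K, abs=1e-12)

    def test_charges_off_kills_solute_solvent_elec(self, solvated):
        f = solvated.initial_frame
        s = sampling_settings(solvated)
        bd = decompose_energy(solvated, f, AlchemicalState(1.0, 0.0), s)
        assert bd.solute_solvent_elec == 0.0
        assert bd.solute_solute == pytest.approx(
            decompose_energy(solvated, f, FULLY_INTERACTING, s).solute_solvent_vdw * 0.0
            + bd.solute_solute
        )

    def test_periodic_image_overlap_detected(self):
        m = pair_model(eps=0.0, rmin_half=1.0, q=(0.5, 0.5), box_edge=6.0)
        f = frame_at(6.0)  # separated by exactly one box edge -> image distance 0
        with pytest.raises(AtomOverlapError):
            bk.coulomb_energy(m, f, FULLY_INTERACTING, NonbondedSettings(use_min_image=True))

    def test_excluded_pair_contributes_nothing(self):
        m = pair_model(eps=0.0, rmin_half=1.0, q=(1.0, -1.0), exclude=True)
        assert bk.coulomb_energy(m, frame_at(1.0)) == 0.0

    def test_minimum_image_wraps_distance(self):
        m = pair_model(eps=0.0, rmin_half=1.0, q=(1.0, -1.0),
                       groups=("solute", "solute"), box_edge=10.0)
        s = NonbondedSettings(use_min_image=True)
        assert bk.coulomb_energy(m, frame_at(9.0), FULLY_INTERACTING, s) == pytest.approx(
            -COULOMB_K / 1.0, abs=1e-9
        )


class TestDrudeRelax:
    def isolated_site(self, alpha=2.5e-3, kd=1000.0):
        t = AtomType("P", 16.0, 0.0, 0.0, 1.0, alpha, kd)
        topo = Topology([Atom(0, "P", "solute")], [], [], frozenset())
        m = SystemModel(topo, ParameterSet({"P": t}))
        return m, Frame(np.zeros((1, 3)), np.zeros((1, 3)))

    def test_linear_response_in_uniform_field(self):
        m, f = self.isolated_site()
        t = m.atom_type(0)
        E = np.array([0.3, -0.2, 0.5])
        relaxed, _ = bk.drude_relax(m, f, external_field=E, settings=GAS)
        d = relaxed.drude_displacements[0]
        np.testing.assert_allclose(d, t.drude_charge * E / t.drude_spring, atol=1e-8)
        np.testing.assert_allclose(t.drude_charge * d, t.polarizability * E, atol=1e-8)

    def test_zero_field_zero_displacement(self):
        m, f = self.isolated_site()
        relaxed, e = bk.drude_relax(m, f, settings=GAS)
        assert np.abs(relaxed.drude_displacements).max() < 1e-12
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_variational_bound(self, polar_box):
        f = polar_box.initial_frame
        e_zero = bk.total_energy(polar_box, f)
        _, e_rel = bk.drude_relax(polar_box, f)
        assert e_rel <= e_zero

    def test_radius_restriction_freezes_distant_sites(self, polar_box):
        # no solute atoms in a pure box -> nothing within any radius: all frozen
        relaxed, _ = bk.drude_relax(polar_box, polar_box.initial_frame, radius=3.0)
        assert np.abs(relaxed.drude_displacements).max() == 0.0

    def test_polarization_catastrophe_detected(self):
        # soft spring two polarizable sites very close: diverges
        t = AtomType("P", 16.0, 0.4, 0.0, 1.0, polarizability=0.5, drude_spring=5.0)
        topo = Topology([Atom(0, "P", "solute"), Atom(1, "P", "solute")], [], [], frozenset())
        m = SystemModel(topo, ParameterSet({"P": t}))
        f = Frame(np.array([[0.0, 0.0, 0.0], [0.8, 0.0, 0.0]]), np.zeros((2, 3)))
        from bookend.energy import PolarizationCatastropheError

        with pytest.raises((PolarizationCatastropheError, AtomOverlapError)):
            bk.drude_relax(m, f, settings=GAS, max_iter=2000)


class TestGradients:
    def test_gas_finite_difference_agreement(self, charged_chain):
        rng = np.random.default_rng(2)
        h = 1e-6
        for _ in range(50):
            f = charged_chain.initial_frame.copy()
            f.coordinates = f.coordinates + rng.normal(scale=0.12, size=f.coordinates.shape)
            _, g, _ = energy_and_gradient(charged_chain, f, FULLY_INTERACTING, GAS)
            num = np.zeros_like(g)
            for i in range(f.coordinates.shape[0]):
                for k in range(3):
                    fp, fm = f.copy(), f.copy()
                    fp.coordinates[i, k] += h
                    fm.coordinates[i, k] -= h
                    num[i, k] = (
                        bk.total_energy(charged_chain, fp, FULLY_INTERACTING, GAS)
                        - bk.total_energy(charged_chain, fm, FULLY_INTERACTING, GAS)
                    ) / (2 * h)
            scale = max(1.0, np.abs(num).max())
            assert np.abs(g - num).max() / scale < 1e-6

    def test_periodic_switched_finite_difference(self, small_box):
        f = small_box.initial_frame
        s = sampling_settings(small_box)
        _, g, _ = energy_and_gradient(small_box, f, FULLY_INTERACTING, s)
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(12):
            i = int(rng.integers(small_box.n_atoms))
            k = int(rng.integers(3))
            fp, fm = f.copy(), f.copy()
            fp.coordinates[i, k] += h
            fm.coordinates[i, k] -= h
            num = (
                bk.total_energy(small_box, fp, FULLY_INTERACTING, s)
                - bk.total_energy(small_box, fm, FULLY_INTERACTING, s)
            ) / (2 * h)
            assert g[i, k] == pytest.approx(num, rel=1e-5, abs=1e-6)


class TestDecomposition:
    def test_components_sum_to_total(self, solvated):
        f = solvated.initial_frame
        s = sampling_settings(solvated)
        bd = decompose_energy(solvated, f, FULLY_INTERACTING, s)
        total = bk.total_energy(solvated, f, FULLY_INTERACTING, s)
        assert bd.total == pytest.approx(total, abs=1e-9)

    def test_bookend_delta_u_self_is_zero(self, solvated):
        assert bookend_delta_u(solvated, solvated, solvated.initial_frame) == 0.0

    def test_solvent_only_perturbation_invisible(self, solvated):
        # level B differs from A only in solvent-solvent interactions
        import copy

        from bookend.systems import AtomType as AT

        model_b = copy.deepcopy(solvated)
        types = dict(model_b.parameters.atom_types)
        sv = types["SVO"]
        types["SVO"] = AT("SVO", sv.mass, sv.charge, sv.lj_epsilon * 2.0,
                          sv.lj_rmin_half, sv.polarizability, sv.drude_spring)
        model_b.parameters.atom_types = types
        # solvent LJ changed -> solute-solvent vdW also changes, but the
        # bookend dU uses only solute-solute + bonded + solute-solvent elec
        assert bookend_delta_u(solvated, model_b, solvated.initial_frame) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_mismatched_topologies_rejected(self, solvated, triatomic):
        with pytest.raises(ValidationError, match="topolog"):
            bookend_delta_u(solvated, triatomic, solvated.initial_frame)

    def test_bookend_delta_u_sees_solute_perturbation(self, triatomic):
        target = bk.make_surrogate_target(triatomic, SurrogatePerturbation(bond_shifts=0.2))
        du = bookend_delta_u(triatomic, target, triatomic.initial_frame)
        assert du != pytest.approx(0.0, abs=1e-6)


class TestRecenter:
    def test_solute_centroid_at_box_center(self, solvated):
        f = solvated.initial_frame.copy()
        f.coordinates = f.coordinates + 2.7
        out = recenter(f, solvated)
        sol = [a.index for a in solvated.topology.atoms if a.group == "solute"]
        centroid = out.coordinates[sol].mean(axis=0)
        np.testing.assert_allclose(centroid, np.full(3, solvated.box_edge / 2), atol=1e-9)

    def test_energy_invariant(self, solvated):
        f = solvated.initial_frame.copy()
        f.coordinates = f.coordinates + np.array([3.3, -1.2, 0.4])
        s = sampling_settings(solvated)
        e0 = bk.total_energy(solvated, f, FULLY_INTERACTING, s)
        e1 = bk.total_energy(solvated, recenter(f, solvated), FULLY_INTERACTING, s)
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_idempotent(self, solvated):
        once = recenter(solvated.initial_frame, solvated)
        twice = recenter(once, solvated)
        np.testing.assert_allclose(once.coordinates, twice.coordinates, atol=1e-12)

    def test_gas_phase_returned_unchanged(self, triatomic):
        f = triatomic.initial_frame
        assert recenter(f, triatomic) is f
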