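"""Shared fixtures: small deterministic toy systems."""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import bookend as bk

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture
def triatomic():
    """Water-like bent triatomic gas-phase solute (3 atoms, 2 bonds, 1 angle)."""
    return bk.build_solute(bk.bent_triatomic_spec(), seed=11)


@pytest.fixture
def charged_chain():
    """5-atom charged chain with LJ + Coulomb intramolecular pairs."""
    spec = bk.linear_chain_spec(
        5, charges=[0.3, -0.2, 0.1, -0.1, -0.1], lj_epsilon=0.15, lj_rmin_half=1.9
    )
    return bk.build_solute(spec, seed=5)


@pytest.fixture
def small_box():
    """8 fixed-charge solvent molecules in a 9 A periodic box."""
    return bk.build_solvent_box(8, 9.0, "fixed3site", seed=3)


@pytest.fixture
def polar_box():
    """8 polarizable solvent molecules in a 9 A periodic box."""
    return bk.build_solvent_box(8, 9.0, "polarizable4site", seed=3)


@pytest.fixture
def solvated(small_box):
    """Triatomic solute merged into the small box (solute replaces the
    centermost solvent molecule)."""
    return merge_solute_into_box(bk.bent_triatomic_spec(), small_box, seed=7)


def merge_solute_into_box(spec, box, seed=0):
    """Build a solvated model: solute atoms first, then the box's solvent
    molecules except the one closest to the box center."""
    from bookend.systems import Atom, ParameterSet, SystemModel, Topology, Frame

    solute = bk.build_solute(spec, seed=seed)
    ns = solute.n_atoms
    edge = box.box_edge
    coords_box = box.initial_frame.coordinates
    n_mol = box.n_atoms // 3
    centers = coords_box.reshape(n_mol, 3, 3).mean(axis=1)
    drop = int(np.argmin(np.abs(centers - edge / 2).sum(axis=1)))
    keep = [m for m in range(n_mol) if m != drop]

    atoms = [Atom(i, a.type_name, "solute") for i, a in enumerate(solute.topology.atoms)]
    bonds = list(solute.topology.bonds)
    angles = list(solute.topology.angles)
    coords = [solute.initial_frame.coordinates + centers[drop]]
    for mi, m in enumerate(keep):
        base = ns + 3 * mi
        o, h1, h2 = base, base + 1, base + 2
        for k, idx in enumerate((o, h1, h2)):
            src = box.topology.atoms[3 * m + k]
            atoms.append(Atom(idx, src.type_name, "solvent"))
        bonds += [(o, h1), (o, h2)]
        angles.append((h1, o, h2))
        coords.append(coords_box[3 * m : 3 * m + 3])
    topo = Topology(atoms, bonds, angles, Topology.auto_exclusions(bonds, angles))
    params = ParameterSet(
        {**solute.parameters.atom_types, **box.parameters.atom_types},
        {**solute.parameters.bond_params, **box.parameters.bond_params},
        {**solute.parameters.angle_params, **box.parameters.angle_params},
    )
    model = SystemModel(topo, params, level="MM", box_edge=edge)
    x = np.vstack(coords)
    n_pol = len(model.polarizable_indices())
    model.initial_frame = Frame(x, np.zeros((n_pol, 3)) if n_pol else None)
    model.metadata = {"builder": "merge_solute_into_box", "seed": seed}
    return model
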