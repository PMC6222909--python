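"""Domain types and builders for toy molecular systems.

This module defines the in-memory model family used throughout the package:
atom types (optionally Drude-polarizable), topologies with a solute/solvent
partition, bonded parameter sets, and ``SystemModel`` objects tagged with a
Hamiltonian level (MM, MM', or TARGET).  It also provides the synthetic
generators: toy gas-phase solutes, jittered-lattice solvent boxes, and
surrogate high-level target Hamiltonians that play the role a quantum
method would play at full scale (shifted equilibrium geometries, rescaled
charges, optional Morse anharmonicity).

All builders are pure functions of (spec, seed): identical inputs give
bit-identical outputs.

Full-scale reference conditions (recorded as metadata only; the toy
builders operate at desk scale): 1687 water molecules in a cubic cell of
edge 36.85-36.89 Angstrom, 300 K, 5 ns aqueous production with frames
every 1000 steps at 1 fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import LEVEL_MM, LEVEL_TARGET, VALID_LEVELS

__all__ = [
    "AtomType",
    "Atom",
    "Topology",
    "BondParam",
    "AngleParam",
    "ParameterSet",
    "SystemModel",
    "Frame",
    "SoluteSpec",
    "SurrogatePerturbation",
    "ValidationError",
    "PackingError",
    "build_solute",
    "build_solvent_box",
    "make_surrogate_target",
    "bent_triatomic_spec",
    "linear_chain_spec",
    "FULL_SCALE_CONDITIONS",
]

GROUP_SOLUTE = "solute"
GROUP_SOLVENT = "solvent"

#: Conditions of the full-scale study these toys stand in for (metadata only).
FULL_SCALE_CONDITIONS = {
    "n_water": 1687,
    "box_edge_range_A": (36.85, 36.89),
    "temperature_K": 300.0,
    "lj_switch_A": (10.0, 12.0),
    "aqueous_production_ns": 5.0,
    "gas_production_ns": 500.0,
    "swap_interval_steps": 20000,
    "n_repeats": 4,
}


class ValidationError(ValueError):
    """A spec or model violates one of its stated invariants."""


class PackingError(RuntimeError):
    """Solvent molecules cannot be placed without steric overlap."""


@dataclass(frozen=True)
class AtomType:
    """A nonbonded atom type.

    Parameters
    ----------
    name : str
        Short unique type name.
    mass : float
        Mass in amu.
    charge : float
        Partial charge in elementary charges (total charge of the site;
        for polarizable types this is split between core and Drude
        particle at evaluation time).
    lj_epsilon : float
        Lennard-Jones well depth, kcal/mol (>= 0).
    lj_rmin_half : float
        Half the LJ minimum-energy distance, Angstrom.
    polarizability : float
        Mechanical polarizability alpha in e^2*A^2/(kcal/mol); 0 for
        non-polarizable types.  The Drude charge follows as
        q_D = -sqrt(alpha * drude_spring), so alpha = q_D^2 / k_D and the
        induced dipole under a field E (kcal/mol/A/e) is alpha*E.
    drude_spring : float
        Drude spring constant k_D in kcal/mol/A^2 (self-energy
        (1/2) k_D d^2); unused when polarizability is 0.
    """

    name: str
    mass: float
    charge: float
    lj_epsilon: float
    lj_rmin_half: float
    polarizability: float = 0.0
    drude_spring: float = 0.0

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValidationError(f"atom type {self.name!r}: lj_epsilon must be >= 0")
        if self.lj_epsilon > 0 and self.lj_rmin_half <= 0:
            raise ValidationError(
                f"atom type {self.name!r}: lj_rmin_half must be > 0 when lj_epsilon > 0"
            )
        if self.polarizability < 0:
            raise ValidationError(f"atom type {self.name!r}: polarizability must be >= 0")
        if self.polarizability > 0 and self.drude_spring <= 0:
            raise ValidationError(
                f"atom type {self.name!r}: drude_spring must be > 0 when polarizable"
            )

    @property
    def is_polarizable(self) -> bool:
        return self.polarizability > 0

    @property
    def drude_charge(self) -> float:
        """Charge on the Drude particle, q_D = -sqrt(alpha * k_D)."""
        if not self.is_polarizable:
            return 0.0
        return -math.sqrt(self.polarizability * self.drude_spring)


@dataclass(frozen=True)
class Atom:
    """One atom in a topology: 0-based id, type name, and group tag."""

    index: int
    type_name: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in (GROUP_SOLUTE, GROUP_SOLVENT):
            raise ValidationError(
                f"atom {self.index}: group must be 'solute' or 'solvent', got {self.group!r}"
            )


def _norm_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(eq=False)
class Topology:
    """Atoms, bonds, angles, and nonbonded exclusions.

    Atom ids are 0-based and contiguous internally; the text file layer is
    1-based.  All 1-2 and 1-3 pairs must appear in ``exclusions``.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    exclusions: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        ids = [a.index for a in self.atoms]
        if ids != list(range(n)):
            raise ValidationError("atom ids must be unique, contiguous and 0-based")
        for b in self.bonds:
            if not all(0 <= i < n for i in b):
                raise ValidationError(f"bond {b} references an invalid atom id")
        for a in self.angles:
            if not all(0 <= i < n for i in a):
                raise ValidationError(f"angle {a} references an invalid atom id")
        for i, j in self.bonds:
            if _norm_pair(i, j) not in self.exclusions:
                raise ValidationError(f"1-2 pair {(i, j)} missing from exclusions")
        for i, _, k in self.angles:
            if _norm_pair(i, k) not in self.exclusions:
                raise ValidationError(f"1-3 pair {(i, k)} missing from exclusions")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.group == group], dtype=int)

    @staticmethod
    def auto_exclusions(
        bonds: Sequence[tuple[int, int]], angles: Sequence[tuple[int, int, int]]
    ) -> frozenset[tuple[int, int]]:
        """All 1-2 and 1-3 pairs implied by the bonded lists."""
        excl = {_norm_pair(i, j) for i, j in bonds}
        excl |= {_norm_pair(i, k) for i, _, k in angles}
        return frozenset(excl)


@dataclass(frozen=True)
class BondParam:
    """Harmonic (or Morse) bond parameters: U = k_b (b - b0)^2, or
    U = D (1 - exp(-a (b - b0)))^2 with a = sqrt(k_b / D) when
    ``morse_depth`` D is set (curvature at the minimum matches the
    harmonic form)."""

    k_b: float
    b0: float
    morse_depth: float | None = None

    def __post_init__(self) -> None:
        if self.k_b <= 0:
            raise ValidationError("bond k_b must be > 0")
        if self.b0 <= 0:
            raise ValidationError("bond b0 must be > 0")
        if self.morse_depth is not None and self.morse_depth <= 0:
            raise ValidationError("morse well depth must be > 0")


@dataclass(frozen=True)
class AngleParam:
    """Harmonic angle parameters: U = k_theta (theta - theta0)^2."""

    k_theta: float
    theta0: float

    def __post_init__(self) -> None:
        if self.k_theta <= 0:
            raise ValidationError("angle k_theta must be > 0")
        if not 0.0 < self.theta0 < math.pi:
            raise ValidationError("theta0 must lie in (0, pi)")


@dataclass(eq=False)
class ParameterSet:
    """Type-keyed force-field parameters.

    Bond parameters are keyed by unordered type-name pairs, angle
    parameters by type-name triples symmetric under reversal.
    """

    atom_types: dict[str, AtomType]
    bond_params: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angle_params: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)

    def bond_param(self, t1: str, t2: str) -> BondParam:
        for key in ((t1, t2), (t2, t1)):
            if key in self.bond_params:
                return self.bond_params[key]
        raise KeyError(f"no bond parameters for type pair ({t1}, {t2})")

    def angle_param(self, t1: str, t2: str, t3: str) -> AngleParam:
        for key in ((t1, t2, t3), (t3, t2, t1)):
            if key in self.angle_params:
                return self.angle_params[key]
        raise KeyError(f"no angle parameters for type triple ({t1}, {t2}, {t3})")


@dataclass(eq=False)
class SystemModel:
    """A topology + parameter set tagged with its Hamiltonian level.

    ``box_edge`` (Angstrom) is None for gas-phase systems.  Builders attach
    an ``initial_frame`` with the generated coordinates.
    """

    topology: Topology
    parameters: ParameterSet
    level: str = LEVEL_MM
    box_edge: float | None = None
    initial_frame: "Frame | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise ValidationError(f"level must be one of {VALID_LEVELS}, got {self.level!r}")
        for atom in self.topology.atoms:
            if atom.type_name not in self.parameters.atom_types:
                raise ValidationError(f"atom {atom.index} has unknown type {atom.type_name!r}")
        # every bond/angle must resolve to exactly one parameter entry
        for i, j in self.topology.bonds:
            self.parameters.bond_param(self._tname(i), self._tname(j))
        for i, j, k in self.topology.angles:
            self.parameters.angle_param(self._tname(i), self._tname(j), self._tname(k))

    def _tname(self, i: int) -> str:
        return self.topology.atoms[i].type_name

    def atom_type(self, i: int) -> AtomType:
        return self.parameters.atom_types[self._tname(i)]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def is_periodic(self) -> bool:
        return self.box_edge is not None

    def polarizable_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.topology.atoms if self.atom_type(a.index).is_polarizable],
            dtype=int,
        )


@dataclass
class Frame:
    """One configuration: atomic coordinates plus per-polarizable-atom
    Drude displacements (aligned with ``model.polarizable_indices()``)."""

    coordinates: np.ndarray
    drude_displacements: np.ndarray | None = None
    replica_index: int = 0
    step: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError("coordinates must have shape (n_atoms, 3)")
        if self.drude_displacements is not None:
            self.drude_displacements = np.asarray(self.drude_displacements, dtype=float)
            if not np.all(np.isfinite(self.drude_displacements)):
                raise ValidationError("drude displacements must be finite")

    def copy(self) -> "Frame":
        return Frame(
            self.coordinates.copy(),
            None if self.drude_displacements is None else self.drude_displacements.copy(),
            self.replica_index,
            self.step,
        )

    def validate_against(self, model: SystemModel) -> None:
        if self.coordinates.shape[0] != model.n_atoms:
            raise ValidationError(
                f"frame has {self.coordinates.shape[0]} atoms, model has {model.n_atoms}"
            )
        n_pol = len(model.polarizable_indices())
        if n_pol and (
            self.drude_displacements is None or self.drude_displacements.shape[0] != n_pol
        ):
            raise ValidationError(
                f"model has {n_pol} polarizable sites; frame drude_displacements mismatch"
            )


def _zero_drude(model: SystemModel) -> np.ndarray | None:
    n_pol = len(model.polarizable_indices())
    return np.zeros((n_pol, 3)) if n_pol else None


# ---------------------------------------------------------------------------
# Toy solute builder
# ---------------------------------------------------------------------------


@dataclass
class SoluteSpec:
    """Specification of a toy gas-phase solute.

    Connectivity must form a tree (acyclic, connected); angles are derived
    automatically from every pair of bonds sharing a central atom.  Per-atom
    lists must all match ``n_atoms``; per-bond/per-angle parameter lists
    match the bond list and the derived angle list.
    """

    name: str
    charges: Sequence[float]
    masses: Sequence[float] | None = None
    lj_epsilon: Sequence[float] | None = None
    lj_rmin_half: Sequence[float] | None = None
    polarizabilities: Sequence[float] | None = None
    drude_springs: Sequence[float] | None = None
    bonds: Sequence[tuple[int, int]] = ()
    bond_k: Sequence[float] | float = 300.0
    bond_b0: Sequence[float] | float = 1.2
    angle_k: Sequence[float] | float = 50.0
    angle_theta0: Sequence[float] | float = math.radians(109.5)

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


def _broadcast(value, n: int, what: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    out = [float(v) for v in value]
    if len(out) != n:
        raise ValidationError(f"{what}: expected {n} entries, got {len(out)}")
    return out


def derive_angles(bonds: Sequence[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All (i, j, k) triples with bonds (i, j) and (j, k), i < k."""
    neighbors: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    angles = []
    for j in sorted(neighbors):
        nb = sorted(neighbors[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    return angles


def _check_tree(n: int, bonds: Sequence[tuple[int, int]]) -> None:
    if n == 1 and not bonds:
        return
    if len(bonds) != n - 1:
        raise ValidationError(
            f"bonds: toy solutes must be trees ({n} atoms need {n - 1} bonds, got {len(bonds)})"
        )
    seen = {0}
    edges = [tuple(b) for b in bonds]
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            if (i in seen) != (j in seen):
                seen.update((i, j))
                changed = True
    if len(seen) != n:
        raise ValidationError("bonds: connectivity is not a single connected tree")


def _embed_tree(
    bonds: Sequence[tuple[int, int]],
    angles: Sequence[tuple[int, int, int]],
    b0: Sequence[float],
    theta0: Sequence[float],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Deterministic planar embedding of a tree at its equilibrium internal
    coordinates, with a tiny seeded jitter to break exact symmetry."""
    b0_of = {_norm_pair(i, j): b for (i, j), b in zip(bonds, b0)}
    theta_of = {}
    for (i, j, k), t in zip(angles, theta0):
        theta_of[(i, j, k)] = t
        theta_of[(k, j, i)] = t
    coords = np.full((n, 3), np.nan)
    coords[0] = 0.0
    placed = [0]
    neighbors: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    # BFS placement: child direction rotated from the parent-grandparent axis
    queue = [0]
    parent = {0: None}
    while queue:
        j = queue.pop(0)
        k_sign = 1.0
        for child in sorted(neighbors[j]):
            if child in parent:
                continue
            parent[child] = j
            blen = b0_of[_norm_pair(j, child)]
            gp = parent[j]
            if gp is None:
                direction = np.array([1.0, 0.0, 0.0])
                if len(placed) > 1:  # additional children of the root fan out
                    ang = theta_of.get((placed[1], j, child), math.radians(109.5))
                    direction = np.array([math.cos(ang), math.sin(ang), 0.0])
            else:
                ang = theta_of.get((gp, j, child), math.radians(109.5))
                axis = coords[j] - coords[gp]
                axis /= np.linalg.norm(axis)
                perp = np.array([-axis[1], axis[0], 0.0])
                if np.linalg.norm(perp) < 1e-8:
                    perp = np.array([1.0, 0.0, 0.0])
                perp /= np.linalg.norm(perp)
                direction = math.cos(math.pi - ang) * axis + k_sign * math.sin(math.pi - ang) * perp
                k_sign = -k_sign  # alternate sides for siblings
            coords[child] = coords[j] + blen * direction
            placed.append(child)
            queue.append(child)
    coords += rng.uniform(-1e-3, 1e-3, size=coords.shape)
    return coords


def build_solute(spec: SoluteSpec, seed: int = 0) -> SystemModel:
    """Build a gas-phase MM-level toy solute from a spec.

    Every atom receives its own type named ``{spec.name}{i+1}``; angles and
    1-2/1-3 exclusions are derived from the bond list.  Deterministic for a
    fixed seed.
    """
    n = spec.n_atoms
    if n < 1:
        raise ValidationError("charges: at least one atom required")
    charges = _broadcast(spec.charges, n, "charges")
    masses = _broadcast(spec.masses if spec.masses is not None else 12.0, n, "masses")
    eps = _broadcast(spec.lj_epsilon if spec.lj_epsilon is not None else 0.1, n, "lj_epsilon")
    rmh = _broadcast(
        spec.lj_rmin_half if spec.lj_rmin_half is not None else 1.8, n, "lj_rmin_half"
    )
    alphas = _broadcast(
        spec.polarizabilities if spec.polarizabilities is not None else 0.0,
        n,
        "polarizabilities",
    )
    springs = _broadcast(
        spec.drude_springs if spec.drude_springs is not None else 1000.0, n, "drude_springs"
    )
    bonds = [tuple(int(x) for x in b) for b in spec.bonds]
    for i, j in bonds:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValidationError(f"bonds: invalid bond ({i}, {j}) for {n} atoms")
    _check_tree(n, bonds)
    angles = derive_angles(bonds)
    bond_k = _broadcast(spec.bond_k, len(bonds), "bond_k")
    bond_b0 = _broadcast(spec.bond_b0, len(bonds), "bond_b0")
    angle_k = _broadcast(spec.angle_k, len(angles), "angle_k")
    angle_t0 = _broadcast(spec.angle_theta0, len(angles), "angle_theta0")

    atom_types = {}
    atoms = []
    tnames = []
    for i in range(n):
        tname = f"{spec.name}{i + 1}"
        atom_types[tname] = AtomType(
            tname, masses[i], charges[i], eps[i], rmh[i], alphas[i],
            springs[i] if alphas[i] > 0 else 0.0,
        )
        atoms.append(Atom(i, tname, GROUP_SOLUTE))
        tnames.append(tname)
    bond_params = {
        (tnames[i], tnames[j]): BondParam(k, b)
        for (i, j), k, b in zip(bonds, bond_k, bond_b0)
    }
    angle_params = {
        (tnames[i], tnames[j], tnames[k]): AngleParam(kk, t0)
        for (i, j, k), kk, t0 in zip(angles, angle_k, angle_t0)
    }
    topo = Topology(atoms, bonds, angles, Topology.auto_exclusions(bonds, angles))
    params = ParameterSet(atom_types, bond_params, angle_params)
    model = SystemModel(topo, params, level=LEVEL_MM, box_edge=None)
    rng = np.random.default_rng(seed)
    coords = _embed_tree(bonds, angles, bond_b0, angle_t0, n, rng)
    model.initial_frame = Frame(coords, _zero_drude(model))
    model.metadata = {"builder": "build_solute", "spec_name": spec.name, "seed": seed}
    return model


def bent_triatomic_spec(
    name: str = "sol",
    charges: Sequence[float] = (-0.8, 0.4, 0.4),
    b0: float = 0.9572,
    theta0: float = math.radians(104.52),
    bond_k: float = 450.0,
    angle_k: float = 55.0,
    **kwargs,
) -> SoluteSpec:
    """A water-like bent triatomic: central atom 0 bonded to atoms 1 and 2."""
    return SoluteSpec(
        name=name,
        charges=charges,
        masses=kwargs.pop("masses", (15.999, 1.008, 1.008)),
        lj_epsilon=kwargs.pop("lj_epsilon", (0.15, 0.0, 0.0)),
        lj_rmin_half=kwargs.pop("lj_rmin_half", (1.77, 0.2, 0.2)),
        bonds=((0, 1), (0, 2)),
        bond_k=bond_k,
        bond_b0=b0,
        angle_k=angle_k,
        angle_theta0=theta0,
        **kwargs,
    )


def linear_chain_spec(n: int, name: str = "chain", **kwargs) -> SoluteSpec:
    """An n-atom linear chain (n-1 bonds, n-2 angles), alkane-like toy."""
    return SoluteSpec(
        name=name,
        charges=kwargs.pop("charges", [0.0] * n),
        bonds=[(i, i + 1) for i in range(n - 1)],
        bond_b0=kwargs.pop("bond_b0", 1.53),
        angle_theta0=kwargs.pop("angle_theta0", math.radians(112.0)),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Toy solvent box builder
# ---------------------------------------------------------------------------

_SOLVENT_GEOM = {"b0": 0.9572, "theta0": math.radians(104.52), "k_b": 450.0, "k_theta": 55.0}


def _solvent_types(model: str) -> tuple[AtomType, AtomType]:
    if model == "fixed3site":
        center = AtomType("SVO", 15.999, -0.834, 0.152, 1.768, 0.0, 0.0)
    elif model == "polarizable4site":
        # alpha = 1e-3 e^2 A^2/(kcal/mol) with k_D = 1000 gives q_D = -1 e,
        # a mild induced-dipole response suited to the toy box scale
        center = AtomType("SVOP", 15.999, -0.834, 0.152, 1.768, 1.0e-3, 1000.0)
    else:
        raise ValidationError(
            f"unknown solvent model {model!r}; valid: fixed3site, polarizable4site"
        )
    hydrogen = AtomType("SVH", 1.008, 0.417, 0.0, 0.2, 0.0, 0.0)
    return center, hydrogen


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR decomposition of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_solvent_box(
    n_molecules: int,
    edge: float,
    model: str = "fixed3site",
    seed: int = 0,
    overlap_factor: float = 0.8,
) -> SystemModel:
    """Build a periodic box of bent-triatomic solvent molecules.

    Molecules are placed on a jittered cubic lattice with random
    orientations.  ``polarizable4site`` attaches one Drude-bearing site per
    molecule (on the central atom).  Raises :class:`PackingError` when no
    placement keeps every intermolecular atom pair beyond
    ``overlap_factor * (rmin_half_i + rmin_half_j)``.
    """
    if n_molecules < 1:
        raise ValidationError("n_molecules must be >= 1")
    if edge <= 0:
        raise ValidationError("edge must be positive")
    center_t, h_t = _solvent_types(model)
    rng = np.random.default_rng(seed)
    g = _SOLVENT_GEOM
    # local geometry: center at origin, hydrogens in the xy-plane
    half = g["theta0"] / 2.0
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [g["b0"] * math.cos(half), g["b0"] * math.sin(half), 0.0],
            [g["b0"] * math.cos(half), -g["b0"] * math.sin(half), 0.0],
        ]
    )
    m = math.ceil(n_molecules ** (1.0 / 3.0))
    spacing = edge / m
    sites = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]
    order = rng.permutation(len(sites))[:n_molecules]
    coords = np.empty((3 * n_molecules, 3))
    for mol, site_idx in enumerate(order):
        i, j, k = sites[site_idx]
        center = (np.array([i, j, k]) + 0.5) * spacing
        center += rng.uniform(-0.1, 0.1, size=3) * spacing
        rot = _rotation_matrix(rng)
        coords[3 * mol : 3 * mol + 3] = center + local @ rot.T

    atoms, bonds, angles = [], [], []
    for mol in range(n_molecules):
        o, h1, h2 = 3 * mol, 3 * mol + 1, 3 * mol + 2
        atoms.append(Atom(o, center_t.name, GROUP_SOLVENT))
        atoms.append(Atom(h1, h_t.name, GROUP_SOLVENT))
        atoms.append(Atom(h2, h_t.name, GROUP_SOLVENT))
        bonds += [(o, h1), (o, h2)]
        angles.append((h1, o, h2))
    topo = Topology(atoms, bonds, angles, Topology.auto_exclusions(bonds, angles))
    params = ParameterSet(
        {center_t.name: center_t, h_t.name: h_t},
        {(center_t.name, h_t.name): BondParam(g["k_b"], g["b0"])},
        {(h_t.name, center_t.name, h_t.name): AngleParam(g["k_theta"], g["theta0"])},
    )
    sys_model = SystemModel(topo, params, level=LEVEL_MM, box_edge=edge)

    # overlap check (minimum image, intermolecular pairs only)
    rmh = np.array([sys_model.atom_type(i).lj_rmin_half for i in range(3 * n_molecules)])
    mol_of = np.repeat(np.arange(n_molecules), 3)
    d = coords[:, None, :] - coords[None, :, :]
    d -= edge * np.round(d / edge)
    r = np.sqrt((d ** 2).sum(-1))
    thresh = overlap_factor * (rmh[:, None] + rmh[None, :])
    inter = mol_of[:, None] != mol_of[None, :]
    if np.any((r < thresh) & inter):
        raise PackingError(
            f"cannot place {n_molecules} molecules in a {edge:.2f} A box without "
            f"steric overlap; increase the edge length"
        )
    sys_model.initial_frame = Frame(coords, _zero_drude(sys_model))
    sys_model.metadata = {
        "builder": "build_solvent_box",
        "solvent_model": model,
        "n_molecules": n_molecules,
        "seed": seed,
    }
    return sys_model


# ---------------------------------------------------------------------------
# Surrogate target Hamiltonians
# ---------------------------------------------------------------------------


@dataclass
class SurrogatePerturbation:
    """How the surrogate target Hamiltonian differs from its MM base.

    ``bond_shifts`` (Angstrom, per bond in topology order, or scalar) shift
    equilibrium bond lengths; ``angle_shifts`` (rad) shift equilibrium
    angles; ``charge_scale`` multiplies all charges; ``morse_depth``
    (kcal/mol), when set, replaces every harmonic bond with a Morse well of
    that depth (matching curvature at the minimum).
    """

    bond_shifts: Sequence[float] | float = 0.0
    angle_shifts: Sequence[float] | float = 0.0
    charge_scale: float = 1.0
    morse_depth: float | None = None


def _unique_retype(base: SystemModel, prefix: str) -> tuple[
    dict[str, AtomType], list[Atom], list[str]
]:
    """Give every atom a fresh unique type copying its base nonbonded
    parameters.  Shared by surrogate-target construction and MM' tailoring."""
    new_types: dict[str, AtomType] = {}
    new_atoms: list[Atom] = []
    names: list[str] = []
    for atom in base.topology.atoms:
        old = base.atom_type(atom.index)
        name = f"{prefix}{atom.index + 1}"
        new_types[name] = AtomType(
            name, old.mass, old.charge, old.lj_epsilon, old.lj_rmin_half,
            old.polarizability, old.drude_spring,
        )
        new_atoms.append(Atom(atom.index, name, atom.group))
        names.append(name)
    return new_types, new_atoms, names


def make_surrogate_target(
    base: SystemModel, perturbation: SurrogatePerturbation
) -> SystemModel:
    """Derive a TARGET-level Hamiltonian from an MM base.

    The target shares the base topology but may shift equilibrium bond
    lengths/angles, rescale charges, and use Morse bonds.  With the null
    perturbation the target is exactly energy-equivalent to the base.  The
    perturbation magnitudes are free synthetic choices; they are recorded in
    the model metadata rather than claimed to correspond to any particular
    high-level method.
    """
    if base.level != LEVEL_MM:
        raise ValidationError(f"surrogate targets derive from MM bases, got level {base.level}")
    topo = base.topology
    shifts_b = _broadcast(perturbation.bond_shifts, len(topo.bonds), "bond_shifts")
    shifts_a = _broadcast(perturbation.angle_shifts, len(topo.angles), "angle_shifts")
    new_types, new_atoms, names = _unique_retype(base, "T")
    scale = perturbation.charge_scale
    if scale != 1.0:
        for name in list(new_types):
            t = new_types[name]
            # charge scaling also scales the Drude charge, i.e. alpha
            new_types[name] = AtomType(
                t.name, t.mass, t.charge * scale, t.lj_epsilon, t.lj_rmin_half,
                t.polarizability * scale * scale, t.drude_spring,
            )
    bond_params = {}
    for (i, j), shift in zip(topo.bonds, shifts_b):
        old = base.parameters.bond_param(base._tname(i), base._tname(j))
        new_b0 = old.b0 + shift
        if new_b0 <= 0:
            raise ValidationError(
                f"bond_shifts: shift {shift} makes b0 non-positive for bond ({i}, {j})"
            )
        bond_params[(names[i], names[j])] = BondParam(
            old.k_b, new_b0, perturbation.morse_depth
        )
    angle_params = {}
    for (i, j, k), shift in zip(topo.angles, shifts_a):
        old = base.parameters.angle_param(
            base._tname(i), base._tname(j), base._tname(k)
        )
        angle_params[(names[i], names[j], names[k])] = AngleParam(
            old.k_theta, old.theta0 + shift
        )
    new_topo = Topology(new_atoms, list(topo.bonds), list(topo.angles), topo.exclusions)
    params = ParameterSet(new_types, bond_params, angle_params)
    model = SystemModel(new_topo, params, level=LEVEL_TARGET, box_edge=base.box_edge)
    model.initial_frame = None if base.initial_frame is None else base.initial_frame.copy()
    model.metadata = {
        "builder": "make_surrogate_target",
        "base": base.metadata.get("spec_name", "?"),
        "bond_shifts": shifts_b,
        "angle_shifts": shifts_a,
        "charge_scale": scale,
        "morse_depth": perturbation.morse_depth,
    }
    return model
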