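"""Potential-energy evaluation for toy systems.

Terms: harmonic (or Morse) bonds and harmonic angles, 12-6 Lennard-Jones
with Lorentz-Berthelot combining and a cubic switching function, a
separation-shifted soft-core LJ form for alchemical vdW annihilation,
minimum-image Coulomb over charge sites (cores + Drude particles), Drude
spring self-energy, and alchemical charge scaling.

Two evaluation conventions coexist, mirroring the split between sampling
and post-processing:

* sampling evaluations use the switched LJ cutoff and minimum image
  (:func:`sampling_settings` scales the 10-12 A analog to the toy box);
* bookend evaluations (:func:`bookend_settings`, :func:`bookend_delta_u`)
  use full minimum-image sums with no cutoff and no switching.

Alchemical scaling: all solute charges (including Drude charges) are
multiplied by (1 - lambda_elec), so intra-solute electrostatics scale as
(1 - lambda_elec)^2 and solute-solvent electrostatics linearly; soft-core
vdW scaling applies to every non-excluded pair involving a solute atom
(annihilation, not decoupling), identically in gas and aqueous phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from weakref import WeakKeyDictionary

import numpy as np

from .constants import COULOMB_K
from .systems import Frame, SystemModel, ValidationError

__all__ = [
    "AlchemicalState",
    "NonbondedSettings",
    "EnergyBreakdown",
    "AtomOverlapError",
    "PolarizationCatastropheError",
    "FULLY_INTERACTING",
    "sampling_settings",
    "bookend_settings",
    "bonded_energy",
    "lj_energy",
    "softcore_lj_energy",
    "coulomb_energy",
    "drude_spring_energy",
    "total_energy",
    "energy_and_gradient",
    "drude_relax",
    "decompose_energy",
    "bookend_delta_u",
    "recenter",
]

_OVERLAP_R = 1e-6


class AtomOverlapError(RuntimeError):
    """Two interacting atoms are (numerically) on top of each other."""


class PolarizationCatastropheError(RuntimeError):
    """Drude relaxation diverged; the spring is too soft for the field."""


@dataclass(frozen=True)
class AlchemicalState:
    """Coupling parameters of one alchemical window.

    ``lambda_elec`` scales solute charges by (1 - lambda_elec): 0 = full
    charges, 1 = charges off.  ``lambda_vdw`` drives soft-core vdW
    annihilation: 0 = full vdW, 1 = vdW off.  Charges are removed before
    vdW, so lambda_vdw > 0 requires lambda_elec = 1.
    """

    lambda_elec: float = 0.0
    lambda_vdw: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_elec <= 1.0 and 0.0 <= self.lambda_vdw <= 1.0):
            raise ValidationError("lambda values must lie in [0, 1]")
        if self.lambda_vdw > 0.0 and self.lambda_elec != 1.0:
            raise ValidationError(
                "protocol constraint violated: lambda_vdw > 0 requires lambda_elec = 1 "
                "(charges are removed before van der Waals)"
            )


FULLY_INTERACTING = AlchemicalState(0.0, 0.0)


@dataclass(frozen=True)
class NonbondedSettings:
    """Cutoff/switching and soft-core controls.

    ``r_on``/``r_off`` (Angstrom) bound the cubic LJ switching region; both
    None means no cutoff (S = 1 everywhere).  ``use_min_image`` applies the
    minimum-image convention in periodic boxes.  ``softcore_delta`` is the
    separation-shift parameter of the soft-core form (recorded in every
    result file)."""

    r_on: float | None = None
    r_off: float | None = None
    use_min_image: bool = False
    softcore_delta: float = 0.5

    def __post_init__(self) -> None:
        if (self.r_on is None) != (self.r_off is None):
            raise ValidationError("r_on and r_off must be set together")
        if self.r_on is not None and not (0.0 < self.r_on < self.r_off):
            raise ValidationError("need 0 < r_on < r_off")
        if self.softcore_delta <= 0:
            raise ValidationError("softcore_delta must be > 0")


def sampling_settings(model: SystemModel, softcore_delta: float = 0.5) -> NonbondedSettings:
    """The sampling convention: switched LJ scaled to the toy box
    (r_on = 0.35 edge, r_off = 0.45 edge, the 10-12 A analog), minimum
    image.  Gas-phase models get no cutoff."""
    if not model.is_periodic:
        return NonbondedSettings(softcore_delta=softcore_delta)
    e = model.box_edge
    return NonbondedSettings(0.35 * e, 0.45 * e, True, softcore_delta)


def bookend_settings() -> NonbondedSettings:
    """The post-processing convention: no cutoff, minimum image."""
    return NonbondedSettings(use_min_image=True)


@dataclass
class EnergyBreakdown:
    """Group-wise decomposition; ``total`` is the sum of all components."""

    solute_solute: float
    solute_solvent_elec: float
    solute_solvent_vdw: float
    solvent_solvent: float
    bonded_solute: float
    drude_spring: float
    total: float = field(default=0.0)

    def __post_init__(self) -> None:
        s = (
            self.solute_solute
            + self.solute_solvent_elec
            + self.solute_solvent_vdw
            + self.solvent_solvent
            + self.bonded_solute
            + self.drude_spring
        )
        if self.total == 0.0:
            self.total = s
        elif abs(self.total - s) > 1e-9:
            raise ValidationError("EnergyBreakdown components do not sum to total")


# ---------------------------------------------------------------------------
# Compiled per-model arrays (cached on the model instance)
# ---------------------------------------------------------------------------

_PAIR_SS, _PAIR_SV, _PAIR_VV = 0, 1, 2
_cache: "WeakKeyDictionary[SystemModel, _Compiled]" = WeakKeyDictionary()


class _Compiled:
    def __init__(self, model: SystemModel):
        topo = model.topology
        n = topo.n_atoms
        self.n = n
        self.q = np.array([model.atom_type(i).charge for i in range(n)])
        self.eps = np.array([model.atom_type(i).lj_epsilon for i in range(n)])
        self.rmh = np.array([model.atom_type(i).lj_rmin_half for i in range(n)])
        self.solute = np.array([a.group == "solute" for a in topo.atoms])
        self.pol_idx = model.polarizable_indices()
        self.n_pol = len(self.pol_idx)
        self.qd = np.array([model.atom_type(i).drude_charge for i in self.pol_idx])
        self.kd = np.array([model.atom_type(i).drude_spring for i in self.pol_idx])

        excl = topo.exclusions
        pi, pj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in excl:
                    pi.append(i)
                    pj.append(j)
        self.pair_i = np.array(pi, dtype=int)
        self.pair_j = np.array(pj, dtype=int)
        ns = self.solute[self.pair_i].astype(int) + self.solute[self.pair_j].astype(int)
        self.pair_class = np.where(ns == 2, _PAIR_SS, np.where(ns == 1, _PAIR_SV, _PAIR_VV))
        self.eps_ij = np.sqrt(self.eps[self.pair_i] * self.eps[self.pair_j])
        self.rmin_ij = self.rmh[self.pair_i] + self.rmh[self.pair_j]

        # charge sites: n cores then n_pol drudes
        self.site_parent = np.concatenate([np.arange(n), self.pol_idx]).astype(int)
        n_sites = n + self.n_pol
        sa, sb = [], []
        for a in range(n_sites):
            pa = self.site_parent[a]
            for b in range(a + 1, n_sites):
                pb = self.site_parent[b]
                if pa == pb:
                    continue
                key = (pa, pb) if pa < pb else (pb, pa)
                if key in excl:
                    continue
                sa.append(a)
                sb.append(b)
        self.spair_a = np.array(sa, dtype=int)
        self.spair_b = np.array(sb, dtype=int)
        pa = self.site_parent[self.spair_a]
        pb = self.site_parent[self.spair_b]
        ns2 = self.solute[pa].astype(int) + self.solute[pb].astype(int)
        self.spair_class = np.where(ns2 == 2, _PAIR_SS, np.where(ns2 == 1, _PAIR_SV, _PAIR_VV))

        self.bond_i = np.array([b[0] for b in topo.bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in topo.bonds], dtype=int)
        bps = [
            model.parameters.bond_param(model._tname(i), model._tname(j))
            for i, j in topo.bonds
        ]
        self.bond_k = np.array([p.k_b for p in bps])
        self.bond_b0 = np.array([p.b0 for p in bps])
        self.bond_morse = np.array(
            [p.morse_depth if p.morse_depth is not None else np.nan for p in bps]
        )
        self.bond_solute = self.solute[self.bond_i] & self.solute[self.bond_j]
        self.ang_i = np.array([a[0] for a in topo.angles], dtype=int)
        self.ang_j = np.array([a[1] for a in topo.angles], dtype=int)
        self.ang_k = np.array([a[2] for a in topo.angles], dtype=int)
        aps = [
            model.parameters.angle_param(
                model._tname(i), model._tname(j), model._tname(k)
            )
            for i, j, k in topo.angles
        ]
        self.ang_kth = np.array([p.k_theta for p in aps])
        self.ang_t0 = np.array([p.theta0 for p in aps])
        self.ang_solute = (
            self.solute[self.ang_i] & self.solute[self.ang_j] & self.solute[self.ang_k]
        )

        # solvent molecules as bond-connected components (for whole-molecule wrapping)
        parent_of = list(range(n))

        def find(x):
            while parent_of[x] != x:
                parent_of[x] = parent_of[parent_of[x]]
                x = parent_of[x]
            return x

        for i, j in topo.bonds:
            parent_of[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        self.solvent_molecules = [
            np.array(g, dtype=int) for g in groups.values() if not self.solute[g[0]]
        ]


def _compiled(model: SystemModel) -> _Compiled:
    c = _cache.get(model)
    if c is None:
        c = _Compiled(model)
        _cache[model] = c
    return c


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _disp(xa: np.ndarray, xb: np.ndarray, model, settings) -> np.ndarray:
    d = xb - xa
    if settings.use_min_image and model.is_periodic:
        e = model.box_edge
        d -= e * np.round(d / e)
    return d


def _switch(r2: np.ndarray, settings: NonbondedSettings):
    """Cubic switching function S(r) and dS/dr2 evaluated on squared
    distances.  S = 1 for r <= r_on, 0 for r >= r_off."""
    if settings.r_on is None:
        return np.ones_like(r2), np.zeros_like(r2)
    a, b = settings.r_on ** 2, settings.r_off ** 2
    denom = (b - a) ** 3
    s = np.ones_like(r2)
    ds = np.zeros_like(r2)
    mid = (r2 > a) & (r2 < b)
    rm = r2[mid]
    s[mid] = (b - rm) ** 2 * (b + 2 * rm - 3 * a) / denom
    ds[mid] = (-2 * (b - rm) * (b + 2 * rm - 3 * a) + 2 * (b - rm) ** 2) / denom
    s[r2 >= b] = 0.0
    return s, ds


def _effective_site_charges(c: _Compiled, lambda_elec: float):
    """Per-site charges with solute scaling: cores carry q - q_D for
    polarizable atoms, Drude sites carry q_D; all solute charges (and thus
    solute Drude charges) are scaled by (1 - lambda_elec)."""
    scale_atom = np.where(c.solute, 1.0 - lambda_elec, 1.0)
    q_atom = c.q * scale_atom
    qd_eff = c.qd * scale_atom[c.pol_idx] if c.n_pol else np.zeros(0)
    q_core = q_atom.copy()
    if c.n_pol:
        q_core[c.pol_idx] -= qd_eff
    return np.concatenate([q_core, qd_eff])


def _site_positions(c: _Compiled, frame: Frame) -> np.ndarray:
    if c.n_pol == 0:
        return frame.coordinates
    d = frame.drude_displacements
    if d is None:
        d = np.zeros((c.n_pol, 3))
    return np.vstack([frame.coordinates, frame.coordinates[c.pol_idx] + d])


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


def _bonded(c: _Compiled, x: np.ndarray, grad: np.ndarray | None):
    e = 0.0
    if len(c.bond_i):
        bi, bj = c.bond_i, c.bond_j
        d = x[bj] - x[bi]
        r = np.linalg.norm(d, axis=1)
        x0 = r - c.bond_b0
        harm = np.isnan(c.bond_morse)
        u = np.where(harm, c.bond_k * x0 ** 2, 0.0)
        dudr = np.where(harm, 2.0 * c.bond_k * x0, 0.0)
        if not harm.all():
            D = np.where(harm, 1.0, c.bond_morse)
            a = np.sqrt(c.bond_k / D)
            ex = np.exp(-a * x0)
            u = np.where(harm, u, D * (1.0 - ex) ** 2)
            dudr = np.where(harm, dudr, 2.0 * D * a * ex * (1.0 - ex))
        e += float(np.sum(u))
        if grad is not None:
            with np.errstate(invalid="ignore"):
                g = (dudr / np.where(r > 0, r, 1.0))[:, None] * d
            np.add.at(grad, bj, g)
            np.add.at(grad, bi, -g)
    if len(c.ang_i):
        u_v = x[c.ang_i] - x[c.ang_j]
        v_v = x[c.ang_k] - x[c.ang_j]
        nu = np.linalg.norm(u_v, axis=1)
        nv = np.linalg.norm(v_v, axis=1)
        cos = np.einsum("ij,ij->i", u_v, v_v) / (nu * nv)
        cos = np.clip(cos, -1.0, 1.0)
        theta = np.arccos(cos)
        dth = theta - c.ang_t0
        e += float(np.sum(c.ang_kth * dth ** 2))
        if grad is not None:
            dudth = 2.0 * c.ang_kth * dth
            sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
            uh = u_v / nu[:, None]
            vh = v_v / nv[:, None]
            dthi = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
            dthk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
            gi = dudth[:, None] * dthi
            gk = dudth[:, None] * dthk
            np.add.at(grad, c.ang_i, gi)
            np.add.at(grad, c.ang_k, gk)
            np.add.at(grad, c.ang_j, -(gi + gk))
    return e


def _bonded_split(c: _Compiled, x: np.ndarray) -> tuple[float, float]:
    """(solute bonded, solvent bonded) energies, no gradient."""
    e_sol = e_svt = 0.0
    if len(c.bond_i):
        d = x[c.bond_j] - x[c.bond_i]
        r = np.linalg.norm(d, axis=1)
        x0 = r - c.bond_b0
        harm = np.isnan(c.bond_morse)
        u = np.where(harm, c.bond_k * x0 ** 2, 0.0)
        if not harm.all():
            D = np.where(harm, 1.0, c.bond_morse)
            a = np.sqrt(c.bond_k / D)
            u = np.where(harm, u, D * (1.0 - np.exp(-a * x0)) ** 2)
        e_sol += float(np.sum(u[c.bond_solute]))
        e_svt += float(np.sum(u[~c.bond_solute]))
    if len(c.ang_i):
        u_v = x[c.ang_i] - x[c.ang_j]
        v_v = x[c.ang_k] - x[c.ang_j]
        cos = np.clip(
            np.einsum("ij,ij->i", u_v, v_v)
            / (np.linalg.norm(u_v, axis=1) * np.linalg.norm(v_v, axis=1)),
            -1.0,
            1.0,
        )
        u = c.ang_kth * (np.arccos(cos) - c.ang_t0) ** 2
        e_sol += float(np.sum(u[c.ang_solute]))
        e_svt += float(np.sum(u[~c.ang_solute]))
    return e_sol, e_svt


def bonded_energy(model: SystemModel, frame: Frame) -> float:
    """Sum of K_b (b - b0)^2 bond terms (or Morse where configured) and
    K_theta (theta - theta0)^2 angle terms; always >= 0 for harmonic
    parameters."""
    frame.validate_against(model)
    c = _compiled(model)
    e_sol, e_svt = _bonded_split(c, frame.coordinates)
    return e_sol + e_svt


# ---------------------------------------------------------------------------
# Nonbonded terms
# ---------------------------------------------------------------------------


def _lj_pair_terms(c, x, model, settings, lambda_vdw: float, want_grad: bool):
    """Per-pair vdW energies and (optionally) dU/dr2 including switching.

    Solute-involving pairs use the soft-core form at lambda_vdw > 0;
    solvent-solvent pairs are always plain LJ.
    """
    if len(c.pair_i) == 0:
        z = np.zeros(0)
        return z, (z if want_grad else None), z
    d = _disp(x[c.pair_i], x[c.pair_j], model, settings)
    r2 = np.einsum("ij,ij->i", d, d)
    soft = (c.pair_class != _PAIR_VV) & (lambda_vdw > 0.0)
    active = c.eps_ij > 0.0
    bad = active & ~soft & (r2 < _OVERLAP_R ** 2)
    if np.any(bad):
        k = int(np.argmax(bad))
        raise AtomOverlapError(
            f"atoms {c.pair_i[k]} and {c.pair_j[k]} overlap (r < {_OVERLAP_R} A)"
        )
    s, dsdr2 = _switch(r2, settings)
    sigma2 = (c.rmin_ij / 2.0 ** (1.0 / 6.0)) ** 2
    delta = settings.softcore_delta
    shift = np.where(soft, delta * lambda_vdw * sigma2, 0.0)
    prefac = np.where(soft, 1.0 - lambda_vdw, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u6 = np.where(active, sigma2 / (r2 + shift), 0.0)
    u3 = u6 ** 3
    core = 4.0 * c.eps_ij * (u3 ** 2 - u3)
    u_pair = prefac * core * s
    grad_r2 = None
    if want_grad:
        dcore = 4.0 * c.eps_ij * (6 * u3 ** 2 - 3 * u3) * np.where(active, -1.0 / (r2 + shift), 0.0)
        grad_r2 = prefac * (dcore * s + core * dsdr2)
    return u_pair, grad_r2, d


def lj_energy(model: SystemModel, frame: Frame, settings: NonbondedSettings) -> float:
    """Switched 12-6 Lennard-Jones energy over non-excluded pairs."""
    frame.validate_against(model)
    if settings.use_min_image and not model.is_periodic:
        raise ValidationError("use_min_image requires a periodic box")
    c = _compiled(model)
    u, _, _ = _lj_pair_terms(c, frame.coordinates, model, settings, 0.0, False)
    return float(np.sum(u))


def softcore_lj_energy(
    model: SystemModel,
    frame: Frame,
    state: AlchemicalState,
    settings: NonbondedSettings,
) -> float:
    """vdW energy with soft-core annihilation of solute-involving pairs:
    with u = sigma^2/(r^2 + delta*lambda*sigma^2),
    U = (1 - lambda) * 4 eps (u^6 - u^3), switched like plain LJ.  Finite at
    r = 0 for lambda > 0; equals :func:`lj_energy` at lambda = 0 and is
    identically 0 at lambda = 1."""
    frame.validate_against(model)
    c = _compiled(model)
    lam = state.lambda_vdw
    if lam == 1.0:
        # annihilated solute: only solvent-solvent vdW survives
        u, _, _ = _lj_pair_terms(c, frame.coordinates, model, settings, lam, False)
        return float(np.sum(u[c.pair_class == _PAIR_VV]))
    u, _, _ = _lj_pair_terms(c, frame.coordinates, model, settings, lam, False)
    return float(np.sum(u))


def coulomb_energy(
    model: SystemModel,
    frame: Frame,
    state: AlchemicalState = FULLY_INTERACTING,
    settings: NonbondedSettings = NonbondedSettings(),
) -> float:
    """Pairwise Coulomb energy k_e q_a q_b / r over non-excluded charge-site
    pairs (cores and Drude particles), minimum-image when periodic, never
    switched."""
    frame.validate_against(model)
    c = _compiled(model)
    if len(c.spair_a) == 0:
        return 0.0
    qs = _effective_site_charges(c, state.lambda_elec)
    pos = _site_positions(c, frame)
    d = _disp(pos[c.spair_a], pos[c.spair_b], model, settings)
    r = np.linalg.norm(d, axis=1)
    qq = qs[c.spair_a] * qs[c.spair_b]
    bad = (np.abs(qq) > 0) & (r < _OVERLAP_R)
    if np.any(bad):
        k = int(np.argmax(bad))
        raise AtomOverlapError(
            f"charge sites of atoms {c.site_parent[c.spair_a[k]]} and "
            f"{c.site_parent[c.spair_b[k]]} overlap (r < {_OVERLAP_R} A)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(np.abs(qq) > 0, COULOMB_K * qq / np.where(r > 0, r, 1.0), 0.0)
    return float(np.sum(u))


def drude_spring_energy(model: SystemModel, frame: Frame) -> float:
    """Drude self-energy, sum of (1/2) k_D |d|^2."""
    c = _compiled(model)
    if c.n_pol == 0 or frame.drude_displacements is None:
        return 0.0
    return float(0.5 * np.sum(c.kd * np.einsum("ij,ij->i", frame.drude_displacements,
                                               frame.drude_displacements)))


def total_energy(
    model: SystemModel,
    frame: Frame,
    state: AlchemicalState = FULLY_INTERACTING,
    settings: NonbondedSettings | None = None,
) -> float:
    """Bonded + Drude spring + Coulomb + (soft-core) vdW energy."""
    if settings is None:
        settings = sampling_settings(model)
    return (
        bonded_energy(model, frame)
        + drude_spring_energy(model, frame)
        + coulomb_energy(model, frame, state, settings)
        + softcore_lj_energy(model, frame, state, settings)
    )


# ---------------------------------------------------------------------------
# Gradient (atoms and Drude displacements)
# ---------------------------------------------------------------------------


def energy_and_gradient(
    model: SystemModel,
    frame: Frame,
    state: AlchemicalState = FULLY_INTERACTING,
    settings: NonbondedSettings | None = None,
    external_field: np.ndarray | None = None,
):
    """Total energy with analytic gradients.

    Returns ``(energy, grad_atoms (n, 3), grad_drude (n_pol, 3))``.  An
    optional uniform ``external_field`` (kcal/mol/A/e) couples to the Drude
    displacement only (energy term -q_D E . d), which is what the isolated
    linear-response setup probes.
    """
    if settings is None:
        settings = sampling_settings(model)
    frame.validate_against(model)
    c = _compiled(model)
    x = frame.coordinates
    grad = np.zeros_like(x)
    e = _bonded(c, x, grad)

    # vdW on atom centers
    u, grad_r2, d = _lj_pair_terms(c, x, model, settings, state.lambda_vdw, True)
    if state.lambda_vdw == 1.0:
        keep = c.pair_class == _PAIR_VV
        e += float(np.sum(u[keep]))
        grad_r2 = np.where(keep, grad_r2, 0.0)
    else:
        e += float(np.sum(u))
    if len(c.pair_i):
        g = 2.0 * grad_r2[:, None] * d
        np.add.at(grad, c.pair_j, g)
        np.add.at(grad, c.pair_i, -g)

    # Coulomb on charge sites
    grad_d = np.zeros((c.n_pol, 3))
    if len(c.spair_a):
        qs = _effective_site_charges(c, state.lambda_elec)
        pos = _site_positions(c, frame)
        dv = _disp(pos[c.spair_a], pos[c.spair_b], model, settings)
        r = np.linalg.norm(dv, axis=1)
        qq = qs[c.spair_a] * qs[c.spair_b]
        bad = (np.abs(qq) > 0) & (r < _OVERLAP_R)
        if np.any(bad):
            raise AtomOverlapError("overlapping charge sites in gradient evaluation")
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r = np.where(r > 0, 1.0 / r, 0.0)
        e += float(np.sum(COULOMB_K * qq * inv_r))
        dudr = -COULOMB_K * qq * inv_r ** 2
        gpair = (dudr * inv_r)[:, None] * dv  # dU/dr_b
        site_grad = np.zeros((c.n + c.n_pol, 3))
        np.add.at(site_grad, c.spair_b, gpair)
        np.add.at(site_grad, c.spair_a, -gpair)
        grad += site_grad[: c.n]
        if c.n_pol:
            np.add.at(grad, c.pol_idx, site_grad[c.n :])
            grad_d += site_grad[c.n :]

    # Drude springs and external field
    if c.n_pol:
        dd = frame.drude_displacements
        if dd is None:
            dd = np.zeros((c.n_pol, 3))
        e += float(0.5 * np.sum(c.kd * np.einsum("ij,ij->i", dd, dd)))
        grad_d += c.kd[:, None] * dd
        if external_field is not None:
            ef = np.asarray(external_field, dtype=float)
            scale = np.where(c.solute[c.pol_idx], 1.0 - state.lambda_elec, 1.0)
            qd_eff = c.qd * scale
            e += float(-np.sum(qd_eff[:, None] * ef[None, :] * dd))
            grad_d += -qd_eff[:, None] * ef[None, :]
    return e, grad, grad_d


# ---------------------------------------------------------------------------
# Drude relaxation (SCF)
# ---------------------------------------------------------------------------


def drude_relax(
    model: SystemModel,
    frame: Frame,
    tol: float = 1e-8,
    max_iter: int = 500,
    radius: float | None = None,
    state: AlchemicalState = FULLY_INTERACTING,
    settings: NonbondedSettings | None = None,
    external_field: np.ndarray | None = None,
    damping: float = 0.5,
) -> tuple[Frame, float]:
    """Relax Drude displacements to the self-consistent energy minimum.

    Iterates the damped fixed point d <- d + damping * (q_D E_local / k_D - d)
    with all atomic positions held in place, until the largest
    displacement-gradient component falls below ``tol`` (kcal/mol/A) or
    ``max_iter`` is reached.  ``radius`` (Angstrom) restricts relaxation to
    Drude particles whose parent atom lies within that distance of any
    solute atom; None relaxes all.  Returns the relaxed frame and its
    energy, which never exceeds the input frame's energy.
    """
    if settings is None:
        settings = sampling_settings(model)
    frame.validate_against(model)
    c = _compiled(model)
    if c.n_pol == 0:
        raise ValidationError("model has no polarizable sites")
    out = frame.copy()
    if out.drude_displacements is None:
        out.drude_displacements = np.zeros((c.n_pol, 3))
    active = np.ones(c.n_pol, dtype=bool)
    if radius is not None:
        sol_x = frame.coordinates[c.solute]
        if len(sol_x) == 0:
            active = np.zeros(c.n_pol, dtype=bool)
        else:
            px = frame.coordinates[c.pol_idx]
            dv = px[:, None, :] - sol_x[None, :, :]
            if settings.use_min_image and model.is_periodic:
                e_ = model.box_edge
                dv -= e_ * np.round(dv / e_)
            dist = np.sqrt((dv ** 2).sum(-1)).min(axis=1)
            active = dist <= radius

    e_prev, _, g_d = energy_and_gradient(model, out, state, settings, external_field)
    for _ in range(max_iter):
        gmax = np.abs(g_d[active]).max() if active.any() else 0.0
        if gmax < tol:
            break
        # g_d = k_D d - q_D E, so the fixed point is d* = d - g_d / k_D
        step = -g_d / c.kd[:, None]
        out.drude_displacements[active] += damping * step[active]
        e_new, _, g_d = energy_and_gradient(model, out, state, settings, external_field)
        if e_new > e_prev + 1e-8:
            raise PolarizationCatastropheError(
                "Drude relaxation diverged (energy increased); the spring constant "
                "k_D is too small for the local field -- use a stiffer spring"
            )
        e_prev = e_new
    return out, e_prev


# ---------------------------------------------------------------------------
# Decomposition and bookend ΔU
# ---------------------------------------------------------------------------


def decompose_energy(
    model: SystemModel,
    frame: Frame,
    state: AlchemicalState = FULLY_INTERACTING,
    settings: NonbondedSettings | None = None,
) -> EnergyBreakdown:
    """Group-wise energy decomposition by pair membership.

    ``solute_solute`` collects intra-solute nonbonded terms (elec + vdW);
    ``solvent_solvent`` collects intra-solvent nonbonded terms plus the
    solvent's own bonded (stiff-spring) energy; the Drude self-energy is
    reported separately.
    """
    if settings is None:
        settings = sampling_settings(model)
    frame.validate_against(model)
    c = _compiled(model)
    x = frame.coordinates
    bonded_sol, bonded_svt = _bonded_split(c, x)

    u, _, _ = _lj_pair_terms(c, x, model, settings, state.lambda_vdw, False)
    if state.lambda_vdw == 1.0:
        u = np.where(c.pair_class == _PAIR_VV, u, 0.0)
    vdw_ss = float(np.sum(u[c.pair_class == _PAIR_SS]))
    vdw_sv = float(np.sum(u[c.pair_class == _PAIR_SV]))
    vdw_vv = float(np.sum(u[c.pair_class == _PAIR_VV]))

    elec_ss = elec_sv = elec_vv = 0.0
    if len(c.spair_a):
        qs = _effective_site_charges(c, state.lambda_elec)
        pos = _site_positions(c, frame)
        dv = _disp(pos[c.spair_a], pos[c.spair_b], model, settings)
        r = np.linalg.norm(dv, axis=1)
        qq = qs[c.spair_a] * qs[c.spair_b]
        with np.errstate(divide="ignore", invalid="ignore"):
            ue = np.where(np.abs(qq) > 0, COULOMB_K * qq / np.where(r > 0, r, 1.0), 0.0)
        elec_ss = float(np.sum(ue[c.spair_class == _PAIR_SS]))
        elec_sv = float(np.sum(ue[c.spair_class == _PAIR_SV]))
        elec_vv = float(np.sum(ue[c.spair_class == _PAIR_VV]))

    return EnergyBreakdown(
        solute_solute=vdw_ss + elec_ss,
        solute_solvent_elec=elec_sv,
        solute_solvent_vdw=vdw_sv,
        solvent_solvent=vdw_vv + elec_vv + bonded_svt,
        bonded_solute=bonded_sol,
        drude_spring=drude_spring_energy(model, frame),
    )


def _check_compatible(model_a: SystemModel, model_b: SystemModel) -> None:
    ta, tb = model_a.topology, model_b.topology
    if (
        ta.n_atoms != tb.n_atoms
        or ta.bonds != tb.bonds
        or ta.angles != tb.angles
        or [a.group for a in ta.atoms] != [a.group for a in tb.atoms]
    ):
        raise ValidationError("Hamiltonian levels have mismatched topologies")


def bookend_delta_u(
    model_a: SystemModel,
    model_b: SystemModel,
    frame: Frame,
    settings: NonbondedSettings | None = None,
) -> float:
    """Potential-energy difference U_B - U_A between two Hamiltonian levels
    on a shared frame, using only the terms that do not cancel between
    levels: solute-solute nonbonded, solute bonded, and electrostatic
    solute-solvent interactions.  (Solvent-solvent interactions and
    solute-solvent vdW are identical at both levels and drop out.)
    Evaluated with the bookend convention (no cutoff, minimum image) unless
    settings are given.
    """
    _check_compatible(model_a, model_b)
    if settings is None:
        settings = bookend_settings() if model_a.is_periodic else NonbondedSettings()

    def _relevant(model: SystemModel) -> float:
        b = decompose_energy(model, frame, FULLY_INTERACTING, settings)
        return b.solute_solute + b.bonded_solute + b.solute_solvent_elec

    return _relevant(model_b) - _relevant(model_a)


def recenter(frame: Frame, model: SystemModel) -> Frame:
    """Center the solvent box around the solute.

    Translates so the solute centroid sits at the box center, then wraps
    each solvent molecule whole so its centroid lies inside the primary
    box.  Minimum-image energies are unchanged; gas-phase frames are
    returned unmodified.  Idempotent.
    """
    if not model.is_periodic:
        return frame
    frame.validate_against(model)
    c = _compiled(model)
    e = model.box_edge
    out = frame.copy()
    if c.solute.any():
        centroid = out.coordinates[c.solute].mean(axis=0)
        out.coordinates += (np.full(3, e / 2.0) - centroid)
    for mol in c.solvent_molecules:
        com = out.coordinates[mol].mean(axis=0)
        shift = np.floor(com / e) * e
        out.coordinates[mol] -= shift
    return out
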