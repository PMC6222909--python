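"""Tailored MM' force-field generation.

Reweighting from a sampling Hamiltonian toward a stiffly bonded target
converges poorly when their equilibrium geometries disagree: the bonded
energy difference dominates the work distribution and the effective sample
size collapses.  The remedy implemented here is to (1) minimize the target
Hamiltonian's gas-phase geometry, (2) copy the base force field while
assigning every atom its own unique type, and (3) reset every equilibrium
bond length and angle to the value measured in the target-minimized
geometry.  Charges, Lennard-Jones parameters, polarizabilities and force
constants are copied unchanged from the base types -- only the equilibrium
values are tailored, which is the procedure's main limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constants import LEVEL_MM_PRIME
from .energy import FULLY_INTERACTING, NonbondedSettings, energy_and_gradient
from .systems import (
    AngleParam,
    BondParam,
    Frame,
    ParameterSet,
    SystemModel,
    Topology,
    ValidationError,
    _unique_retype,
)

__all__ = [
    "MinimizationReport",
    "TailoringError",
    "minimize_geometry",
    "make_tailored_parameters",
    "write_tailored_files",
]


class TailoringError(RuntimeError):
    """Tailoring preconditions are not met."""


@dataclass
class MinimizationReport:
    """Outcome of a gas-phase geometry minimization."""

    final_coordinates: Frame
    final_energy: float
    grad_inf_norm: float
    n_iterations: int
    converged: bool
    tolerance: float
    minimizer: str = "L-BFGS-B"

    def __post_init__(self) -> None:
        if self.converged and self.grad_inf_norm > self.tolerance:
            raise ValidationError("converged report violates its own gradient tolerance")


def minimize_geometry(
    model: SystemModel,
    start: Frame | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> MinimizationReport:
    """Minimize the gas-phase potential energy over atomic coordinates.

    Quasi-Newton (L-BFGS-B) with the analytic gradient, polished by a short
    steepest-descent-with-backtracking phase if needed to push the gradient
    infinity norm below ``tol`` (kcal/mol/A).  Hitting ``max_iter`` returns
    ``converged=False`` rather than raising.  Deterministic.
    """
    if model.is_periodic:
        raise TailoringError("geometry minimization expects a gas-phase model")
    if start is None:
        start = model.initial_frame
    if start is None:
        raise TailoringError("no start frame available")
    settings = NonbondedSettings()
    n = model.n_atoms

    def fun(x: np.ndarray):
        frame = Frame(x.reshape(n, 3))
        e, g, _ = energy_and_gradient(model, frame, FULLY_INTERACTING, settings)
        return e, g.ravel()

    res = minimize(
        fun,
        start.coordinates.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * 0.1, "ftol": 1e-15},
    )
    x = res.x
    e, g = fun(x)
    n_iter = int(res.nit)
    # polish with damped Newton (finite-difference Hessian of the analytic
    # gradient): L-BFGS-B stalls slightly above very tight tolerances
    h = 1e-6
    mu = 1e-8
    dim = x.size
    while np.abs(g).max() > tol and n_iter < max_iter:
        hess = np.empty((dim, dim))
        for k in range(dim):
            xp = x.copy()
            xp[k] += h
            hess[:, k] = (fun(xp)[1] - g) / h
        hess = 0.5 * (hess + hess.T)
        try:
            step = np.linalg.solve(hess + mu * np.eye(dim), -g)
        except np.linalg.LinAlgError:
            step = -g
        e_new, g_new = fun(x + step)
        if e_new <= e + 1e-12 and np.isfinite(e_new):
            x, e, g = x + step, e_new, g_new
            mu = max(mu * 0.3, 1e-12)
        else:
            mu = mu * 10.0 + 1e-6
            if mu > 1e12:
                break
        n_iter += 1
    gmax = float(np.abs(g).max())
    return MinimizationReport(
        final_coordinates=Frame(x.reshape(n, 3)),
        final_energy=float(e),
        grad_inf_norm=gmax,
        n_iterations=n_iter,
        converged=gmax <= tol,
        tolerance=tol,
    )


def _measure_bond(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[j] - x[i]))


def _measure_angle(x: np.ndarray, i: int, j: int, k: int) -> float:
    u = x[i] - x[j]
    v = x[k] - x[j]
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.acos(max(-1.0, min(1.0, c)))


def make_tailored_parameters(
    base: SystemModel, target_geometry: MinimizationReport
) -> SystemModel:
    """Build the MM' model from an MM base and a converged target geometry.

    Every atom receives a fresh unique type; every bond's b0 and angle's
    theta0 are set to the values measured in the minimized target geometry;
    charges, LJ parameters, polarizabilities and force constants come from
    the base unchanged.  Refuses unconverged geometries.
    """
    if not isinstance(target_geometry, MinimizationReport):
        raise TailoringError(
            "tailoring requires a MinimizationReport (evidence of convergence), "
            f"got {type(target_geometry).__name__}"
        )
    if not target_geometry.converged:
        raise TailoringError(
            "refusing to tailor to an unconverged geometry "
            f"(grad inf-norm {target_geometry.grad_inf_norm:.3g} > "
            f"tol {target_geometry.tolerance:.3g})"
        )
    topo = base.topology
    x = target_geometry.final_coordinates.coordinates
    if x.shape[0] != topo.n_atoms:
        raise TailoringError("target geometry does not match the base topology")
    new_types, new_atoms, names = _unique_retype(base, "MP")
    bond_params: dict[tuple[str, str], BondParam] = {}
    for i, j in topo.bonds:
        old = base.parameters.bond_param(
            topo.atoms[i].type_name, topo.atoms[j].type_name
        )
        bond_params[(names[i], names[j])] = BondParam(old.k_b, _measure_bond(x, i, j))
    angle_params: dict[tuple[str, str, str], AngleParam] = {}
    for i, j, k in topo.angles:
        old = base.parameters.angle_param(
            topo.atoms[i].type_name, topo.atoms[j].type_name, topo.atoms[k].type_name
        )
        angle_params[(names[i], names[j], names[k])] = AngleParam(
            old.k_theta, _measure_angle(x, i, j, k)
        )
    new_topo = Topology(new_atoms, list(topo.bonds), list(topo.angles), topo.exclusions)
    params = ParameterSet(new_types, bond_params, angle_params)
    model = SystemModel(new_topo, params, level=LEVEL_MM_PRIME, box_edge=base.box_edge)
    model.initial_frame = target_geometry.final_coordinates.copy()
    model.metadata = {
        "builder": "make_tailored_parameters",
        "base": base.metadata.get("spec_name", "?"),
        "minimizer": target_geometry.minimizer,
        "minimizer_tol": target_geometry.tolerance,
        "minimizer_iterations": target_geometry.n_iterations,
    }
    return model


def write_tailored_files(model_mm_prime: SystemModel, path) -> None:
    """Write the MM' model in the package system schema with a provenance
    block (base name, minimizer settings); read-back round-trips to an
    energy-equivalent model with bit-identical parameters."""
    from .io import write_system

    if model_mm_prime.level != LEVEL_MM_PRIME:
        raise TailoringError(f"expected an MM' model, got level {model_mm_prime.level}")
    write_system(model_mm_prime, path)
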