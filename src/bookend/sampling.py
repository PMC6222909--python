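"""Samplers and the lambda-Hamiltonian replica-exchange harness.

The primary sampler is single-particle Metropolis Monte Carlo: its
stationary distribution is exactly the Boltzmann distribution of the
lambda-scaled Hamiltonian, which is what every statistical check in this
package leans on.  A BAOAB Langevin integrator is provided as a secondary
sampler for gas-phase systems; it carries finite-timestep bias and is not
used by any quantitative test.

Replica exchange couples the windows of a lambda schedule: neighbor pairs
of alternating parity attempt configuration swaps with the standard
acceptance min{1, exp(-beta[U_i(x_j) + U_j(x_i) - U_i(x_i) - U_j(x_j)])},
and every energy that enters a decision is logged.  Free energies per
adjacent window pair come from the accumulated forward/reverse energy
differences via BAR, and the whole protocol is repeated with distinct
seeds (four by default) to report mean +/- sample SD.

Seed policy: each (repeat, window) stream uses
``base_seed + 1000 * repeat + window``; the swap decisions of a repeat use
``base_seed + 1000 * repeat + 997``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB, beta_from_temperature
from .energy import (
    AlchemicalState,
    NonbondedSettings,
    drude_relax,
    energy_and_gradient,
    sampling_settings,
    total_energy,
)
from .estimators import FreeEnergyResult, WorkSampleSet, aggregate, bar
from .systems import Frame, SystemModel, ValidationError

__all__ = [
    "SamplerSettings",
    "LambdaSchedule",
    "ReplicaLog",
    "Replica",
    "make_lambda_schedule",
    "run_sampler",
    "run_langevin",
    "replica_exchange_sweep",
    "run_replica_exchange",
    "run_alchemical_leg",
    "LegResult",
]

DRUDE_MODES = ("scf_each_step", "lagged")

#: Full-scale swap interval (MD steps), kept as metadata; the desk-scale
#: default between swap attempts is 50 MC sweeps.
FULL_SCALE_SWAP_INTERVAL = 20000


@dataclass(frozen=True)
class SamplerSettings:
    """Monte Carlo / Langevin sampling controls.

    ``move_width`` is the full width (Angstrom) of the uniform
    single-particle MC displacement; ``timestep_fs``/``friction_per_ps``
    apply to the optional Langevin sampler.  ``swap_interval`` is the
    number of MC steps each replica takes between swap attempts.
    """

    temperature: float = 300.0
    n_steps: int = 1000
    save_interval: int = 10
    move_width: float = 0.3
    seed: int = 0
    drude_mode: str = "scf_each_step"
    burn_in: int = 0
    swap_interval: int = 50
    timestep_fs: float = 1.0
    friction_per_ps: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if not (self.n_steps >= self.save_interval >= 1):
            raise ValidationError("need n_steps >= save_interval >= 1")
        if self.drude_mode not in DRUDE_MODES:
            raise ValidationError(f"drude_mode must be one of {DRUDE_MODES}")

    @property
    def beta(self) -> float:
        return beta_from_temperature(self.temperature)


@dataclass(frozen=True)
class LambdaSchedule:
    """An ordered lambda grid for one annihilation stage."""

    stage: str
    ff_family: str
    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        lam = self.lambdas
        if len(lam) < 2 or lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValidationError("lambda schedule must run from 0 to 1")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValidationError("lambda schedule must be strictly increasing")

    def __len__(self) -> int:
        return len(self.lambdas)


_SCHEDULES = {
    # charge stage: three steps (four states) fixed, five steps (six states) Drude
    ("charge", "fixed"): (0.00, 0.20, 0.55, 1.00),
    ("charge", "drude"): (0.00, 0.10, 0.25, 0.50, 0.75, 1.00),
    # vdW stage: nine states fixed, eleven uniform states Drude
    ("vdw", "fixed"): (0.00, 0.15, 0.30, 0.45, 0.60, 0.75, 0.87, 0.96, 1.00),
    ("vdw", "drude"): tuple(round(0.1 * i, 1) for i in range(11)),
}


def make_lambda_schedule(stage: str, ff_family: str) -> LambdaSchedule:
    """The production lambda grids: charges are scaled off first, then the
    van der Waals interactions, with denser grids for the polarizable
    force-field family."""
    key = (stage, ff_family)
    if key not in _SCHEDULES:
        valid = sorted(set(k[0] for k in _SCHEDULES)), sorted(set(k[1] for k in _SCHEDULES))
        raise ValidationError(
            f"unknown schedule {key}; valid stages {valid[0]}, families {valid[1]}"
        )
    return LambdaSchedule(stage, ff_family, _SCHEDULES[key])


# ---------------------------------------------------------------------------
# Plain samplers
# ---------------------------------------------------------------------------


def _frame_energy(model, frame, state, settings, drude_mode):
    """Energy of a frame, relaxing Drude particles first in scf mode."""
    if len(model.polarizable_indices()) and drude_mode == "scf_each_step":
        relaxed, e = drude_relax(model, frame, state=state, settings=settings)
        return e, relaxed
    return total_energy(model, frame, state, settings), frame


def run_sampler(
    model: SystemModel,
    state: AlchemicalState,
    settings: SamplerSettings,
    start: Frame | None = None,
    nonbonded: NonbondedSettings | None = None,
) -> tuple[list[Frame], list[float]]:
    """Metropolis MC sampling of the lambda-scaled Hamiltonian.

    One step proposes a uniform displacement of one randomly chosen atom;
    frames are saved every ``save_interval`` accepted-or-rejected steps
    after ``burn_in``.  With ``drude_mode='scf_each_step'`` the Drude
    particles are relaxed before every energy use (cold-Drude limit); with
    ``'lagged'`` the previous displacements are carried unchanged,
    emulating extended-Lagrangian propagation.  Deterministic for a fixed
    seed.
    """
    if nonbonded is None:
        nonbonded = sampling_settings(model)
    if start is None:
        start = model.initial_frame
    if start is None:
        raise ValidationError("no start frame: model has no initial_frame")
    rng = np.random.default_rng(settings.seed)
    beta = settings.beta
    frame = start.copy()
    n_pol = len(model.polarizable_indices())
    if n_pol and frame.drude_displacements is None:
        frame.drude_displacements = np.zeros((n_pol, 3))
    if n_pol:  # both modes start from relaxed displacements
        frame, _ = drude_relax(model, frame, state=state, settings=nonbonded)
    energy, frame = _frame_energy(model, frame, state, nonbonded, settings.drude_mode)
    if not math.isfinite(energy):
        raise ValidationError(f"non-finite energy at start: {energy}")
    frames: list[Frame] = []
    energies: list[float] = []
    n = model.n_atoms
    w = settings.move_width
    for step in range(1, settings.n_steps + 1):
        atom = int(rng.integers(n))
        trial = frame.copy()
        trial.coordinates[atom] += rng.uniform(-w / 2.0, w / 2.0, size=3)
        try:
            e_trial, trial = _frame_energy(model, trial, state, nonbonded, settings.drude_mode)
        except (FloatingPointError, OverflowError):
            e_trial = math.inf
        if w == 0.0 or e_trial <= energy or rng.random() < math.exp(-beta * (e_trial - energy)):
            frame, energy = trial, e_trial
        if step > settings.burn_in and step % settings.save_interval == 0:
            saved = frame.copy()
            saved.step = step
            frames.append(saved)
            energies.append(energy)
    return frames, energies


def run_langevin(
    model: SystemModel,
    state: AlchemicalState,
    settings: SamplerSettings,
    start: Frame | None = None,
) -> tuple[list[Frame], list[float]]:
    """BAOAB Langevin dynamics for gas-phase systems (approximate sampler).

    Uses the analytic gradient; masses from the atom types; friction in
    1/ps and timestep in fs.  Finite-timestep bias makes this unsuitable
    for the quantitative statistical checks, which all use MC.
    """
    if model.is_periodic:
        raise ValidationError("the Langevin sampler supports gas-phase models only")
    nonbonded = sampling_settings(model)
    if start is None:
        start = model.initial_frame
    rng = np.random.default_rng(settings.seed)
    kbt = KB * settings.temperature
    # unit bookkeeping: with E in kcal/mol, x in A, m in amu and t in fs,
    # a = -grad/m needs the factor (kcal/mol)/(amu A) -> A/fs^2
    acc_unit = 4.184e-4
    masses = np.array([model.atom_type(i).mass for i in range(model.n_atoms)])
    dt = settings.timestep_fs
    gamma = settings.friction_per_ps * 1e-3  # 1/fs
    c1 = math.exp(-gamma * dt)
    frame = start.copy()
    x = frame.coordinates
    v = rng.normal(size=x.shape) * np.sqrt(kbt * acc_unit / masses)[:, None]
    _, g, _ = energy_and_gradient(model, frame, state, nonbonded)
    frames, energies = [], []
    for step in range(1, settings.n_steps + 1):
        v += -0.5 * dt * acc_unit * g / masses[:, None]
        x += 0.5 * dt * v
        v = c1 * v + np.sqrt((1 - c1 ** 2) * kbt * acc_unit / masses)[:, None] * rng.normal(
            size=v.shape
        )
        x += 0.5 * dt * v
        e, g, _ = energy_and_gradient(model, frame, state, nonbonded)
        v += -0.5 * dt * acc_unit * g / masses[:, None]
        if step > settings.burn_in and step % settings.save_interval == 0:
            saved = frame.copy()
            saved.step = step
            frames.append(saved)
            energies.append(e + 0.5 / acc_unit * float(np.sum(masses[:, None] * v ** 2)))
    return frames, energies


# ---------------------------------------------------------------------------
# Replica exchange
# ---------------------------------------------------------------------------


@dataclass
class Replica:
    """One replica: a traveling id, its configuration, and its energy at
    the lambda state it currently occupies."""

    replica_id: int
    config: np.ndarray
    energy: float


@dataclass
class ReplicaLog:
    """Per-sweep exchange bookkeeping.

    Each record holds the sweep index, the replica -> state permutation
    after the sweep, and per attempted pair the four energies that entered
    the acceptance rule plus the outcome.
    """

    records: list[dict] = field(default_factory=list)

    def append(self, sweep: int, permutation: Sequence[int], attempts: list[dict]) -> None:
        perm = tuple(int(p) for p in permutation)
        if sorted(perm) != list(range(len(perm))):
            raise ValidationError("replica->state mapping must be a bijection")
        self.records.append({"sweep": sweep, "permutation": perm, "attempts": attempts})

    @property
    def n_attempts(self) -> int:
        return sum(len(r["attempts"]) for r in self.records)

    @property
    def n_accepted(self) -> int:
        return sum(a["accepted"] for r in self.records for a in r["attempts"])

    def acceptance_rate(self) -> float:
        n = self.n_attempts
        return self.n_accepted / n if n else float("nan")


def replica_exchange_sweep(
    replicas: list[Replica],
    energy_of: Callable[[int, np.ndarray], float],
    beta: float,
    sweep_parity: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Attempt neighbor swaps for all pairs of the given parity.

    ``replicas`` is ordered by lambda state; ``energy_of(s, x)`` evaluates
    state s's Hamiltonian on configuration x.  Swaps exchange
    configurations (and replica ids) between adjacent states with
    acceptance min{1, exp(-beta * delta)} where delta is the symmetric
    cross-energy difference.  Returns the attempt records; mutates
    ``replicas`` in place.
    """
    attempts = []
    for s in range(sweep_parity % 2, len(replicas) - 1, 2):
        lo, hi = replicas[s], replicas[s + 1]
        u_ll, u_hh = lo.energy, hi.energy
        u_lh = energy_of(s, hi.config)  # state s on the upper config
        u_hl = energy_of(s + 1, lo.config)
        delta = (u_lh + u_hl) - (u_ll + u_hh)
        accepted = delta <= 0.0 or rng.random() < math.exp(-beta * delta)
        if accepted:
            replicas[s], replicas[s + 1] = (
                Replica(hi.replica_id, hi.config, u_lh),
                Replica(lo.replica_id, lo.config, u_hl),
            )
        attempts.append(
            {
                "state_lo": s,
                "state_hi": s + 1,
                "u_lo_lo": u_ll,
                "u_lo_hi": u_lh,
                "u_hi_lo": u_hl,
                "u_hi_hi": u_hh,
                "accepted": bool(accepted),
            }
        )
    return attempts


def _mc_sweep(
    replica: Replica,
    s: int,
    energy_of,
    propose,
    beta: float,
    n_steps: int,
    rng: np.random.Generator,
) -> Replica:
    x, e = replica.config, replica.energy
    for _ in range(n_steps):
        x_new = propose(x, rng)
        e_new = energy_of(s, x_new)
        if e_new <= e or rng.random() < math.exp(-beta * (e_new - e)):
            x, e = x_new, e_new
    return Replica(replica.replica_id, x, e)


def run_replica_exchange(
    energy_of: Callable[[int, np.ndarray], float],
    n_states: int,
    x0: np.ndarray,
    beta: float,
    propose: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    n_sweeps: int,
    steps_per_sweep: int,
    base_seed: int = 0,
    burn_in_sweeps: int = 0,
) -> tuple[list[WorkSampleSet], ReplicaLog]:
    """Generic lambda-replica-exchange driver.

    Runs ``n_states`` coupled Metropolis chains (per-window RNG streams
    seeded ``base_seed + window``), attempting neighbor swaps of
    alternating parity after every sweep of ``steps_per_sweep`` MC steps.
    After each post-burn-in sweep the forward/reverse energy differences of
    every adjacent window pair are accumulated; these become per-window
    :class:`WorkSampleSet` objects ready for BAR.  The third return value
    holds the post-burn-in configurations visited at each lambda state
    (one per sweep), for distributional checks.
    """
    if n_states < 2:
        raise ValidationError("replica exchange needs at least 2 lambda states")
    rngs = [np.random.default_rng(base_seed + s) for s in range(n_states)]
    swap_rng = np.random.default_rng(base_seed + 997)
    replicas = [
        Replica(s, np.array(x0, dtype=float, copy=True), energy_of(s, np.asarray(x0, float)))
        for s in range(n_states)
    ]
    fwd: list[list[float]] = [[] for _ in range(n_states - 1)]
    rev: list[list[float]] = [[] for _ in range(n_states - 1)]
    configs: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    log = ReplicaLog()
    for sweep in range(n_sweeps):
        for s in range(n_states):
            replicas[s] = _mc_sweep(
                replicas[s], s, energy_of, propose, beta, steps_per_sweep, rngs[s]
            )
        if sweep >= burn_in_sweeps:
            for w in range(n_states - 1):
                lo, hi = replicas[w], replicas[w + 1]
                fwd[w].append(energy_of(w + 1, lo.config) - lo.energy)
                rev[w].append(energy_of(w, hi.config) - hi.energy)
            for s in range(n_states):
                configs[s].append(replicas[s].config.copy())
        attempts = replica_exchange_sweep(replicas, energy_of, beta, sweep, swap_rng)
        state_of_replica = [0] * n_states
        for s, rep in enumerate(replicas):
            state_of_replica[rep.replica_id] = s
        log.append(sweep, state_of_replica, attempts)
    samples = [
        WorkSampleSet(np.array(fwd[w]), np.array(rev[w]), beta=beta)
        for w in range(n_states - 1)
    ]
    return samples, log, [np.array(c) for c in configs]


# ---------------------------------------------------------------------------
# Alchemical legs
# ---------------------------------------------------------------------------


@dataclass
class LegResult:
    """An annihilation leg: aggregated total plus per-stage totals and the
    raw per-repeat, per-window sample sets."""

    result: FreeEnergyResult
    stage_totals: dict[str, FreeEnergyResult]
    samples: dict[str, list[list[WorkSampleSet]]]  # stage -> [repeat][window]

    @property
    def delta_g(self) -> float:
        return self.result.delta_g

    @property
    def std_dev(self) -> float:
        return self.result.std_dev


def _stage_state(stage: str, lam: float) -> AlchemicalState:
    if stage == "charge":
        return AlchemicalState(lambda_elec=lam, lambda_vdw=0.0)
    if stage == "vdw":
        return AlchemicalState(lambda_elec=1.0, lambda_vdw=lam)
    raise ValidationError(f"unknown stage {stage!r}")


def run_alchemical_leg(
    model: SystemModel,
    schedules: Sequence[LambdaSchedule],
    settings: SamplerSettings,
    n_repeats: int = 4,
    nonbonded: NonbondedSettings | None = None,
    start: Frame | None = None,
) -> LegResult:
    """Annihilate a solute along staged lambda schedules with replica
    exchange, estimating each window by BAR and aggregating over repeats.

    ``schedules`` lists the stages in protocol order (charge stage before
    vdW).  Each repeat r runs every window with seed
    ``settings.seed + 1000 r + window`` and the repeat statistics are the
    mean and sample SD of the repeat totals.
    """
    if nonbonded is None:
        nonbonded = sampling_settings(model)
    if start is None:
        start = model.initial_frame
    if start is None:
        raise ValidationError("no start frame available")
    n_pol = len(model.polarizable_indices())

    def make_energy_of(stage: str, lambdas: tuple[float, ...]):
        states = [_stage_state(stage, lam) for lam in lambdas]

        def energy_of(s: int, coords: np.ndarray) -> float:
            frame = Frame(coords.reshape(-1, 3), np.zeros((n_pol, 3)) if n_pol else None)
            if n_pol and settings.drude_mode == "scf_each_step":
                _, e = drude_relax(model, frame, state=states[s], settings=nonbonded)
                return e
            return total_energy(model, frame, states[s], nonbonded)

        return energy_of

    w = settings.move_width

    def propose(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x_new = x.copy()
        atom = int(rng.integers(len(x_new) // 3))
        x_new[3 * atom : 3 * atom + 3] += rng.uniform(-w / 2.0, w / 2.0, size=3)
        return x_new

    n_sweeps = max(1, settings.n_steps // settings.swap_interval)
    burn_sweeps = settings.burn_in // settings.swap_interval
    x0 = start.coordinates.ravel()

    stage_samples: dict[str, list[list[WorkSampleSet]]] = {}
    stage_results: dict[str, FreeEnergyResult] = {}
    all_window_results: list[list[FreeEnergyResult]] = [[] for _ in range(n_repeats)]
    window_offset = 0
    for schedule in schedules:
        energy_of = make_energy_of(schedule.stage, schedule.lambdas)
        per_repeat_samples: list[list[WorkSampleSet]] = []
        per_repeat_windows: list[list[FreeEnergyResult]] = []
        for repeat in range(n_repeats):
            base = settings.seed + 1000 * repeat + window_offset
            samples, _, _ = run_replica_exchange(
                energy_of,
                len(schedule),
                x0,
                settings.beta,
                propose,
                n_sweeps,
                settings.swap_interval,
                base_seed=base,
                burn_in_sweeps=burn_sweeps,
            )
            window_results = []
            for wdx, s in enumerate(samples):
                r = bar(s)
                r.per_window[0].window = f"{schedule.stage}:{wdx}"
                window_results.append(r)
            per_repeat_samples.append(samples)
            per_repeat_windows.append(window_results)
            all_window_results[repeat].extend(window_results)
        stage_samples[schedule.stage] = per_repeat_samples
        stage_results[schedule.stage] = aggregate(per_repeat_windows)
        window_offset += len(schedule)
    total = aggregate(all_window_results)
    total.provenance.update(
        {
            "seed": settings.seed,
            "n_repeats": n_repeats,
            "softcore_delta": nonbonded.softcore_delta,
            "schedules": [
                {"stage": s.stage, "ff_family": s.ff_family, "lambdas": list(s.lambdas)}
                for s in schedules
            ],
            "temperature": settings.temperature,
        }
    )
    return LegResult(total, stage_results, stage_samples)
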