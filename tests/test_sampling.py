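"""Sampler statistics, lambda schedules, and replica-exchange bookkeeping."""

import numpy as np
import pytest
from scipy import stats

import bookend as bk
from bookend.constants import KB, UNIT_REDUCED_TEMPERATURE
from bookend.energy import AlchemicalState, FULLY_INTERACTING
from bookend.sampling import (
    Replica,
    SamplerSettings,
    make_lambda_schedule,
    replica_exchange_sweep,
    run_alchemical_leg,
    run_replica_exchange,
    run_sampler,
)
from bookend.systems import ValidationError


def harmonic_energy_of(lambdas, k0=1.0, k1=4.0):
    """1-dof energy interpolating K(lambda) = k0 (1 - lambda) + k1 lambda."""

    def energy_of(s, x):
        k = k0 * (1 - lambdas[s]) + k1 * lambdas[s]
        return k * float(x[0] * x[0])

    return energy_of


def propose_1d(width=1.5):
    def propose(x, rng):
        return x + rng.uniform(-width, width, size=x.shape)

    return propose


class TestSchedules:
    def test_printed_grids(self):
        assert make_lambda_schedule("charge", "fixed").lambdas == (0.0, 0.20, 0.55, 1.0)
        assert make_lambda_schedule("charge", "drude").lambdas == (
            0.0, 0.10, 0.25, 0.50, 0.75, 1.0,
        )
        vf = make_lambda_schedule("vdw", "fixed").lambdas
        assert len(vf) == 9 and vf[-3:] == (0.87, 0.96, 1.0)
        vd = make_lambda_schedule("vdw", "drude").lambdas
        assert len(vd) == 11
        np.testing.assert_allclose(np.diff(vd), 0.1)

    def test_unknown_tag_lists_valid(self):
        with pytest.raises(ValidationError, match="charge"):
            make_lambda_schedule("nope", "fixed")

    def test_schedule_invariants_enforced(self):
        from bookend.sampling import LambdaSchedule

        with pytest.raises(ValidationError):
            LambdaSchedule("charge", "fixed", (0.0, 0.5, 0.4, 1.0))
        with pytest.raises(ValidationError):
            LambdaSchedule("charge", "fixed", (0.1, 1.0))


class TestRunSampler:
    def test_zero_width_proposal_identity(self, triatomic):
        settings = SamplerSettings(
            temperature=300.0, n_steps=50, save_interval=5, move_width=0.0, seed=1
        )
        frames, energies = run_sampler(triatomic, FULLY_INTERACTING, settings)
        assert len(frames) == 10
        for f in frames:
            np.testing.assert_array_equal(
                f.coordinates, triatomic.initial_frame.coordinates
            )
        assert len(set(energies)) == 1

    def test_deterministic_for_fixed_seed(self, triatomic):
        settings = SamplerSettings(n_steps=200, save_interval=20, seed=9)
        f1, e1 = run_sampler(triatomic, FULLY_INTERACTING, settings)
        f2, e2 = run_sampler(triatomic, FULLY_INTERACTING, settings)
        assert e1 == e2
        np.testing.assert_array_equal(f1[-1].coordinates, f2[-1].coordinates)

    def test_equipartition_mean_bond_energy(self):
        # one harmonic bond ~ one quadratic dof: <U> = kT/2 within 3 SE
        spec = bk.SoluteSpec(
            "d", charges=[0.0, 0.0], lj_epsilon=0.0, lj_rmin_half=1.0,
            bonds=[(0, 1)], bond_k=300.0, bond_b0=1.2,
        )
        m = bk.build_solute(spec, seed=0)
        kt = KB * 300.0
        settings = SamplerSettings(
            temperature=300.0, n_steps=60000, save_interval=20, move_width=0.12,
            seed=21, burn_in=2000,
        )
        _, energies = run_sampler(m, FULLY_INTERACTING, settings)
        e = np.asarray(energies)
        # batch means for a defensible SE under autocorrelation
        batches = e[: len(e) // 10 * 10].reshape(10, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(e.mean() - kt / 2) < 3 * max(se, 1e-4)

    def test_nonfinite_start_rejected(self, triatomic):
        f = triatomic.initial_frame.copy()
        f.coordinates = f.coordinates.copy()
        f.coordinates[0, 0] = np.nan
        with pytest.raises(Exception):
            run_sampler(triatomic, FULLY_INTERACTING, SamplerSettings(n_steps=10,
                        save_interval=1), start=f)


class TestLangevin:
    def test_gas_phase_trajectory_is_finite_and_bounded(self, triatomic):
        from bookend.sampling import run_langevin

        frames, energies = run_langevin(
            triatomic, FULLY_INTERACTING,
            SamplerSettings(n_steps=500, save_interval=50, seed=3),
        )
        assert len(frames) == 10
        assert np.all(np.isfinite(energies))
        assert np.all(np.isfinite(frames[-1].coordinates))

    def test_periodic_model_rejected(self, small_box):
        from bookend.sampling import run_langevin

        with pytest.raises(ValidationError):
            run_langevin(small_box, FULLY_INTERACTING, SamplerSettings(n_steps=10,
                         save_interval=1))


class TestReplicaExchangeSweep:
    def test_identical_hamiltonians_always_accept(self):
        energy_of = lambda s, x: float(x[0] ** 2)
        rng = np.random.default_rng(0)
        for parity in (0, 1):
            replicas = [Replica(s, np.array([0.1 * s]), energy_of(s, np.array([0.1 * s])))
                        for s in range(4)]
            attempts = replica_exchange_sweep(replicas, energy_of, 1.0, parity, rng)
            assert all(a["accepted"] for a in attempts)

    def test_acceptance_symmetric_under_pair_swap(self):
        # delta is symmetric in (i, j): recompute both orderings explicitly
        k = [1.0, 3.0]
        energy_of = lambda s, x: k[s] * float(x[0] ** 2)
        xi, xj = np.array([0.4]), np.array([1.1])
        d_ij = energy_of(0, xj) + energy_of(1, xi) - energy_of(0, xi) - energy_of(1, xj)
        d_ji = energy_of(1, xi) + energy_of(0, xj) - energy_of(1, xj) - energy_of(0, xi)
        assert d_ij == pytest.approx(d_ji)

    def test_log_energies_reproduce_recomputation(self):
        lambdas = [0.0, 0.5, 1.0]
        energy_of = harmonic_energy_of(lambdas)
        samples, log, configs = run_replica_exchange(
            energy_of, 3, np.array([0.3]), 1.0, propose_1d(), 20, 5, base_seed=3
        )
        # permutations stay bijections and the logged energies are exact
        for record in log.records:
            assert sorted(record["permutation"]) == [0, 1, 2]
        assert log.n_attempts > 0

    def test_acceptance_rate_matches_quadrature(self):
        """Empirical swap acceptance for k=1 vs k=2 matches the analytic
        expectation <min(1, exp(-beta delta))> under independent sampling."""
        k1, k2, beta = 1.0, 2.0, 1.0
        lambdas = [0.0, 1.0]
        energy_of = harmonic_energy_of(lambdas, k1, k2)
        n_sweeps = 10000
        _, log, _ = run_replica_exchange(
            energy_of, 2, np.zeros(1), beta, propose_1d(2.0), n_sweeps, 8, base_seed=12
        )
        rate = log.acceptance_rate()

        # quadrature oracle: x1 ~ N(0, 1/(2 b k1)), x2 ~ N(0, 1/(2 b k2)),
        # delta = (k1 - k2)(x2^2 - x1^2)
        from scipy import integrate

        s1 = np.sqrt(1 / (2 * beta * k1))
        s2 = np.sqrt(1 / (2 * beta * k2))

        def inner(x1):
            f = lambda x2: (
                np.minimum(1.0, np.exp(-beta * (k1 - k2) * (x2 ** 2 - x1 ** 2)))
                * stats.norm.pdf(x2, scale=s2)
            )
            return integrate.quad(f, -8 * s2, 8 * s2, limit=200)[0]

        xs = np.linspace(-8 * s1, 8 * s1, 301)
        expected = np.trapezoid(
            [inner(x) * stats.norm.pdf(x, scale=s1) for x in xs], xs
        )
        se = np.sqrt(expected * (1 - expected) / n_sweeps)
        assert abs(rate - expected) < 3 * se

    def test_two_state_occupancy_detailed_balance(self):
        """Each replica of a symmetric 2-state system spends half its time
        in each state (uniform permutation distribution)."""
        lambdas = [0.0, 1.0]
        energy_of = harmonic_energy_of(lambdas, 1.0, 2.0)
        n_sweeps = 4000
        _, log, _ = run_replica_exchange(
            energy_of, 2, np.zeros(1), 1.0, propose_1d(2.0), n_sweeps, 10, base_seed=31
        )
        frac = np.mean([r["permutation"][0] == 0 for r in log.records])
        se = 0.5 / np.sqrt(n_sweeps)  # upper bound on binomial SE
        # swaps decorrelate quickly at ~0.9 acceptance; allow 4x the iid SE
        assert abs(frac - 0.5) < 12 * se

    def test_boltzmann_marginal_ks(self):
        """KS test of the sampled 1-dof marginal against the analytic
        Gaussian passes at alpha = 0.001 for n = 10^4."""
        lambdas = [0.0, 1.0]
        k0 = 1.0
        energy_of = harmonic_energy_of(lambdas, k0, 2.0)
        _, _, configs = run_replica_exchange(
            energy_of, 2, np.zeros(1), 1.0, propose_1d(2.0), 10000, 10, base_seed=41,
            burn_in_sweeps=100,
        )
        x = configs[0][:, 0]
        assert len(x) >= 9000
        p = stats.kstest(x, "norm", args=(0.0, np.sqrt(1 / (2 * k0)))).pvalue
        assert p > 0.001


class TestAlchemicalLeg:
    def test_noninteracting_solute_zero_leg(self):
        spec = bk.SoluteSpec(
            "ghost", charges=[0.0, 0.0], lj_epsilon=0.0, lj_rmin_half=1.0,
            bonds=[(0, 1)], bond_k=300.0, bond_b0=1.2,
        )
        m = bk.build_solute(spec, seed=2)
        settings = SamplerSettings(
            temperature=300.0, n_steps=200, save_interval=10, move_width=0.2,
            seed=5, swap_interval=20,
        )
        schedules = [make_lambda_schedule("charge", "fixed"),
                     make_lambda_schedule("vdw", "fixed")]
        leg = run_alchemical_leg(m, schedules, settings, n_repeats=2)
        assert leg.delta_g == pytest.approx(0.0, abs=1e-12)
        assert leg.std_dev == pytest.approx(0.0, abs=1e-12)

    def test_charged_solute_charge_stage_nonzero(self):
        # a 4-atom chain has a non-excluded 1-4 pair, so intra-solute
        # electrostatics make the gas-phase charge leg finite
        spec = bk.SoluteSpec(
            "dip", charges=[0.35, 0.0, 0.0, -0.35], lj_epsilon=0.05, lj_rmin_half=1.2,
            bonds=[(0, 1), (1, 2), (2, 3)], bond_k=250.0, bond_b0=1.4,
        )
        m = bk.build_solute(spec, seed=3)
        settings = SamplerSettings(
            temperature=UNIT_REDUCED_TEMPERATURE, n_steps=600, save_interval=10,
            move_width=0.25, seed=8, swap_interval=30, burn_in=60,
        )
        leg = run_alchemical_leg(m, [make_lambda_schedule("charge", "fixed")], n_repeats=2,
                                 settings=settings)
        assert leg.delta_g != pytest.approx(0.0, abs=1e-6)
        assert "charge" in leg.stage_totals

    def test_determinism_and_repeat_structure(self):
        spec = bk.SoluteSpec(
            "d2", charges=[0.2, 0.0, 0.0, -0.2], lj_epsilon=0.02, lj_rmin_half=1.2,
            bonds=[(0, 1), (1, 2), (2, 3)], bond_k=300.0, bond_b0=1.3,
        )
        m = bk.build_solute(spec, seed=4)
        settings = SamplerSettings(n_steps=100, save_interval=10, move_width=0.2,
                                   seed=6, swap_interval=20)
        sched = [make_lambda_schedule("charge", "fixed")]
        a = run_alchemical_leg(m, sched, settings, n_repeats=2)
        b = run_alchemical_leg(m, sched, settings, n_repeats=2)
        assert a.delta_g == b.delta_g
        assert a.result.provenance["repeat_totals"] == b.result.provenance["repeat_totals"]
        # distinct repeats use distinct seeds -> totals differ
        totals = a.result.provenance["repeat_totals"]
        assert totals[0] != totals[1]

    def test_single_state_schedule_rejected(self):
        spec = bk.SoluteSpec("x", charges=[0.0])
        m = bk.build_solute(spec, seed=0)
        from bookend.sampling import LambdaSchedule

        with pytest.raises(ValidationError):
            LambdaSchedule("charge", "fixed", (0.0,))

    def test_interpolated_harmonic_recovers_partition_ratio(self):
        """Replica-exchange BAR on K(lambda) = k0(1-lambda) + k1 lambda
        recovers (1/2 beta) ln(k1/k0)."""
        k0, k1 = 1.0, 4.0
        lambdas = [0.0, 0.3, 0.6, 1.0]
        energy_of = harmonic_energy_of(lambdas, k0, k1)
        from bookend.estimators import aggregate, bar

        reps = []
        for rep in range(4):
            samples, _, _ = run_replica_exchange(
                energy_of, 4, np.zeros(1), 1.0, propose_1d(), 700, 10,
                base_seed=1000 * rep + 3, burn_in_sweeps=50,
            )
            reps.append([bar(s) for s in samples])
        agg = aggregate(reps)
        truth = 0.5 * np.log(k1 / k0)
        se = agg.std_dev / np.sqrt(agg.n_repeats)
        assert abs(agg.delta_g - truth) < 3 * max(se, 5e-3)
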