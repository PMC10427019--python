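import dataclasses
import math

import numpy as np
import pytest

from conftest import gaussian_target_1d

from mlfit.adaptive import ScalingConfig, accumulate_work
from mlfit.grids import AtomSet, DensityGrid
from mlfit.spreading import SpreadParams, spread_density
from mlfit.toysim import (
    Benchmark1D,
    ToySystem,
    _run_arm,
    brownian_step,
    default_benchmark,
    forcefield_energy_forces,
    kinked_positions,
    landscape_scan,
    local_minima_2d,
    make_bead_helix,
    make_kinked_target,
    perturbed,
    run_refinement,
    suggest_fmax,
)


class TestBrownianStep:
    def test_no_noise_no_force_is_identity(self):
        sys0 = ToySystem(AtomSet([[1.0, 2.0, 3.0]]), kT=0.0)
        out = brownian_step(sys0, np.zeros((1, 3)), np.random.default_rng(0))
        np.testing.assert_array_equal(out, [[1.0, 2.0, 3.0]])

    def test_deterministic_drift(self):
        sys0 = ToySystem(AtomSet([[0.0, 0.0, 0.0]]), kT=0.0, gamma=2.0, dt=0.1)
        F = np.array([[4.0, 0.0, -2.0]])
        out = brownian_step(sys0, F, np.random.default_rng(0))
        np.testing.assert_allclose(out, [[0.2, 0.0, -0.1]])

    def test_einstein_relation(self):
        """Free diffusion MSD per coordinate = 2*(kT/gamma)*t."""
        n_rep, n_steps, dt = 1000, 10000, 1e-3
        rng = np.random.default_rng(7)
        x = np.zeros((n_rep, 3))
        for _ in range(n_steps):
            x = brownian_step(ToySystem(AtomSet(x), kT=1.0, gamma=1.0, dt=dt),
                              np.zeros_like(x), rng)
        msd = float(np.mean(x**2))
        assert msd == pytest.approx(2.0 * n_steps * dt, rel=0.05)

    def test_nonfinite_force_rejected(self):
        sys0 = ToySystem(AtomSet([[0.0, 0.0, 0.0]]))
        with pytest.raises(FloatingPointError):
            brownian_step(sys0, np.array([[np.nan, 0, 0]]), np.random.default_rng(0))


class TestForceField:
    def test_bond_and_angle_forces_match_finite_differences(self, rng):
        pos = rng.normal(size=(5, 3)) * 2
        system = ToySystem(
            AtomSet(pos),
            bonds=[(0, 1, 10.0, 1.5), (1, 2, 8.0, 2.0), (3, 4, 5.0, 1.0)],
            angles=[(0, 1, 2, 6.0, 1.9), (2, 3, 4, 4.0, 2.1)],
        )
        U0, F = forcefield_energy_forces(system, pos)
        h = 1e-6
        for i in range(5):
            for ax in range(3):
                p = pos.copy()
                p[i, ax] += h
                up, _ = forcefield_energy_forces(system, p)
                p[i, ax] -= 2 * h
                dn, _ = forcefield_energy_forces(system, p)
                assert F[i, ax] == pytest.approx(-(up - dn) / (2 * h), rel=1e-5, abs=1e-7)

    def test_bond_length_variance_matches_boltzmann(self):
        """Unbiased sampling of one harmonic bond reproduces the analytic
        bond-length variance of p(r) ~ r^2 exp(-k(r-r0)^2/2kT)."""
        kb, r0, kT, dt = 50.0, 2.0, 1.0, 5e-4
        system = ToySystem(AtomSet([[0, 0, 0], [r0, 0, 0]]), bonds=[(0, 1, kb, r0)],
                           kT=kT, gamma=1.0, dt=dt)
        rng = np.random.default_rng(3)
        x = system.atoms.positions
        rs = []
        for i in range(100_000):
            _, F = forcefield_energy_forces(system, x)
            x = brownian_step(dataclasses.replace(system, atoms=AtomSet(x)), F, rng)
            if i > 2000 and i % 10 == 0:
                rs.append(np.linalg.norm(x[1] - x[0]))
        rs = np.asarray(rs)
        rr = np.linspace(r0 - 6 * math.sqrt(kT / kb), r0 + 6 * math.sqrt(kT / kb), 4001)
        w = rr**2 * np.exp(-kb * (rr - r0) ** 2 / (2 * kT))
        mean = np.trapezoid(rr * w, rr) / np.trapezoid(w, rr)
        var = np.trapezoid((rr - mean) ** 2 * w, rr) / np.trapezoid(w, rr)
        assert rs.var() == pytest.approx(var, rel=0.05)


def _target_1d(mu=0.0, sigma=1.0):
    return gaussian_target_1d([mu], sigma=sigma)


class TestRunRefinement:
    def test_identical_seeds_identical_trajectories(self):
        target = _target_1d()
        system = ToySystem(AtomSet([[4.0, 0, 0]]), kT=0.01, dt=1e-3)
        cfg = ScalingConfig(alpha=0.01, k_init=0.1, f_max=1e6)
        params = SpreadParams(1.0, 4.0, normalize=True)
        a = run_refinement(system, target, "re", cfg, 300, seed=5, spread_params=params)
        b = run_refinement(system, target, "re", cfg, 300, seed=5, spread_params=params)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.S, b.S)

    def test_negligible_force_constant_matches_unbiased_dynamics(self):
        """With a vanishing force constant the trajectory is pure unbiased
        Brownian dynamics: the bias adds exactly zero displacement."""
        target = _target_1d()
        system = ToySystem(AtomSet([[4.0, 0, 0]]), kT=0.5, dt=1e-3)
        params = SpreadParams(1.0, 4.0, normalize=True)
        cfg = ScalingConfig(alpha=1e-9, k_init=1e-300, f_max=np.inf)
        biased = run_refinement(system, target, "re", cfg, 400, seed=9,
                                spread_params=params, adaptive_scaling=False)
        rng = np.random.default_rng(9)
        x = system.atoms.positions.copy()
        free = [x.copy()]
        for _ in range(399):
            x = brownian_step(dataclasses.replace(system, atoms=AtomSet(x)),
                              np.zeros_like(x), rng)
            free.append(x.copy())
        np.testing.assert_array_equal(biased.positions, np.asarray(free))

    def test_work_column_reproducible_from_logs(self):
        target = _target_1d()
        system = ToySystem(AtomSet([[4.0, 0, 0]]), kT=0.01, dt=1e-3)
        cfg = ScalingConfig(alpha=0.01, k_init=0.1, f_max=1e6)
        traj = run_refinement(system, target, "re", cfg, 500, seed=2,
                              spread_params=SpreadParams(1.0, 4.0, normalize=True))
        assert traj.W[-1] == pytest.approx(traj.work(), rel=1e-12, abs=1e-12)

    def test_long_range_convergence_from_five_sigma(self):
        """A particle 5 sigma from a Gaussian target converges under the
        relative-entropy potential with adaptive scaling."""
        target = _target_1d()
        system = ToySystem(AtomSet([[5.0, 0, 0]]), kT=0.01, dt=1e-3)
        cfg = ScalingConfig(alpha=0.01, ema_weight=0.1, k_init=0.1, f_max=20.0)
        traj = run_refinement(system, target, "re", cfg, 15_000, seed=0,
                              spread_params=SpreadParams(1.0, 4.0, normalize=True))
        assert abs(traj.positions[-1][0, 0]) < 0.1

    def test_inner_product_short_range_stall(self):
        """Inner product with a small fixed force constant exerts almost no
        force outside the Gaussian spread width: the particle stays put."""
        target = _target_1d()
        system = ToySystem(AtomSet([[5.0, 0, 0]]), kT=0.01, dt=1e-3)
        cfg = ScalingConfig(alpha=1e-9, ema_weight=0.1, k_init=0.1, f_max=1e6)
        traj = run_refinement(system, target, "ip", cfg, 10_000, seed=0,
                              spread_params=SpreadParams(1.0, 4.0), n_fit=1,
                              adaptive_scaling=False)
        assert abs(traj.positions[-1][0, 0]) > 4.0


class TestLandscapes:
    sigma = 1.0
    spacing = 0.25

    def _two_peak_target(self):
        centers, amps = [-3.0, 3.0], [1.0, 2.0]
        return gaussian_target_1d(centers, amps, sigma=self.sigma,
                                  spacing=self.spacing, x_min=-20, x_max=20)

    def test_inner_product_minimum_at_coincident_highest_peak(self):
        target = self._two_peak_target()
        system = ToySystem(AtomSet([[0.0, 0, 0], [0.0, 0, 0]]))
        scan = np.linspace(-8, 8, 33)
        res = landscape_scan(system, target, "ip", scan, bond_weight=0.0,
                             spread_params=SpreadParams(self.sigma, 4.0))
        assert len(res.minima) == 1
        np.testing.assert_allclose(res.minima[0], [3.0, 3.0], atol=0.5)

    def test_relative_entropy_two_swap_symmetric_minima(self):
        target = self._two_peak_target()
        system = ToySystem(AtomSet([[0.0, 0, 0], [0.0, 0, 0]]))
        scan = np.linspace(-8, 8, 33)
        res = landscape_scan(system, target, "re", scan, bond_weight=0.0,
                             spread_params=SpreadParams(self.sigma, 8.0, normalize=True))
        mins = sorted(map(tuple, np.round(res.minima, 6).tolist()))
        assert len(mins) == 2
        np.testing.assert_allclose(mins[0], [-3.0, 3.0], atol=0.5)
        np.testing.assert_allclose(mins[1], [3.0, -3.0], atol=0.5)
        # a single swap barrier: exactly the two assignment minima
        assert len(local_minima_2d(res.values)) == 2

    def test_single_particle_relative_entropy_is_quadratic(self):
        target = gaussian_target_1d([0.0], sigma=self.sigma, spacing=0.2)
        system = ToySystem(AtomSet([[0.0, 0, 0]]))
        scan = np.linspace(-3, 3, 41)
        res = landscape_scan(system, target, "re", scan, bond_weight=0.0,
                             spread_params=SpreadParams(self.sigma, 8.0, normalize=True))
        coef = np.polyfit(scan, res.values, 2)
        resid = res.values - np.polyval(coef, scan)
        assert np.abs(resid).max() < 0.01 * np.ptp(res.values)
        # continuum curvature: U = (x-mu)^2 / (2 sigma^2)
        assert coef[0] == pytest.approx(1 / (2 * self.sigma**2), rel=1e-3)

    def test_swapped_and_plain_relative_entropy_agree_for_one_particle(self):
        """For the single-particle 1D case the two maximum-likelihood
        potentials have the same analytic (harmonic) form up to offset."""
        # wide target truncation so the continuum (infinite-support) limit
        # applies over the scanned window
        target = gaussian_target_1d([0.0], sigma=self.sigma, spacing=0.2, cutoff=12.0)
        system = ToySystem(AtomSet([[0.0, 0, 0]]))
        scan = np.linspace(-2, 2, 21)
        params = SpreadParams(self.sigma, 8.0, normalize=True)
        u_re = landscape_scan(system, target, "re", scan, 0.0, spread_params=params).values
        u_res = landscape_scan(system, target, "res", scan, 0.0, spread_params=params).values
        np.testing.assert_allclose(u_re - u_re.min(), u_res - u_res.min(), atol=2e-3)

    def test_three_particles_rejected(self):
        target = _target_1d()
        system = ToySystem(AtomSet(np.zeros((3, 3))))
        with pytest.raises(ValueError):
            landscape_scan(system, target, "re", np.linspace(-1, 1, 3), 0.0,
                           spread_params=SpreadParams(1.0))


class TestBenchmark:
    def test_flat_potential_same_bias_reproducible_mfpt(self):
        """On a flat landscape two identically biased arms (different noise
        streams) give statistically indistinguishable MFPTs."""
        flat = Benchmark1D(lambda x: np.zeros_like(x), lambda x: np.zeros_like(x),
                           0.0, 5.0, kT=0.05, gamma=1.0, dt=1e-2, max_steps=100_000)
        f1, _, m1, _ = _run_arm(flat, 50, seed=1, k_fixed=0.5)
        f2, _, m2, _ = _run_arm(flat, 50, seed=2, k_fixed=0.5)
        assert m1 == m2 == 0
        se = np.std(f1, ddof=1) / math.sqrt(len(f1))
        assert abs(np.mean(f1) - np.mean(f2)) < 4 * se

    def test_work_recomputation_from_traces(self):
        bench, cfg = default_benchmark()
        fpt, work, _, traces = _run_arm(bench, 4, seed=3, config=cfg, n_traced=4)
        for r, (k_tr, s_tr) in enumerate(traces):
            assert work[r] == pytest.approx(accumulate_work(k_tr, s_tr), rel=1e-12)


class TestBeadHelix:
    def test_bond_lengths_equal_by_construction(self):
        system = make_bead_helix(20)
        pos = system.atoms.positions
        r0 = system.bonds[0][3]
        lengths = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        np.testing.assert_allclose(lengths, r0, atol=1e-9)

    def test_zero_kink_target_equals_straight_spread(self):
        system = make_bead_helix(12)
        target = make_kinked_target(system, 0.0, sigma=2.0, spacing=1.0)
        straight = spread_density(system.atoms, target, SpreadParams(2.0))
        np.testing.assert_allclose(target.values, straight.values, atol=1e-12)

    def test_kink_moves_only_upper_half(self):
        system = make_bead_helix(10)
        kinked = kinked_positions(system, 30.0)
        mid = 5
        np.testing.assert_array_equal(kinked[:mid], system.atoms.positions[:mid])
        assert np.linalg.norm(kinked[-1] - system.atoms.positions[-1]) > 1.0

    def test_too_few_beads(self):
        with pytest.raises(ValueError):
            make_bead_helix(3)

    def test_perturbed_is_seeded(self):
        system = make_bead_helix(6)
        a = perturbed(system.atoms, 0.5, seed=4)
        b = perturbed(system.atoms, 0.5, seed=4)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert not np.allclose(a.positions, system.atoms.positions)

    def test_suggest_fmax_positive(self):
        system = make_bead_helix(8)
        assert suggest_fmax(system, n_steps=50) > 0
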