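"""Trajectory handling, MSD computation and diffusion-coefficient fitting."""

import numpy as np
import pytest

import hydrokin as hk
from hydrokin.errors import ConfigurationError, DomainError, InsufficientDataError
from conftest import naive_msd


def traj_1d(displacements, n_particles=1):
    """Build an unwrapped trajectory moving along x by the given per-frame steps."""
    steps = np.asarray(displacements, dtype=float)
    x = np.concatenate([[0.0], np.cumsum(steps)])
    pos = np.zeros((x.size, n_particles, 3))
    pos[:, :, 0] = x[:, None]
    return hk.Trajectory(np.arange(float(x.size)), pos)


class TestTrajectory:
    def test_nonuniform_times_rejected(self):
        with pytest.raises(DomainError, match="uniform"):
            hk.Trajectory(np.array([0.0, 1.0, 3.0]), np.zeros((3, 1, 3)))

    def test_bad_box_rejected(self):
        with pytest.raises(DomainError):
            hk.Trajectory(np.arange(2.0), np.zeros((2, 1, 3)), box=[10.0, -1.0, 10.0])

    def test_selection_lookup(self):
        t = hk.Trajectory(np.arange(2.0), np.zeros((2, 3, 3)),
                          particle_ids=("a", "b", "c"))
        assert list(t.indices_of(["c", "a"])) == [0, 2]
        with pytest.raises(DomainError):
            t.indices_of([])
        with pytest.raises(DomainError, match="unknown"):
            t.indices_of(["nope"])


class TestUnwrap:
    def test_single_boundary_crossing(self):
        pos = np.zeros((2, 1, 3))
        pos[0, 0, 0], pos[1, 0, 0] = 9.5, 0.5
        t = hk.Trajectory(np.arange(2.0), pos, box=[10.0] * 3, wrapped=True)
        u = hk.unwrap_pbc(t)
        assert u.positions[1, 0, 0] == pytest.approx(10.5)
        assert not u.wrapped

    def test_no_crossing_is_identity(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(4.0, 6.0, size=(5, 4, 3))  # well inside a 10 A box
        t = hk.Trajectory(np.arange(5.0), pos, box=[10.0] * 3, wrapped=True)
        assert np.allclose(hk.unwrap_pbc(t).positions, pos)

    def test_rewrap_roundtrip(self):
        traj = hk.simulate_bulk_brownian(
            hk.BulkSimParams(n_particles=20, n_frames=100, D_target=0.5, box=8.0, seed=5)
        )
        back = hk.wrap_pbc(hk.unwrap_pbc(traj))
        assert np.allclose(back.positions, traj.positions, atol=1e-10)

    def test_missing_box_is_configuration_error(self):
        t = hk.Trajectory(np.arange(2.0), np.zeros((2, 1, 3)), wrapped=True)
        with pytest.raises(ConfigurationError):
            hk.unwrap_pbc(t)


class TestComputeMsd:
    def test_stationary_is_zero(self):
        t = hk.Trajectory(np.arange(10.0), np.ones((10, 3, 3)))
        curve = hk.compute_msd(t)
        assert np.allclose(curve.msd, 0.0)

    def test_unit_steps_quadratic(self):
        # one particle stepping +1 A per frame: displacement over lag n is n
        t = traj_1d([1.0] * 4)
        curve = hk.compute_msd(t, max_lag=4.0)
        assert np.allclose(curve.msd, np.arange(5.0) ** 2)
        # hand-evaluated multiple-origin oracle on the same 5-frame trace
        assert np.allclose(curve.msd, naive_msd(t.positions, 4))

    def test_two_particle_average(self):
        pos = np.zeros((2, 2, 3))
        pos[1, 0, 0] = 1.0  # |d| = 1
        pos[1, 1, 1] = 3.0  # |d| = 3
        t = hk.Trajectory(np.arange(2.0), pos)
        curve = hk.compute_msd(t, max_lag=1.0)
        assert curve.msd[1] == pytest.approx(5.0)  # (1 + 9) / 2

    def test_fft_matches_naive_oracle(self, random_walk_traj):
        curve = hk.compute_msd(random_walk_traj, max_lag=24.0)
        oracle = naive_msd(random_walk_traj.positions, 24)
        assert np.abs(curve.msd - oracle).max() < 1e-10

    def test_single_origin_mode(self, random_walk_traj):
        curve = hk.compute_msd(random_walk_traj, max_lag=20.0, single_origin=True)
        pos = random_walk_traj.positions
        direct = ((pos[:21] - pos[:1]) ** 2).sum(axis=2).mean(axis=1)
        assert np.allclose(curve.msd[1:], direct[1:])
        assert curve.msd[0] == 0.0

    def test_invariance_translation_and_relabel(self, random_walk_traj):
        base = hk.compute_msd(random_walk_traj, max_lag=20.0).msd
        shifted = hk.Trajectory(
            random_walk_traj.times, random_walk_traj.positions + [123.0, -7.0, 0.5]
        )
        assert np.allclose(hk.compute_msd(shifted, max_lag=20.0).msd, base, atol=1e-9)
        perm = np.random.default_rng(3).permutation(random_walk_traj.n_particles)
        relabeled = hk.Trajectory(
            random_walk_traj.times, random_walk_traj.positions[:, perm, :]
        )
        assert np.allclose(hk.compute_msd(relabeled, max_lag=20.0).msd, base, atol=1e-10)

    def test_n_samples_non_increasing(self, random_walk_traj):
        curve = hk.compute_msd(random_walk_traj)
        assert np.all(np.diff(curve.n_samples) <= 0)

    def test_wrapped_input_rejected(self):
        t = hk.Trajectory(np.arange(4.0), np.zeros((4, 1, 3)),
                          box=[10.0] * 3, wrapped=True)
        with pytest.raises(ConfigurationError):
            hk.compute_msd(t)

    def test_max_lag_beyond_duration(self, random_walk_traj):
        with pytest.raises(DomainError):
            hk.compute_msd(random_walk_traj, max_lag=1000.0)


class TestResidenceMsd:
    def test_origin_and_endpoint_same_interval(self):
        # particle resident frames 0-4 and 7-9: lags crossing the gap excluded
        t = traj_1d([1.0] * 9)
        mask = np.ones((10, 1), dtype=bool)
        mask[5:7, 0] = False
        curve = hk.compute_msd(t, max_lag=4.0, residence_mask=mask)
        # lag 1: pairs inside [0,4] (4) and inside [7,9] (2) -> all displacement 1
        assert curve.msd[1] == pytest.approx(1.0)
        assert curve.n_samples[1] == 6
        # lag 4: only within [0,4]
        assert curve.msd[4] == pytest.approx(16.0)
        assert curve.n_samples[4] == 1

    def test_short_intervals_discarded(self):
        t = traj_1d([1.0] * 9)
        mask = np.zeros((10, 1), dtype=bool)
        mask[0:2, 0] = True  # 2-frame run < 3-frame minimum
        curve = hk.compute_msd(t, max_lag=3.0, residence_mask=mask)
        assert curve.n_samples[1:].sum() == 0


class TestFitMsd:
    def make_curve(self, f):
        lags = np.arange(0.0, 51.0)
        return hk.MSDCurve(lags, f(lags), np.full(lags.size, 100, dtype=np.int64))

    def test_pure_diffusion_paper_model(self):
        curve = self.make_curve(lambda t: 4 * 0.2 * t)
        est = hk.fit_msd(curve, model="paper_4Dt")
        assert est.D == pytest.approx(2e-9, rel=1e-9)  # m^2/s
        assert est.D_A2_per_ps == pytest.approx(0.2, rel=1e-9)
        assert est.V == pytest.approx(0.0, abs=1e-6)

    def test_ballistic_limit(self):
        curve = self.make_curve(lambda t: (2.0 * t) ** 2)
        est = hk.fit_msd(curve)
        assert est.V == pytest.approx(2.0, rel=1e-8)
        assert est.D == pytest.approx(0.0, abs=1e-18)

    def test_dimension_factor(self):
        curve = self.make_curve(lambda t: 6 * 0.1 * t)
        est = hk.fit_msd(curve, model="dim_2nDt", n_dim=3)
        assert est.D_A2_per_ps == pytest.approx(0.1, rel=1e-9)

    def test_all_zero_curve(self):
        curve = self.make_curve(lambda t: 0.0 * t)
        est = hk.fit_msd(curve)
        assert est.D == 0.0 and est.V == 0.0 and not est.clamped

    def test_window_too_small(self):
        curve = self.make_curve(lambda t: t)
        with pytest.raises(InsufficientDataError):
            hk.fit_msd(curve, window=(10.0, 11.0))

    def test_brownian_recovery_single_replicate(self):
        traj = hk.simulate_bulk_brownian(
            hk.BulkSimParams(n_particles=500, n_frames=2000, D_target=0.2, seed=7)
        )
        est = hk.estimate_diffusion(hk.unwrap_pbc(traj), model="dim_2nDt", n_dim=3)
        assert abs(est.D - 2e-9) <= 3 * est.stderr_D


class TestDiffusionVsTemperature:
    @staticmethod
    def bulk_run(T, seed):
        law = hk.DiffusionLaw(ln_pre=2.71, B=-15000.0)  # Arrhenius D(T), Eb = 15 kJ/mol
        traj = hk.simulate_bulk_brownian(hk.BulkSimParams(
            n_particles=60, n_frames=400, D_target=law, temperature=T, seed=seed))
        return T, hk.unwrap_pbc(traj), None

    def test_monotone_generator(self):
        series, ests = hk.diffusion_vs_temperature(
            [self.bulk_run(280.0, 0), self.bulk_run(320.0, 1)],
            model="dim_2nDt", n_dim=3,
        )
        assert series.value_kind == "diffusion"
        assert series.values[1] > series.values[0]
        assert len(ests) == 2

    def test_single_run_insufficient(self):
        with pytest.raises(InsufficientDataError):
            hk.diffusion_vs_temperature([self.bulk_run(280.0, 0)])

    def test_duplicate_temperature_rejected(self):
        with pytest.raises(DomainError):
            hk.diffusion_vs_temperature(
                [self.bulk_run(280.0, 0), self.bulk_run(280.0, 1)]
            )
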