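"""Metropolis sampler: determinism, equilibrium correctness, work samples."""

import numpy as np
import pytest
from scipy import stats

from alkylbind.fep import WindowSamples, zwanzig_window
from alkylbind.reference import mean_site_energy, partition_function
from alkylbind.thermo import ThermoState
from alkylbind.toysim import (
    GaussianWell,
    LambdaSchedule,
    SiteRegion,
    ToyHostGuest,
    sample_trajectory,
    window_work_samples,
)
from alkylbind.trajectory import read_xyz, write_xyz


def make_system(depths=(5.0,), widths=(1.0,), centers=((0.0, 0.0, 0.0),)):
    return ToyHostGuest(
        box_lengths=(20.0, 20.0, 20.0),
        wells=[GaussianWell(c, d, w) for c, d, w in zip(centers, depths, widths)],
        site_region=SiteRegion((0.0, 0.0, 0.0), 4.0),
    )


class TestValidation:
    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            GaussianWell((0, 0, 0), -1.0, 1.0)

    def test_site_region_must_fit_in_box(self):
        with pytest.raises(ValueError, match="inside the box"):
            ToyHostGuest(
                box_lengths=(10.0, 10.0, 10.0),
                wells=[],
                site_region=SiteRegion((4.0, 0.0, 0.0), 3.0),
            )

    def test_schedule_endpoints(self):
        with pytest.raises(ValueError):
            LambdaSchedule((1.0, 0.5))
        with pytest.raises(ValueError):
            LambdaSchedule((1.0, 0.6, 0.7, 0.0))
        sched = LambdaSchedule.uniform(24)
        assert sched.n_windows == 24
        assert sched.values[0] == 1.0 and sched.values[-1] == 0.0

    def test_bad_step_sizes(self):
        with pytest.raises(ValueError, match="step sizes"):
            sample_trajectory(make_system(), ThermoState(), 1.0, 10, step_sizes=(0.0, 0.5))

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError, match="lambda"):
            sample_trajectory(make_system(), ThermoState(), 1.5, 10)


class TestDeterminism:
    def test_same_seed_identical_frames(self, thermo):
        s = make_system()
        t1 = sample_trajectory(s, thermo, 1.0, 150, seed=42)
        t2 = sample_trajectory(s, thermo, 1.0, 150, seed=42)
        np.testing.assert_array_equal(t1.coords[100], t2.coords[100])
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_different_seed_differs(self, thermo):
        s = make_system()
        t1 = sample_trajectory(s, thermo, 1.0, 150, seed=1)
        t2 = sample_trajectory(s, thermo, 1.0, 150, seed=2)
        assert not np.array_equal(t1.coords, t2.coords)

    def test_seed_recorded_in_metadata(self, thermo):
        traj = sample_trajectory(make_system(), thermo, 0.7, 10, seed=9)
        assert traj.metadata["seed"] == 9
        assert traj.metadata["lambda"] == 0.7

    def test_window_samples_seeded_repeat(self, thermo):
        s = make_system()
        sched = LambdaSchedule((1.0, 0.5, 0.0), 200, 50)
        w1 = window_work_samples(s, thermo, sched, seed=5)
        w2 = window_work_samples(s, thermo, sched, seed=5)
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a.delta_u, b.delta_u)


class TestEquilibrium:
    def test_decoupled_positions_uniform(self, thermo):
        """At lambda=0 the ligand oxygen is uniform over the box: octant
        chi-square on thinned (decorrelated) frames."""
        traj = sample_trajectory(make_system(), thermo, 0.0, 50_000, seed=7)
        O = traj.coords[::20, 1, :]  # thin: chain samples are serially correlated
        octant = (O[:, 0] > 0) * 4 + (O[:, 1] > 0) * 2 + (O[:, 2] > 0)
        counts = np.bincount(octant.astype(int), minlength=8)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_mean_energy_matches_quadrature(self, thermo):
        """<U_site> at lambda=1 agrees with the Boltzmann integral."""
        s = make_system(depths=(5.0,), widths=(1.0,))
        traj = sample_trajectory(s, thermo, 1.0, 50_000, seed=3, equilibration=1000)
        u = np.asarray(traj.metadata["u_site"])
        batch_means = u.reshape(50, 1000).mean(axis=1)
        se = batch_means.std(ddof=1) / np.sqrt(50)
        assert abs(u.mean() - mean_site_energy(s, thermo)) < 3 * se

    def test_two_state_occupancy_ratio(self, thermo):
        """Detailed balance: long-run well occupancies follow the Boltzmann
        weights of the two regions."""
        s = make_system(
            depths=(2.0, 1.0),
            widths=(1.2, 1.2),
            centers=((-4.0, 0.0, 0.0), (4.0, 0.0, 0.0)),
        )
        traj = sample_trajectory(s, thermo, 1.0, 60_000, seed=11, equilibration=2000)
        O = traj.coords[:, 1, :]
        in_a = np.linalg.norm(O - np.array([-4.0, 0.0, 0.0]), axis=1) < 2.0
        in_b = np.linalg.norm(O - np.array([4.0, 0.0, 0.0]), axis=1) < 2.0
        ratio_mc = in_a.sum() / in_b.sum()

        # quadrature weights of the same regions
        axes = [np.linspace(-10, 10, 201)] * 3
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        r = np.stack([X, Y, Z], axis=-1)
        w = np.exp(-s.site_energy(r) / thermo.RT)
        da = np.linalg.norm(r - np.array([-4.0, 0.0, 0.0]), axis=-1) < 2.0
        db = np.linalg.norm(r - np.array([4.0, 0.0, 0.0]), axis=-1) < 2.0
        ratio_exact = w[da].sum() / w[db].sum()

        # block bootstrap error on the MC ratio
        blocks_a = in_a.reshape(30, 2000).mean(axis=1)
        blocks_b = in_b.reshape(30, 2000).mean(axis=1)
        se = np.std(blocks_a / blocks_b, ddof=1) / np.sqrt(30)
        assert abs(ratio_mc - ratio_exact) < 4 * se

    def test_acceptance_rate_strictly_between_zero_and_one(self, thermo):
        traj = sample_trajectory(make_system(), thermo, 1.0, 5000, seed=1)
        assert 0.0 < traj.metadata["acceptance"] < 1.0


class TestWorkSamples:
    def test_flat_site_gives_exactly_zero_work(self, thermo):
        s = make_system(depths=(0.0,))
        sched = LambdaSchedule((1.0, 0.5, 0.0), 500, 50)
        for w in window_work_samples(s, thermo, sched, seed=0):
            assert np.all(w.delta_u == 0.0)

    def test_counts_match_schedule(self, thermo):
        sched = LambdaSchedule((1.0, 0.5, 0.0), 321, 40)
        ws = window_work_samples(make_system(), thermo, sched, seed=0)
        assert len(ws) == 2
        assert all(w.n == 321 for w in ws)

    def test_window_mean_matches_scaled_mean_energy(self, thermo):
        """In window (1 -> 0.5), dU = -0.5 U_site, so the sample mean must
        agree with the quadrature <U_site> at lambda=1."""
        s = make_system(depths=(3.0,), widths=(1.2,))
        sched = LambdaSchedule((1.0, 0.5, 0.0), 20_000, 2000)
        ws = window_work_samples(s, thermo, sched, seed=13)
        u_samples = ws[0].delta_u / (0.5 - 1.0)
        batch = u_samples.reshape(40, 500).mean(axis=1)
        se = batch.std(ddof=1) / np.sqrt(40)
        expected = mean_site_energy(s, thermo, lam=1.0)
        assert abs(u_samples.mean() - expected) < 3 * se

    def test_zwanzig_on_window_is_finite_and_bounded(self, thermo):
        s = make_system()
        sched = LambdaSchedule.uniform(4, 2000, 200)
        ws = window_work_samples(s, thermo, sched, seed=2)
        for w in ws:
            dg = zwanzig_window(w, thermo)
            assert np.isfinite(dg)
            assert dg <= w.delta_u.mean() + 1e-9  # Jensen


def test_partition_function_against_independent_integrator(thermo):
    """Simpson-grid Z agrees with scipy's adaptive 3-D quadrature."""
    from scipy.integrate import tplquad

    s = make_system(depths=(2.0,), widths=(1.5,))
    z_grid = partition_function(s, thermo, 1.0, points_per_axis=121)
    f = lambda z, y, x: float(
        np.exp(-s.site_energy(np.array([x, y, z])) / thermo.RT)
    )
    z_ref, _ = tplquad(f, -10, 10, -10, 10, -10, 10, epsrel=1e-6)
    assert z_grid == pytest.approx(z_ref, rel=1e-5)


def test_xyz_round_trip(tmp_path, thermo):
    from alkylbind.systems import single_well_system

    traj = sample_trajectory(single_well_system(), thermo, 1.0, 25, seed=8)
    path = tmp_path / "traj.xyz"
    write_xyz(traj, path)
    back = read_xyz(path)
    np.testing.assert_allclose(back.coords, traj.coords, atol=1e-6)
    assert [a.id for a in back.atoms] == [a.id for a in traj.atoms]
    assert [a.role for a in back.atoms] == [a.role for a in traj.atoms]
    assert back.metadata["lambda"] == 1.0
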