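import numpy as np
import pytest

import oligokin as ok
from oligokin.composition import SPECIES_LIBRARY
from oligokin.diffusion import (
    DiffusionEstimate,
    MSDCurve,
    convert_units,
    fit_diffusion,
    msd,
    replica_aggregate,
    rotational_acf,
)
from oligokin.geometry import BoxSpec
from oligokin.trajectory import Trajectory


def free_traj(positions, dt=0.01, box_length=1000.0, orientations=None):
    pos = np.asarray(positions, float)
    n = pos.shape[1]
    return Trajectory(
        species={"SDPC": SPECIES_LIBRARY["SDPC"], "A2A": SPECIES_LIBRARY["A2A"]},
        particle_species=np.array(["A2A" if orientations is not None else "SDPC"] * n, dtype=object),
        times=np.arange(pos.shape[0]) * dt,
        positions=pos,
        box=BoxSpec((box_length, box_length)),
        orientations=orientations,
    )


class TestMSD:
    def test_static_particles_zero(self):
        traj = free_traj(np.tile(np.array([[[5.0, 5.0]]]), (30, 4, 1)))
        curve = msd(traj)
        assert np.all(curve.values == 0)

    def test_ballistic_drift_closed_form(self):
        v = np.array([0.7, -0.4])
        t = np.arange(40) * 0.05
        pos = t[:, None, None] * v[None, None, :] + 100.0
        traj = free_traj(pos, dt=0.05)
        curve = msd(traj)
        assert np.allclose(curve.values, (v @ v) * curve.lags**2, rtol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        pos = np.cumsum(rng.normal(0, 0.3, (12, 3, 2)), axis=0) + 50
        traj = free_traj(pos)
        curve = msd(traj)
        for k, lag in enumerate(range(1, 12 // 2 + 1)):
            acc = [
                ((pos[t0 + lag, p] - pos[t0, p]) ** 2).sum()
                for t0 in range(12 - lag)
                for p in range(3)
            ]
            assert curve.values[k] == pytest.approx(np.mean(acc))
            assert curve.n_samples[k] == len(acc)

    def test_sample_counts_non_increasing(self, rng):
        pos = np.cumsum(rng.normal(0, 0.3, (30, 5, 2)), axis=0) + 50
        curve = msd(free_traj(pos))
        assert np.all(np.diff(curve.n_samples) <= 0)

    def test_wrapped_input_detected(self):
        pos = np.zeros((5, 1, 2))
        pos[:, 0, 0] = [0.5, 9.8, 0.4, 9.9, 0.3]  # jumps across a 10 nm box
        traj = free_traj(pos, box_length=10.0)
        with pytest.raises(ValueError, match="unwrap"):
            msd(traj)


class TestFitDiffusion:
    def _line_curve(self, D, b=0.0, n=30):
        lags = np.linspace(0.05, 3.0, n)
        return MSDCurve(lags, 4 * D * lags + b, np.full(n, 100))

    def test_exact_line_recovers_value(self):
        est = fit_diffusion(self._line_curve(0.48))
        assert est.D == pytest.approx(0.48, rel=1e-12)
        assert est.in_units("1e-9cm2/s") == pytest.approx(4.8)

    def test_zero_msd_gives_zero(self):
        est = fit_diffusion(self._line_curve(0.0))
        assert est.D == 0.0

    def test_negative_slope_clipped_with_warning(self):
        lags = np.linspace(0.1, 1.0, 10)
        curve = MSDCurve(lags, 1.0 - 0.5 * lags, np.full(10, 50))
        with pytest.warns(UserWarning, match="negative"):
            est = fit_diffusion(curve, window=(0.1, 1.0))
        assert est.D == 0.0

    def test_generated_walks_recovered(self):
        traj, _ = ok.simulate(ok.free_config(500, 1.3, n_steps=400, seed=21))
        unwrapped, _ = ok.unwrap_trajectory(traj)
        est = fit_diffusion(msd(unwrapped))
        assert est.D == pytest.approx(1.3, rel=0.10)

    def test_narrow_window_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_diffusion(self._line_curve(1.0), window=(0.0, 0.1))


class TestRotational:
    def test_frozen_orientations(self):
        theta = np.zeros((20, 3))
        pos = np.tile(np.array([[50.0, 50.0]]), (20, 3, 1))
        traj = free_traj(pos, orientations=theta)
        lags, C, est = rotational_acf(traj)
        assert np.allclose(C, 1.0)
        assert est.D == 0.0

    def test_known_rotor_recovered(self, rng):
        Dr, dt, F, n = 0.4, 0.05, 400, 200
        theta = np.cumsum(rng.normal(0, np.sqrt(2 * Dr * dt), (F, n)), axis=0)
        pos = np.tile(np.array([[50.0, 50.0]]), (F, n, 1))
        traj = free_traj(np.repeat(pos[:, :n], 1, axis=1), dt=dt, orientations=theta)
        _, _, est = rotational_acf(traj)
        assert est.D == pytest.approx(Dr, rel=0.10)

    def test_condition_ordering(self, study_runs):
        """Receptors rotate slower in the DHA-poor membrane."""
        def mean_dr(runs):
            out = []
            for tr in runs:
                _, _, est = rotational_acf(tr)
                out.append(est.D)
            return np.mean(out)

        assert mean_dr(study_runs["healthy"]) > mean_dr(study_runs["diseased"])

    def test_missing_orientations_rejected(self):
        traj = free_traj(np.zeros((5, 2, 2)) + 50)
        with pytest.raises(ValueError, match="orientation"):
            rotational_acf(traj)


class TestUnits:
    @pytest.mark.parametrize(
        "value,frm,to,expected",
        [
            (0.48, "nm2/us", "cm2/s", 4.8e-9),
            (2.1e-8, "cm2/s", "nm2/us", 2.1),
            (1.3, "nm2/us", "1e-8cm2/s", 1.3),
            (1.0, "1e-9cm2/s", "nm2/us", 0.1),
        ],
    )
    def test_conversions(self, value, frm, to, expected):
        assert convert_units(value, frm, to) == pytest.approx(expected, rel=1e-12)

    def test_round_trip_exact(self):
        v = 0.123456
        assert convert_units(convert_units(v, "nm2/us", "cm2/s"), "cm2/s", "nm2/us") == v

    def test_unknown_unit(self):
        with pytest.raises(ValueError, match="unknown unit"):
            convert_units(1.0, "nm2/us", "furlong2/fortnight")


class TestReplicaAggregate:
    def _est(self, d, err=0.01):
        return DiffusionEstimate(d, err, (0.1, 1.0), "translational")

    def test_identical_estimates(self):
        agg = replica_aggregate([self._est(2.0)] * 3)
        assert agg.D == 2.0 and agg.error == 0.0

    def test_closed_form_sem(self):
        agg = replica_aggregate([self._est(2.0), self._est(2.2), self._est(2.4)])
        assert agg.D == pytest.approx(2.2)
        assert agg.error == pytest.approx(0.11547, abs=1e-4)

    def test_single_estimate_passes_error_through(self):
        agg = replica_aggregate([self._est(1.5, err=0.07)])
        assert agg.error == 0.07

    def test_mixed_methods_rejected(self):
        rot = DiffusionEstimate(1.0, 0.1, (0.1, 1.0), "rotational")
        with pytest.raises(ValueError, match="mixed"):
            replica_aggregate([self._est(1.0), rot])


class TestEstimatorInvariance:
    def test_rotation_and_time_shift(self, rng):
        pos = np.cumsum(rng.normal(0, 0.3, (60, 20, 2)), axis=0) + 100
        traj = free_traj(pos)
        window = (0.047, 0.253)  # edges between lag points (float-shift safe)
        d0 = fit_diffusion(msd(traj), window=window).D
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = free_traj(pos @ R.T)
        assert fit_diffusion(msd(rotated), window=window).D == pytest.approx(d0, rel=1e-9)
        shifted = Trajectory(traj.species, traj.particle_species, traj.times + 5.0,
                             pos, traj.box)
        assert fit_diffusion(msd(shifted), window=window).D == pytest.approx(d0, rel=1e-9)

    def test_crowding_slows_dha_lipid(self, study_runs):
        """Receptor-bound DHA lipid diffuses below its generating value."""
        ds = []
        for tr in study_runs["healthy"][:3]:
            unwrapped, _ = ok.unwrap_trajectory(tr)
            sel = unwrapped.indices_where(species="SDPC")
            ds.append(fit_diffusion(msd(unwrapped, selection=sel)).D)
        assert np.mean(ds) < 2.1  # generating (free) value for this species
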