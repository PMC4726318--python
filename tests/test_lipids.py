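import numpy as np
import pytest

import oligokin as ok
from oligokin.composition import SPECIES_LIBRARY
from oligokin.geometry import BoxSpec
from oligokin.lipids import (
    RDFCurve,
    bound_fraction,
    lipid_contact_ratio,
    mixing_contact_fraction,
    rdf2d,
    shell_report,
)
from oligokin.trajectory import Trajectory


def membrane_frame(receptor_pos, lipid_pos, lipid_names, box_length=40.0, n_frames=1):
    n_rec = len(receptor_pos)
    names = ["A2A"] * n_rec + list(lipid_names)
    pos = np.concatenate([np.asarray(receptor_pos, float), np.asarray(lipid_pos, float)])
    species = {"A2A": SPECIES_LIBRARY["A2A"]}
    for n in set(lipid_names):
        species[n] = SPECIES_LIBRARY[n]
    return Trajectory(
        species=species,
        particle_species=np.array(names, dtype=object),
        times=np.arange(n_frames, dtype=float),
        positions=np.tile(pos[None], (n_frames, 1, 1)),
        box=BoxSpec((box_length, box_length)),
    )


class TestRDF:
    def test_uniform_gas_is_unity(self, rng):
        lipids = rng.uniform(0, 40, (4000, 2))
        traj = membrane_frame([[20.0, 20.0]], lipids, ["DPPC"] * 4000)
        curve = rdf2d(traj, "DPPC", bin_width=0.5)
        # Poisson tolerance: expected annulus count rho * area per bin
        areas = np.pi * np.diff(curve.bin_edges**2)
        expected = curve.density * areas
        z = (curve.g[2:] - 1.0) * np.sqrt(expected[2:])
        assert np.all(np.abs(z) < 4.0)
        assert curve.g[2:].mean() == pytest.approx(1.0, abs=0.05)

    def test_delta_configuration(self):
        traj = membrane_frame([[20.0, 20.0]], [[23.0, 20.0]], ["DPPC"])
        curve = rdf2d(traj, "DPPC", bin_width=0.5)
        hot = np.flatnonzero(curve.g > 0)
        assert len(hot) == 1
        assert curve.bin_edges[hot[0]] <= 3.0 < curve.bin_edges[hot[0] + 1]

    def test_matches_brute_force_histogram(self, rng):
        lipids = rng.uniform(0, 40, (200, 2))
        recs = rng.uniform(0, 40, (3, 2))
        traj = membrane_frame(recs, lipids, ["SDPC"] * 200)
        curve = rdf2d(traj, "SDPC", bin_width=0.25)
        # independent pair histogram over 9 periodic images
        L = 40.0
        dists = []
        for r in recs:
            for l in lipids:
                best = np.inf
                for ix in (-1, 0, 1):
                    for iy in (-1, 0, 1):
                        best = min(best, np.hypot(*(l + np.array([ix, iy]) * L - r)))
                dists.append(best)
        counts, _ = np.histogram(dists, bins=curve.bin_edges)
        rho = 200 / L**2
        areas = np.pi * np.diff(curve.bin_edges**2)
        assert np.allclose(curve.g, counts / (rho * areas * 3), atol=1e-12)

    def test_mass_conservation(self, rng):
        lipids = rng.uniform(0, 40, (500, 2))
        traj = membrane_frame([[10.0, 10.0]], lipids, ["DOPC"] * 500)
        curve = rdf2d(traj, "DOPC", bin_width=0.2)
        areas = np.pi * np.diff(curve.bin_edges**2)
        recovered = np.sum(curve.g * areas) * curve.density
        expected = sum(
            np.hypot(*ok.minimum_image_displacement([10.0, 10.0], lipid, traj.box))
            < curve.bin_edges[-1]
            for lipid in lipids
        )
        assert recovered == pytest.approx(expected, rel=1e-9)

    def test_r_max_beyond_half_box_rejected(self, rng):
        traj = membrane_frame([[20.0, 20.0]], rng.uniform(0, 40, (10, 2)), ["DPPC"] * 10)
        with pytest.raises(ValueError, match="half the box"):
            rdf2d(traj, "DPPC", r_max=25.0)

    def test_healthy_preset_dha_shell_dominates(self, study_runs):
        """DHA lipids crowd the receptor shell more than saturated ones."""
        traj = study_runs["healthy"][0]
        frames = np.arange(traj.n_frames // 2, traj.n_frames)
        g_sdpc = rdf2d(traj, "SDPC", frames=frames, bin_width=0.1)
        g_dppc = rdf2d(traj, "DPPC", frames=frames, bin_width=0.1)
        assert g_sdpc.first_peak()[1] > g_dppc.first_peak()[1]


class TestShellReport:
    def _curve(self, g, bin_width=0.1):
        edges = np.arange(0, bin_width * (len(g) + 0.5), bin_width)[: len(g) + 1]
        return RDFCurve(edges, np.asarray(g, float), "receptors", "all", 1, 1.0, 1)

    def test_constructed_peak_and_minimum(self):
        r = np.arange(0.05, 5.0, 0.1)
        g = np.ones_like(r)
        g[r < 1.5] = 0.0  # excluded core
        g += 3.0 * np.exp(-((r - 2.5) ** 2) / 0.08)  # peak at 2.5
        g -= 0.6 * np.exp(-((r - 3.3) ** 2) / 0.02)  # minimum at 3.3
        curve = self._curve(g)
        traj = membrane_frame([[20.0, 20.0]], [[22.0, 20.0]], ["SDPC"])
        rep = shell_report(curve, traj)
        assert rep.detectable
        assert rep.outer_radius == pytest.approx(3.35, abs=0.1)
        assert rep.width == pytest.approx(rep.outer_radius - rep.core_radius)

    def test_uniform_gas_undetectable(self):
        curve = self._curve(np.ones(50))
        traj = membrane_frame([[20.0, 20.0]], [[22.0, 20.0]], ["SDPC"])
        rep = shell_report(curve, traj)
        assert not rep.detectable and rep.occupancy == {}

    def test_healthy_preset_sdpc_plurality_in_shell(self, study_runs):
        """The DHA phospholipid dominates the first solvation shell."""
        traj = study_runs["healthy"][0]
        frames = np.arange(traj.n_frames - 20, traj.n_frames)
        curve = rdf2d(traj, "SDPC", frames=frames, bin_width=0.2)
        rep = shell_report(curve, traj, frames=frames,
                           lipid_species=["SDPC", "DPPC", "DSPC", "DOPC", "SM"])
        assert rep.detectable
        assert max(rep.occupancy, key=rep.occupancy.get) == "SDPC"


class TestContactRatio:
    def test_all_saturated_zero_ratio(self):
        lipids = [[20.3, 20.0], [20.0, 20.4], [35.0, 5.0]]
        traj = membrane_frame([[20.0, 20.0]], lipids, ["DPPC"] * 3)
        out = lipid_contact_ratio(traj)
        assert np.all(out["UNSAT/SAT"] == 0.0)

    def test_ratio_arithmetic(self):
        # 2 unsaturated and 1 saturated lipid in contact, equal class sizes
        lipids = [[20.3, 20.0], [20.0, 20.3], [20.0, 19.7], [35.0, 5.0], [5.0, 35.0], [35.0, 35.0]]
        names = ["SDPC", "SDPC", "DPPC", "SDPC", "DPPC", "DPPC"]
        traj = membrane_frame([[20.0, 20.0]], lipids, names)
        out = lipid_contact_ratio(traj, cutoff=0.5)
        assert out["UNSAT/SAT"][0] == pytest.approx(2.0)

    def test_no_denominator_contacts_flagged(self):
        lipids = [[20.3, 20.0], [35.0, 5.0]]
        traj = membrane_frame([[20.0, 20.0]], lipids, ["SDPC", "DPPC"])
        out = lipid_contact_ratio(traj, cutoff=0.5)
        assert np.isnan(out["UNSAT/SAT"][0])

    def test_shell_attraction_raises_ratio_over_time(self, study_runs):
        """DHA-receptor affinity builds the unsaturated contact excess."""
        traj = study_runs["healthy"][0]
        out = lipid_contact_ratio(traj, cutoff=3.3)
        ratio = out["UNSAT/SAT"]
        early = np.nanmean(ratio[:5])
        late = np.nanmean(ratio[-5:])
        assert late > early


class TestMixingFraction:
    def test_equimolar_ideal_mixture(self, rng):
        pos = rng.uniform(0, 40, (400, 2))
        names = ["DPPC"] * 200 + ["SDPC"] * 200
        traj = membrane_frame(np.empty((0, 2)), pos, names)
        out = mixing_contact_fraction(traj, ["DPPC"], ["SDPC"])
        assert out["random_expectation"] == pytest.approx(0.5)
        assert out["f_ab"][0] == pytest.approx(0.5, abs=0.1)

    def test_striped_layout_below_random(self, demo_dir):
        traj = ok.load_trajectory(demo_dir["striped"])
        out = mixing_contact_fraction(traj, ["DPPC"], ["SDPC"])
        assert out["f_ab"][0] < 0.5 * out["random_expectation"]

    def test_matches_pair_enumeration(self, rng):
        pos = rng.uniform(0, 40, (60, 2))
        names = ["DPPC"] * 30 + ["SDPC"] * 30
        traj = membrane_frame(np.empty((0, 2)), pos, names)
        out = mixing_contact_fraction(traj, ["DPPC"], ["SDPC"], cutoff=2.0)
        cross = total = 0
        for i in range(60):
            for j in range(i + 1, 60):
                d = np.hypot(*ok.minimum_image_displacement(pos[i], pos[j], traj.box))
                if d < 2.0:
                    total += 1
                    cross += names[i] != names[j]
        assert out["f_ab"][0] == pytest.approx(cross / total)

    def test_disjoint_classes_required(self):
        traj = membrane_frame(np.empty((0, 2)), [[1.0, 1.0], [2.0, 2.0]], ["DPPC", "SDPC"])
        with pytest.raises(ValueError, match="disjoint"):
            mixing_contact_fraction(traj, ["DPPC"], ["DPPC"])


class TestBoundFraction:
    def test_all_in_shell(self):
        lipids = [[20.5, 20.0], [20.0, 20.5], [19.5, 20.0]]
        traj = membrane_frame([[20.0, 20.0]], lipids, ["SDPC"] * 3)
        out = bound_fraction(traj, "SDPC", shell_radius=1.0)
        assert out["mean"] == 1.0

    def test_requires_receptors(self):
        traj = membrane_frame(np.empty((0, 2)), [[1.0, 1.0]], ["SDPC"])
        with pytest.raises(ValueError, match="no receptors"):
            bound_fraction(traj, "SDPC", shell_radius=1.0)

    def test_scarce_dha_more_bound(self, study_runs):
        """With few DHA lipids per receptor, practically all stay bound."""
        h = np.mean([bound_fraction(t, "SDPC", 3.0)["mean"] for t in study_runs["healthy"]])
        d = np.mean([bound_fraction(t, "SDPC", 3.0)["mean"] for t in study_runs["diseased"]])
        assert d > h


def test_metrics_invariant_under_translation_and_reorder(rng):
    pos = rng.uniform(0, 40, (50, 2))
    names = ["DPPC"] * 25 + ["SDPC"] * 25
    traj = membrane_frame([[20.0, 20.0]], pos, names)
    out1 = mixing_contact_fraction(traj, ["DPPC"], ["SDPC"], cutoff=2.0)
    shift = np.array([13.0, -7.0])
    perm = rng.permutation(50)
    traj2 = membrane_frame(
        np.mod([[20.0, 20.0]] + shift, 40.0),
        np.mod(pos[perm] + shift, 40.0),
        [names[i] for i in perm],
    )
    out2 = mixing_contact_fraction(traj2, ["DPPC"], ["SDPC"], cutoff=2.0)
    assert out1["f_ab"][0] == pytest.approx(out2["f_ab"][0])
    b1 = bound_fraction(traj, "SDPC", 3.0)["mean"]
    b2 = bound_fraction(traj2, "SDPC", 3.0)["mean"]
    assert b1 == pytest.approx(b2)
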