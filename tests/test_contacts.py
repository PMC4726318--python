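import numpy as np
import pytest

import oligokin as ok
from oligokin.contacts import (
    classify_contacts,
    compare_aggregation,
    contact_matrix,
    contacts_per_protomer,
    effective_time,
    oligomer_clusters,
    onset_radius,
    pair_distance_series,
)
from oligokin.composition import SPECIES_LIBRARY
from oligokin.geometry import BoxSpec
from oligokin.trajectory import Trajectory


def receptor_frame(points, box_length=50.0, names=None, n_frames=1):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if names is None:
        names = ["A2A" if i % 2 == 0 else "D2" for i in range(n)]
    return Trajectory(
        species={"A2A": SPECIES_LIBRARY["A2A"], "D2": SPECIES_LIBRARY["D2"]},
        particle_species=np.array(names, dtype=object),
        times=np.arange(n_frames, dtype=float),
        positions=np.tile(pts[None], (n_frames, 1, 1)),
        box=BoxSpec((box_length, box_length)),
    )


def brute_force_contacts(pos, box, cutoff):
    """9-periodic-image oracle for the contact matrix."""
    n = len(pos)
    L = box.in_plane_lengths
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    d = pos[j] + np.array([ix, iy]) * L - pos[i]
                    best = min(best, np.hypot(*d))
            out[i, j] = best < cutoff
    return out


class TestContactMatrix:
    def test_strict_inequality_at_cutoff(self):
        box = BoxSpec((50.0, 50.0))
        near = contact_matrix(np.array([[0.0, 10.0], [4.19, 10.0]]), box)
        far = contact_matrix(np.array([[0.0, 10.0], [4.20, 10.0]]), box)
        assert near[0, 1] and not far[0, 1]

    def test_single_receptor_empty(self):
        m = contact_matrix(np.array([[5.0, 5.0]]), BoxSpec((50.0, 50.0)))
        assert m.shape == (1, 1) and not m.any()

    def test_matches_brute_force(self, rng):
        box = BoxSpec((50.0, 50.0))
        pos = rng.uniform(0, 50, (20, 2))
        assert np.array_equal(
            contact_matrix(pos, box), brute_force_contacts(pos, box, 4.2)
        )

    def test_large_cutoff_rejected(self):
        with pytest.raises(ValueError, match="half the box"):
            contact_matrix(np.zeros((2, 2)), BoxSpec((8.0, 8.0)), cutoff=4.2)

    def test_translation_and_wrap_invariance(self, rng):
        box = BoxSpec((50.0, 50.0))
        pos = rng.uniform(0, 50, (12, 2))
        ref = contact_matrix(pos, box)
        shifted = np.mod(pos + np.array([17.3, -8.9]), 50.0)
        assert np.array_equal(contact_matrix(shifted, box), ref)


class TestContactsPerProtomer:
    def test_linear_trimer_counts(self):
        traj = ok.make_layout_fixture("linear_chain", k=3, spacing=4.0)
        series, mean, _ = contacts_per_protomer(traj)
        assert list(series[0].counts[0]) == [1, 2, 1]
        assert mean == pytest.approx(4 / 3)

    def test_mean_bounded_and_equals_edge_formula(self, rng):
        traj = receptor_frame(rng.uniform(0, 50, (10, 2)))
        series, mean, _ = contacts_per_protomer(traj)
        m = series[0].matrices[0]
        edges = m.sum() // 2
        assert 0 <= mean <= 9
        assert mean == pytest.approx(2 * edges / 10)

    def test_empty_window_rejected(self):
        traj = ok.make_layout_fixture("dimers", n_receptors=4, n_frames=3)
        with pytest.raises(ValueError, match="window"):
            contacts_per_protomer(traj, window=(100.0, 200.0))


class TestOligomerClusters:
    def test_chain_of_four(self):
        traj = ok.make_layout_fixture("linear_chain", k=4, spacing=4.0)
        m = contact_matrix(traj.positions[0], traj.box)
        part = oligomer_clusters(m)
        assert part.sizes.tolist() == [4]
        assert m.sum() // 2 == 3

    def test_all_isolated(self):
        part = oligomer_clusters(np.zeros((7, 7), dtype=bool))
        assert len(part.sizes) == 7 and (part.sizes == 1).all()

    def test_matches_transitive_closure_oracle(self, rng):
        import networkx as nx

        for _ in range(20):
            n = int(rng.integers(2, 15))
            m = rng.random((n, n)) < 0.2
            m = np.triu(m, 1)
            m = m | m.T
            part = oligomer_clusters(m)
            comps = list(nx.connected_components(nx.from_numpy_array(m)))
            assert sorted(part.sizes.tolist()) == sorted(len(c) for c in comps)
            # members of one graph component share a partition label
            for comp in comps:
                assert len({part.labels[i] for i in comp}) == 1


class TestClassifyContacts:
    def test_alternating_ring_all_hetero(self):
        traj = ok.make_layout_fixture("ring", k=6, spacing=4.0)
        m = contact_matrix(traj.positions[0], traj.box)
        out = classify_contacts(m, traj.particle_species)
        assert out["fraction_heteromeric"] == 1.0 and out["total"] == 6

    def test_all_homomeric_system(self):
        traj = ok.make_layout_fixture("ring", k=6, spacing=4.0, alternate=False)
        m = contact_matrix(traj.positions[0], traj.box)
        out = classify_contacts(m, traj.particle_species)
        assert out["fraction_heteromeric"] == 0.0

    def test_matches_edge_enumeration(self, rng):
        n = 12
        m = rng.random((n, n)) < 0.3
        m = np.triu(m, 1)
        m = m | m.T
        labels = rng.choice(["A2A", "D2"], n)
        out = classify_contacts(m, labels)
        manual = {"hh": 0, "het": 0}
        for i in range(n):
            for j in range(i + 1, n):
                if m[i, j]:
                    key = "het" if labels[i] != labels[j] else "hh"
                    manual[key] += 1
        assert out["A2A-D2"] == manual["het"]
        assert out["A2A-A2A"] + out["D2-D2"] == manual["hh"]

    def test_unlabelled_rejected(self):
        with pytest.raises(ValueError, match="unlabelled|unknown"):
            classify_contacts(np.zeros((2, 2), dtype=bool), ["A2A", "5HT2A"])


class TestCompareAggregation:
    def test_printed_means_arithmetic(self):
        # the healthy/diseased contact means imply a >20% relative increase
        rel = (1.48 - 1.20) / 1.20 * 100
        assert rel == pytest.approx(23.33, abs=0.01)

    def test_identical_runs_zero_difference(self):
        runs = [ok.make_layout_fixture("dimers", n_receptors=8, n_frames=4)] * 3
        out = compare_aggregation(runs, runs)
        assert out["relative_difference_pct"] == 0.0 and out["p"] == 1.0

    def test_synthetic_conditions_positive(self, study_runs):
        out = compare_aggregation(study_runs["healthy"], study_runs["diseased"])
        assert out["relative_difference_pct"] > 0


class TestTimeAndRadius:
    @pytest.mark.parametrize("raw,eff", [(15.0, 60.0), (0.0, 0.0), (65.0, 260.0)])
    def test_effective_time(self, raw, eff):
        assert effective_time(raw) == eff

    @pytest.mark.parametrize(
        "cutoff,width,expected", [(4.2, 0.9, 6.0), (4.2, 0.0, 4.2), (4.2, 0.8, 5.8)]
    )
    def test_onset_radius(self, cutoff, width, expected):
        r = onset_radius(cutoff, width)
        assert r == pytest.approx(expected)

    def test_onset_radius_in_reported_band(self):
        # shell widths of 0.8-0.9 nm put the onset inside 5.5-6 nm
        assert 5.5 <= onset_radius(4.2, 0.8) <= 6.0
        assert 5.5 <= onset_radius(4.2, 0.9) <= 6.0


class TestPairDistance:
    def test_held_dimer_onset_at_zero(self):
        traj = ok.make_layout_fixture("dimers", n_receptors=2, spacing=4.0, n_frames=5)
        out = pair_distance_series(traj, 0, 1)
        assert out["onset"] == 0.0
        assert np.allclose(out["distance"], 4.0)

    def test_stepwise_approach_onset(self):
        pos = np.zeros((6, 2, 2))
        pos[:, 0] = [10.0, 10.0]
        for f, d in enumerate([6.0, 6.0, 5.0, 5.0, 4.0, 4.0]):
            pos[f, 1] = [10.0 + d, 10.0]
        traj = receptor_frame(np.zeros((2, 2)))
        traj = Trajectory(traj.species, traj.particle_species,
                          np.arange(6, dtype=float) * 0.5, pos, traj.box)
        out = pair_distance_series(traj, 0, 1, persistence=0.5)
        assert out["onset"] == 2.0  # time of the first 4 nm frame

    def test_persistence_longer_than_any_stretch(self):
        pos = np.zeros((4, 2, 2))
        pos[:, 0] = [10.0, 10.0]
        for f, d in enumerate([4.0, 6.0, 4.0, 6.0]):
            pos[f, 1] = [10.0 + d, 10.0]
        traj = receptor_frame(np.zeros((2, 2)))
        traj = Trajectory(traj.species, traj.particle_species,
                          np.arange(4, dtype=float), pos, traj.box)
        out = pair_distance_series(traj, 0, 1, persistence=2.0)
        assert out["onset"] is None

    def test_same_receptor_rejected(self):
        traj = ok.make_layout_fixture("dimers", n_receptors=2)
        with pytest.raises(ValueError, match="distinct"):
            pair_distance_series(traj, 1, 1)
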