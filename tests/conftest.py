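import numpy as np
import pytest

import oligokin as ok


@pytest.fixture(scope="session")
def study_runs():
    """Five seeded replicas of the healthy and diseased study presets.

    Shared across contact-ordering, lipid-shell and diffusion tests to
    avoid re-simulating; each run is 18 receptors + 400 lipids for 4 us
    raw (16 us effective).
    """
    runs = {}
    for condition in ("healthy", "diseased"):
        runs[condition] = [
            ok.simulate(ok.study_config(condition, seed=seed))[0] for seed in range(5)
        ]
    return runs


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    files = ok.make_demo_fixtures(out, seed=0)
    return files


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_trajectory(rng):
    """10 random particles, 3 frames, mixed species, for IO round trips."""
    from oligokin.composition import SPECIES_LIBRARY

    names = ["A2A", "D2"] + ["SDPC"] * 4 + ["DPPC"] * 3 + ["CHOL"]
    box = ok.BoxSpec((11.0, 11.0))
    pos = rng.uniform(0, 11, size=(3, 10, 2))
    theta = np.full((3, 10), np.nan)
    theta[:, :2] = rng.uniform(0, 2 * np.pi, size=(3, 2))
    return ok.Trajectory(
        species={n: SPECIES_LIBRARY[n] for n in set(names)},
        particle_species=np.array(names, dtype=object),
        times=np.array([0.0, 0.5, 1.0]),
        positions=pos,
        box=box,
        orientations=theta,
    )
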