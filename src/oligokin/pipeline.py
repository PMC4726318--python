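"""End-to-end healthy-vs-diseased study orchestration.

Runs the seeded generator for each condition, then the contact, lipid
and diffusion analyses, and collects everything into a StudyReport with
per-stage logging and reproducible provenance (config hash + seeds).
Also builds the deterministic demo fixture set used by the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import contacts as ct
from . import diffusion as df
from . import lipids as lp
from .bret import synthesize_titration
from .simulate import make_layout_fixture, simulate, study_config
from .trajectory import save_trajectory, unwrap_trajectory

__all__ = ["StudyConfig", "StudyReport", "run_study", "make_demo_fixtures",
           "recover_free_diffusion"]


def recover_free_diffusion(d_true: float, *, n_walks: int = 500, n_seeds: int = 10,
                           seed: int = 0, n_steps: int = 400, dt: float = 1e-3,
                           lag_window: tuple[float, float] = (0.01, 0.1)) -> dict:
    """Estimator-recovery experiment: free Brownian walks at a known D.

    Generates ``n_seeds`` independent ensembles of ``n_walks`` 2D walks
    with the generator set to ``d_true`` (nm^2/us), runs the MSD fit
    over ``lag_window`` (us; default 10-100 ns) on each, and returns the
    per-seed estimates with their mean and SEM.
    """
    from .simulate import free_config, simulate

    estimates = []
    for k in range(n_seeds):
        cfg = free_config(n_walks, d_true, dt=dt, n_steps=n_steps, stride=1,
                          seed=int(seed) + k)
        traj, _ = simulate(cfg)
        unwrapped, _ = unwrap_trajectory(traj)
        curve = df.msd(unwrapped)
        estimates.append(df.fit_diffusion(curve, window=lag_window).D)
    est = np.asarray(estimates)
    sem = float(est.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0
    return {"d_true": d_true, "estimates": est, "mean": float(est.mean()),
            "sem": sem, "n_walks": n_walks, "n_seeds": n_seeds}

log = logging.getLogger("oligokin.pipeline")


@dataclass
class StudyConfig:
    """Configuration of a two-condition comparison study."""

    conditions: tuple[str, str] = ("healthy", "diseased")
    seeds: tuple[int, ...] = (0, 1, 2)
    n_lipids: int = 400
    n_receptors_each: int = 9
    box_length: float = 33.0
    dt: float = 1e-3  # us
    t_total: float = 4.0  # raw us (x4 for effective time)
    stride: int = 40
    contact_cutoff: float = ct.DEFAULT_CUTOFF
    shell_radius: float = 3.0  # nm, for bound-fraction reporting
    output_dir: str | None = None

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seeds must be explicit and non-empty")
        if self.contact_cutoff <= 0 or self.shell_radius <= 0:
            raise ValueError("cutoffs must be positive")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Aggregated study results; every number traces to config + seed."""

    config_hash: str
    contacts: dict = field(default_factory=dict)
    comparison: dict = field(default_factory=dict)
    diffusion: dict = field(default_factory=dict)
    bound_sdpc: dict = field(default_factory=dict)
    single_replica_mode: bool = False
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            return o

        payload = asdict(self)
        payload.pop("stage_seconds")  # wall time is logging, not a result
        return json.dumps(clean(payload), indent=2, sort_keys=True)


def run_study(config: StudyConfig) -> StudyReport:
    """Simulate both conditions over all seeds and compare their kinetics."""
    report = StudyReport(config_hash=config.digest(),
                         single_replica_mode=len(config.seeds) == 1)
    runs: dict[str, list] = {}
    for condition in config.conditions:
        t0 = _time.perf_counter()
        runs[condition] = []
        for seed in config.seeds:
            sim_cfg = study_config(
                condition, seed=seed, n_lipids=config.n_lipids,
                n_receptors_each=config.n_receptors_each,
                box_length=config.box_length, dt=config.dt,
                t_total=config.t_total, stride=config.stride,
            )
            traj, _ = simulate(sim_cfg)
            runs[condition].append(traj)
        report.stage_seconds[f"simulate[{condition}]"] = _time.perf_counter() - t0
        log.info("simulated %s: %d replicas in %.1f s", condition,
                 len(config.seeds), report.stage_seconds[f"simulate[{condition}]"])

    t0 = _time.perf_counter()
    for condition, trajs in runs.items():
        _, mean, sem = ct.contacts_per_protomer(trajs, cutoff=config.contact_cutoff)
        report.contacts[condition] = {
            "mean_contacts_per_protomer": mean,
            "sem": sem,
            "n_replicas": len(trajs),
            "effective_time_us": ct.effective_time(config.t_total),
        }
    a, b = config.conditions
    report.comparison = ct.compare_aggregation(runs[a], runs[b],
                                               cutoff=config.contact_cutoff)
    report.stage_seconds["contacts"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    for condition, trajs in runs.items():
        sdpc_like = "SDPC" if "SDPC" in trajs[0].species else "SDPE"
        fractions = [lp.bound_fraction(tr, sdpc_like, config.shell_radius)["mean"]
                     for tr in trajs]
        report.bound_sdpc[condition] = {
            "species": sdpc_like,
            "mean": float(np.mean(fractions)),
            "per_replica": fractions,
        }
    report.stage_seconds["lipids"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    for condition, trajs in runs.items():
        table = {}
        species_names = sorted({str(s) for s in trajs[0].particle_species})
        for name in species_names:
            ests = []
            for tr in trajs:
                unwrapped, _ = unwrap_trajectory(tr)
                sel = unwrapped.indices_where(species=name)
                curve = df.msd(unwrapped, selection=sel)
                ests.append(df.fit_diffusion(curve))
            agg = df.replica_aggregate(ests)
            table[name] = {"D_1e-8_cm2_s": agg.in_units("1e-8cm2/s"),
                           "error": df.convert_units(agg.error, "nm2/us", "1e-8cm2/s")}
        report.diffusion[condition] = table
    report.stage_seconds["diffusion"] = _time.perf_counter() - t0

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "study_report.json").write_text(report.to_json())
    return report


def make_demo_fixtures(output_dir, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic fixture set used by tests and examples.

    Produces layout trajectories (9 dimers, singletons, a linear chain,
    a hexamer ring, a striped demixed frame), a noiseless hyperbolic
    BRET plate CSV and a composition preset table.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    layouts = {
        "dimers9": make_layout_fixture("dimers", n_receptors=18, spacing=4.0),
        "singletons": make_layout_fixture("singletons", n_receptors=9, spacing=4.0),
        "chain4": make_layout_fixture("linear_chain", k=4, spacing=4.0),
        "ring6": make_layout_fixture("ring", k=6, spacing=4.0),
    }
    for name, traj in layouts.items():
        path = out / f"{name}.traj"
        save_trajectory(traj, path)
        files[name] = path

    # striped demixed frame: saturated left half, unsaturated right half
    from .composition import SPECIES_LIBRARY
    from .geometry import BoxSpec
    from .trajectory import Trajectory

    rng = np.random.default_rng(seed)
    L = 40.0
    n_half = 150
    xs_a = rng.uniform(0, L / 2 - 1.5, n_half)
    xs_b = rng.uniform(L / 2 + 1.5, L - 1.5, n_half)
    ys = rng.uniform(0, L, 2 * n_half)
    pos = np.column_stack([np.concatenate([xs_a, xs_b]), ys])[None, :, :]
    striped = Trajectory(
        species={"DPPC": SPECIES_LIBRARY["DPPC"], "SDPC": SPECIES_LIBRARY["SDPC"]},
        particle_species=np.array(["DPPC"] * n_half + ["SDPC"] * n_half, dtype=object),
        times=np.array([0.0]),
        positions=pos,
        box=BoxSpec((L, L)),
    )
    files["striped"] = out / "striped.traj"
    save_trajectory(striped, files["striped"])

    tit = synthesize_titration(bret_max=100.0, bret50=0.5, noise=0.0, seed=seed)
    plate = tit.to_frame()
    files["bret_plate"] = out / "bret_plate.csv"
    plate.to_csv(files["bret_plate"], index=False)

    from .composition import preset, tail_census

    rows = []
    for name in ("healthy", "diseased", "ternary_high_dha"):
        comp = preset(name)
        frame = tail_census(comp).to_frame()
        frame.insert(0, "composition", name)
        rows.append(frame)
    import pandas as pd

    files["tail_census"] = out / "tail_census.csv"
    pd.concat(rows).to_csv(files["tail_census"], index=False)
    return files
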