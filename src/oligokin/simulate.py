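"""Seeded 2D overdamped-Langevin membrane generator.

Stands in for (undeposited) coarse-grained MD trajectories of receptors
in model membranes: particles diffuse in a periodic plane with known
translational/rotational diffusion coefficients and pairwise
interactions (quadratic soft core inside r0 plus a Gaussian attractive
well of depth epsilon centred at r0, truncated and shifted at r0+3*sigma).
Receptor oligomerisation, DHA-lipid solvation shells and partial
saturated/unsaturated demixing emerge from the interaction table; the
generating parameters are returned as ground truth for estimator
recovery tests.

Euler-Maruyama update per step (kT = 1):

    dx = sqrt(2 D dt) N(0,1) + D F dt        (per axis)
    dtheta = sqrt(2 Dr dt) N(0,1)            (receptors)

Identical (config, seed) gives bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .composition import SPECIES_LIBRARY, MembraneComposition, particle_counts, preset
from .geometry import BoxSpec
from .trajectory import Species, Trajectory

__all__ = [
    "SpeciesSpec",
    "Interaction",
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "make_layout_fixture",
    "demix_preset",
    "study_config",
    "free_config",
    "RECEPTOR_D",
    "LIPID_D",
]

#: Receptor translational diffusion (nm^2/us) by condition, at the scale
#: measured for A2A / D2 receptors in healthy- and diseased-like model
#: membranes (0.48/0.46 vs 0.18/0.22 nm^2/us). Rotational diffusion is
#: scaled with the same condition ratio (no measured magnitudes exist).
RECEPTOR_D = {
    "healthy": {"A2A": 0.48, "D2": 0.46},
    "diseased": {"A2A": 0.18, "D2": 0.22},
    "ternary_high_dha": {"A2A": 0.48, "D2": 0.46},
}

#: Lipid translational diffusion (nm^2/us == 1e-8 cm^2/s) by condition,
#: from the protein-crowded measurement tables.
LIPID_D = {
    "healthy": {"CHOL": 3.4, "SM": 2.7, "DPPC": 2.9, "DSPC": 2.9, "DOPC": 2.9, "SDPC": 2.1},
    "diseased": {"CHOL": 2.6, "SM": 2.5, "DPPC": 2.5, "DSPC": 2.4, "DOPC": 2.4, "SDPC": 1.3},
    "ternary_high_dha": {"POPC": 8.1, "SDPE": 8.1, "CHOL": 12.4},
}


@dataclass(frozen=True)
class SpeciesSpec:
    """Simulated species: count plus generating diffusion coefficients."""

    species: Species
    count: int
    D: float  # translational, nm^2/us
    Dr: float = 0.0  # rotational, rad^2/us (receptors)


@dataclass(frozen=True)
class Interaction:
    """Pair interaction: soft core inside r0, Gaussian well at r0.

    epsilon : well depth in kT (0 = excluded volume only)
    sigma   : well range in nm
    r0      : excluded-volume radius / well position in nm
    k_rep   : soft-core stiffness in kT (force continuous at r0);
              defaults to 25 + 20*epsilon so that deep binding wells in
              crowded clusters cannot push pairs far inside the core
    """

    epsilon: float
    sigma: float
    r0: float
    k_rep: float | None = None

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma <= 0 or self.r0 <= 0:
            raise ValueError("need epsilon >= 0 and sigma, r0 > 0")
        if self.k_rep is None:
            object.__setattr__(self, "k_rep", 25.0 + 20.0 * self.epsilon)

    @property
    def cutoff(self) -> float:
        return self.r0 + 3.0 * self.sigma


@dataclass
class SimulationConfig:
    box: BoxSpec
    species: list[SpeciesSpec]
    interactions: dict[tuple[str, str], Interaction] = field(default_factory=dict)
    dt: float = 1e-4  # us
    n_steps: int = 1000
    stride: int = 10
    seed: int = 0
    receptor_min_spacing: float = 6.0  # nm, initial receptor separation

    def __post_init__(self):
        # normalise interaction keys to sorted tuples
        self.interactions = {
            tuple(sorted(k)): v for k, v in self.interactions.items()
        }

    def validate(self) -> None:
        if self.dt <= 0 or self.n_steps < 0 or self.stride < 1:
            raise ValueError("need dt > 0, n_steps >= 0, stride >= 1")
        sigmas = [i.sigma for i in self.interactions.values() if i.epsilon > 0]
        if sigmas:
            sig_min = min(sigmas)
            for spec in self.species:
                step = math.sqrt(2 * spec.D * self.dt)
                if step >= sig_min / 5:
                    dt_max = (sig_min / 5) ** 2 / (2 * spec.D)
                    raise ValueError(
                        f"unstable: sqrt(2 D dt) = {step:.3g} nm >= sigma/5 = "
                        f"{sig_min / 5:.3g} nm for {spec.species.name}; "
                        f"use dt < {dt_max:.3g} us"
                    )


@dataclass
class GroundTruth:
    """Generating parameters, for parameter-recovery oracles."""

    D: dict[str, float]
    Dr: dict[str, float]
    interactions: dict[tuple[str, str], Interaction]
    seed: int
    layout: dict | None = None

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "Dr": self.Dr,
            "interactions": {"|".join(k): asdict(v) for k, v in self.interactions.items()},
            "seed": self.seed,
            "layout": self.layout,
        }


def _pair_tables(names: list[str], interactions: dict[tuple[str, str], Interaction]):
    """Dense per-type-pair parameter matrices for vectorised force sums."""
    nt = len(names)
    idx = {n: i for i, n in enumerate(names)}
    eps = np.zeros((nt, nt))
    sig = np.ones((nt, nt))
    r0 = np.zeros((nt, nt))
    krep = np.zeros((nt, nt))
    cut = np.zeros((nt, nt))
    for (a, b), inter in interactions.items():
        if a not in idx or b not in idx:
            continue
        ia, ib = idx[a], idx[b]
        for i, j in ((ia, ib), (ib, ia)):
            eps[i, j] = inter.epsilon
            sig[i, j] = inter.sigma
            r0[i, j] = inter.r0
            krep[i, j] = inter.k_rep
            cut[i, j] = inter.cutoff if inter.epsilon > 0 else inter.r0
    return eps, sig, r0, krep, cut


def _initial_positions(config: SimulationConfig, rng: np.random.Generator,
                       names_per_particle: np.ndarray, roles: np.ndarray) -> np.ndarray:
    Lx, Ly = config.box.in_plane_lengths
    n = len(names_per_particle)
    pos = np.column_stack([rng.uniform(0, Lx, n), rng.uniform(0, Ly, n)])
    # receptors start on a jittered grid: well separated, deterministic
    rec = np.flatnonzero(np.isin(roles, ("receptor_A2A", "receptor_D2")))
    if rec.size:
        ncols = math.ceil(math.sqrt(rec.size))
        nrows = math.ceil(rec.size / ncols)
        sx, sy = Lx / ncols, Ly / nrows
        if min(sx, sy) < config.receptor_min_spacing:
            import warnings

            warnings.warn(
                f"box too small for receptor spacing {config.receptor_min_spacing} nm; "
                f"grid spacing is {min(sx, sy):.2f} nm",
                stacklevel=3,
            )
        jitter = 0.05 * min(sx, sy)
        for k, p in enumerate(rec):
            r, c = divmod(k, ncols)
            pos[p] = [
                (c + 0.5) * sx + rng.uniform(-jitter, jitter),
                (r + 0.5) * sy + rng.uniform(-jitter, jitter),
            ]
    return pos


def _relax_overlaps(pos: np.ndarray, L: np.ndarray, tidx: np.ndarray,
                    r0_t: np.ndarray, krep_t: np.ndarray,
                    max_iter: int = 200, step_cap: float = 0.05) -> np.ndarray:
    """Deterministic steric relaxation of random initial placements.

    Noise-free soft-core-only descent with a capped step, run until no
    pair sits inside 60% of its excluded-volume radius; guarantees the
    saved frames never start from unphysical overlaps.
    """
    r0_max = float(r0_t.max()) if r0_t.size else 0.0
    if r0_max == 0:
        return pos
    for _ in range(max_iter):
        tree = cKDTree(np.mod(pos, L), boxsize=L)
        pairs = tree.query_pairs(r0_max, output_type="ndarray")
        if pairs.size == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[j] - pos[i]
        d -= np.round(d / L) * L
        r = np.hypot(d[:, 0], d[:, 1])
        r0 = r0_t[tidx[i], tidx[j]]
        act = (r < 0.6 * r0) & (r0 > 0)
        if not act.any():
            break
        i, j, d, r, r0 = i[act], j[act], d[act], r[act], r0[act]
        r = np.maximum(r, 1e-6)
        f = 2 * krep_t[tidx[i], tidx[j]] * (1 - r / r0) / r0
        fv = (f / r)[:, None] * d
        force = np.zeros_like(pos)
        np.add.at(force, j, fv)
        np.add.at(force, i, -fv)
        step = np.clip(0.01 * force, -step_cap, step_cap)
        pos = pos + step
    return pos


def simulate(config: SimulationConfig) -> tuple[Trajectory, GroundTruth]:
    """Run the overdamped Langevin dynamics and return (Trajectory, GroundTruth)."""
    config.validate()
    box = config.box
    box.require_membrane_plane()
    L = box.in_plane_lengths

    names_pp, roles, D_pp, Dr_pp = [], [], [], []
    species_table: dict[str, Species] = {}
    for spec in config.species:
        species_table[spec.species.name] = spec.species
        names_pp += [spec.species.name] * spec.count
        roles += [spec.species.role] * spec.count
        D_pp += [spec.D] * spec.count
        Dr_pp += [spec.Dr] * spec.count
    names_pp = np.array(names_pp, dtype=object)
    roles = np.array(roles)
    D_pp = np.asarray(D_pp)
    Dr_pp = np.asarray(Dr_pp)
    n = names_pp.size
    type_names = list(dict.fromkeys(str(x) for x in names_pp))
    tidx = np.array([type_names.index(str(x)) for x in names_pp])
    eps_t, sig_t, r0_t, krep_t, cut_t = _pair_tables(type_names, config.interactions)
    max_cut = float(cut_t.max()) if cut_t.size else 0.0
    interacting = max_cut > 0

    rng = np.random.default_rng(config.seed)
    pos = _initial_positions(config, rng, names_pp, roles)
    if cut_t.size and cut_t.max() > 0:
        pos = _relax_overlaps(pos, L, tidx, r0_t, krep_t)
    is_rec = np.isin(roles, ("receptor_A2A", "receptor_D2"))
    theta = np.where(is_rec, rng.uniform(0, 2 * np.pi, n), np.nan)

    n_saved = config.n_steps // config.stride + 1
    out_pos = np.empty((n_saved, n, 2))
    out_theta = np.empty((n_saved, n))
    times = np.empty(n_saved)
    out_pos[0], out_theta[0], times[0] = pos, theta, 0.0

    sqrt_trans = np.sqrt(2 * D_pp * config.dt)[:, None]
    sqrt_rot = np.sqrt(2 * Dr_pp * config.dt)
    save_i = 1
    for step in range(1, config.n_steps + 1):
        force = np.zeros((n, 2))
        if interacting:
            tree = cKDTree(np.mod(pos, L), boxsize=L)
            pairs = tree.query_pairs(max_cut, output_type="ndarray")
            if pairs.size:
                i, j = pairs[:, 0], pairs[:, 1]
                d = pos[j] - pos[i]
                d -= np.round(d / L) * L
                r = np.hypot(d[:, 0], d[:, 1])
                ti, tj = tidx[i], tidx[j]
                cut = cut_t[ti, tj]
                act = (r < cut) & (cut > 0) & (r > 1e-12)
                if act.any():
                    i, j, d, r = i[act], j[act], d[act], r[act]
                    ti, tj = ti[act], tj[act]
                    eps, sig, r0, krep = (eps_t[ti, tj], sig_t[ti, tj],
                                          r0_t[ti, tj], krep_t[ti, tj])
                    # scalar force f = -dU/dr; positive = repulsive
                    f = np.zeros_like(r)
                    core = r < r0
                    f[core] += 2 * krep[core] * (1 - r[core] / r0[core]) / r0[core]
                    attr = eps > 0
                    if attr.any():
                        x = (r[attr] - r0[attr]) / sig[attr]
                        f[attr] += -eps[attr] * x / sig[attr] * np.exp(-0.5 * x * x)
                    fv = (f / r)[:, None] * d  # force on j along +d
                    np.add.at(force, j, fv)
                    np.add.at(force, i, -fv)
        noise = rng.standard_normal((n, 2))
        pos = pos + sqrt_trans * noise + (D_pp[:, None] * config.dt) * force
        rot_noise = rng.standard_normal(n)
        theta = theta + sqrt_rot * rot_noise
        if step % config.stride == 0:
            out_pos[save_i] = pos
            out_theta[save_i] = theta
            times[save_i] = step * config.dt
            save_i += 1

    traj = Trajectory(
        species=species_table,
        particle_species=names_pp,
        times=times[:save_i],
        positions=np.mod(out_pos[:save_i], L),
        box=box,
        orientations=out_theta[:save_i] if is_rec.any() else None,
    )
    truth = GroundTruth(
        D={s.species.name: s.D for s in config.species},
        Dr={s.species.name: s.Dr for s in config.species if s.Dr > 0},
        interactions=dict(config.interactions),
        seed=config.seed,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# study presets


def _receptor_specs(condition: str, n_each: int = 9, dr_scale: float = 1.0) -> list[SpeciesSpec]:
    out = []
    for name in ("A2A", "D2"):
        D = RECEPTOR_D[condition][name]
        out.append(SpeciesSpec(SPECIES_LIBRARY[name], n_each, D, Dr=D * dr_scale))
    return out


def default_interactions(condition: str) -> dict[tuple[str, str], Interaction]:
    """Interaction table emulating the condition's statistical structure.

    Receptor-receptor: binding well at the contact scale (oligomers do
    not re-dissolve on the simulated timescale). DHA-lipid (SDPC/SDPE)
    particles are attracted to receptors (solvation shell) and to each
    other (DHA-DHA affinity driving partial demixing). Everything else
    is excluded volume.

    The shell well is deeper in the DHA-poor condition: with no DHA-rich
    bulk domains to partition into, the receptor surface is the only
    favourable environment for the few DHA lipids, which is what keeps
    practically all of them receptor-bound there. In the DHA-rich
    condition bulk DHA-DHA contacts compete with the shell, leaving a
    freely diffusing fraction.
    """
    shell_eps = {"healthy": 2.5, "diseased": 3.5, "ternary_high_dha": 2.5}[condition]
    lipids = [n for n in LIPID_D[condition]]
    table: dict[tuple[str, str], Interaction] = {}
    for rec in ("A2A", "D2"):
        for rec2 in ("A2A", "D2"):
            table[(rec, rec2)] = Interaction(epsilon=4.0, sigma=0.5, r0=4.0)
        for lip in lipids:
            if lip in ("SDPC", "SDPE"):
                # flexible DHA tails pack closest to the receptor surface
                table[(rec, lip)] = Interaction(epsilon=shell_eps, sigma=0.5, r0=2.2)
            else:
                # stiffer tails are sterically disfavoured near the protein
                table[(rec, lip)] = Interaction(epsilon=0.0, sigma=0.5, r0=3.1)
    for a in lipids:
        for b in lipids:
            if a in ("SDPC", "SDPE") and b in ("SDPC", "SDPE"):
                table[(a, b)] = Interaction(epsilon=1.5, sigma=0.5, r0=0.9)
            else:
                table[(a, b)] = Interaction(epsilon=0.0, sigma=0.5, r0=0.8)
    return {tuple(sorted(k)): v for k, v in table.items()}


def study_config(condition: str, *, seed: int = 0, n_lipids: int = 400,
                 n_receptors_each: int = 9, box_length: float = 33.0,
                 dt: float = 1e-3, t_total: float = 4.0,
                 stride: int = 40) -> SimulationConfig:
    """Desk-scale analogue of one membrane-patch run.

    ``t_total`` is raw simulated time in us (multiply by 4 for the
    effective-time convention). Defaults give 18 receptors + 400 lipids
    in a 33 x 33 nm box (the receptor density of a replicated 11 x 11 nm
    two-receptor membrane patch) for 4 us raw = 16 us effective.
    """
    comp: MembraneComposition = preset(
        condition if condition in ("healthy", "diseased") else "ternary_high_dha"
    )
    counts = particle_counts(comp, n_lipids)
    specs = _receptor_specs(condition, n_receptors_each)
    for name, count in sorted(counts.items()):
        specs.append(SpeciesSpec(SPECIES_LIBRARY[name], count, LIPID_D[condition][name]))
    return SimulationConfig(
        box=BoxSpec((box_length, box_length)),
        species=specs,
        interactions=default_interactions(condition),
        dt=dt,
        n_steps=int(round(t_total / dt)),
        stride=stride,
        seed=seed,
    )


def free_config(n: int, D: float, *, box_length: float = 100.0, dt: float = 1e-3,
                n_steps: int = 2000, stride: int = 1, seed: int = 0,
                species_name: str = "SDPC") -> SimulationConfig:
    """Non-interacting Brownian walks of one species (estimator oracles)."""
    sp = SPECIES_LIBRARY.get(species_name, Species(species_name, "unknown"))
    return SimulationConfig(
        box=BoxSpec((box_length, box_length)),
        species=[SpeciesSpec(sp, n, D)],
        interactions={},
        dt=dt,
        n_steps=n_steps,
        stride=stride,
        seed=seed,
    )


def demix_preset(strength: float, *, n_each: int = 150, box_length: float = 40.0,
                 dt: float = 1e-3, n_steps: int = 2000, stride: int = 20,
                 seed: int = 0) -> SimulationConfig:
    """Equimolar saturated/unsaturated mixture with like-like attraction.

    ``strength`` (kT) scales the attraction between same-saturation
    species; 0 gives an ideal mixture (soft cores identical for all
    pairs, so mixing statistics stay random), larger values push the
    steady saturated-unsaturated contact fraction below the 2x(1-x)
    random expectation.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    sat = SPECIES_LIBRARY["DPPC"]
    unsat = SPECIES_LIBRARY["SDPC"]
    like = Interaction(epsilon=strength, sigma=0.5, r0=0.9)
    cross = Interaction(epsilon=0.0, sigma=0.5, r0=0.9)
    return SimulationConfig(
        box=BoxSpec((box_length, box_length)),
        species=[SpeciesSpec(sat, n_each, 2.9), SpeciesSpec(unsat, n_each, 2.1)],
        interactions={("DPPC", "DPPC"): like, ("SDPC", "SDPC"): like,
                      ("DPPC", "SDPC"): cross},
        dt=dt,
        n_steps=n_steps,
        stride=stride,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic layout fixtures


def make_layout_fixture(arrangement: str, *, spacing: float = 4.0, k: int = 6,
                        n_receptors: int = 18, n_frames: int = 1,
                        box_length: float = 50.0, inter_group: float = 12.0,
                        coordinates=None, alternate: bool = True) -> Trajectory:
    """Deterministic receptor layouts with exact inter-COM spacings.

    arrangement: 'singletons' | 'dimers' | 'linear_chain' | 'ring' | 'custom'.
    Receptor species alternate A2A/D2 when ``alternate`` (else all A2A).
    """
    box = BoxSpec((box_length, box_length))
    pts: list[tuple[float, float]] = []
    if arrangement == "singletons":
        ncols = math.ceil(math.sqrt(n_receptors))
        step = box_length / ncols
        if step <= spacing:
            raise ValueError("singletons do not fit at requested spacing")
        for i in range(n_receptors):
            r, c = divmod(i, ncols)
            pts.append(((c + 0.5) * step, (r + 0.5) * step))
    elif arrangement == "dimers":
        n_pairs = n_receptors // 2
        ncols = math.ceil(math.sqrt(n_pairs))
        step = inter_group
        if ncols * step > box_length:
            raise ValueError(
                f"{n_pairs} dimers at inter-pair spacing {inter_group} nm "
                f"do not fit in a {box_length} nm box"
            )
        for i in range(n_pairs):
            r, c = divmod(i, ncols)
            cx, cy = (c + 0.5) * step, (r + 0.5) * step
            pts.append((cx - spacing / 2, cy))
            pts.append((cx + spacing / 2, cy))
    elif arrangement == "linear_chain":
        length = (k - 1) * spacing
        if length >= box_length:
            raise ValueError("chain does not fit in box")
        x0 = (box_length - length) / 2
        pts = [(x0 + i * spacing, box_length / 2) for i in range(k)]
    elif arrangement == "ring":
        R = spacing / (2 * math.sin(math.pi / k))
        if 2 * R >= box_length / 2:
            raise ValueError("ring does not fit in box")
        c = box_length / 2
        pts = [
            (c + R * math.cos(2 * math.pi * i / k), c + R * math.sin(2 * math.pi * i / k))
            for i in range(k)
        ]
    elif arrangement == "custom":
        if coordinates is None:
            raise ValueError("custom arrangement needs coordinates")
        pts = [tuple(map(float, p)) for p in coordinates]
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    n = len(pts)
    names = [("A2A" if i % 2 == 0 else "D2") if alternate else "A2A" for i in range(n)]
    positions = np.tile(np.asarray(pts)[None, :, :], (n_frames, 1, 1))
    times = np.arange(n_frames, dtype=float)
    return Trajectory(
        species={"A2A": SPECIES_LIBRARY["A2A"], "D2": SPECIES_LIBRARY["D2"]},
        particle_species=np.array(names, dtype=object),
        times=times,
        positions=positions,
        box=box,
        orientations=np.zeros((n_frames, n)),
    )
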