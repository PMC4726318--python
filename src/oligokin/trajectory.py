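"""Trajectory data model and readers/writers.

The native fixture format is a self-describing text file: a header with
units, box and a species table, a particle table, then per-frame blocks
of in-plane coordinates (receptors carry an orientation angle). Standard
MD formats (GRO+XTC, PDB+DCD) load through MDAnalysis, with residues
collapsed to their lateral centres of mass.

Units are nm / us / rad package-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import BoxSpec, wrap_positions, unwrap_positions

__all__ = [
    "Species",
    "Trajectory",
    "TrajectoryParseError",
    "TrajectoryStructureError",
    "RECEPTOR_ROLES",
    "load_trajectory",
    "save_trajectory",
    "unwrap_trajectory",
]

RECEPTOR_ROLES = ("receptor_A2A", "receptor_D2")
_ROLES = RECEPTOR_ROLES + ("lipid", "sterol", "unknown")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message names the offending line."""


class TrajectoryStructureError(ValueError):
    """Structurally inconsistent trajectory (counts, time ordering)."""


@dataclass(frozen=True)
class Species:
    """A particle species: receptor, phospholipid or sterol.

    Lipids carry exactly two fatty-acyl tail labels (e.g. ``C22:6`` for
    DHA) each with a saturation class; sterols and receptors carry none.
    """

    name: str
    role: str
    tails: tuple[str, ...] = ()
    saturation: tuple[str, ...] = ()

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r} for species {self.name!r}")
        if self.role == "lipid" and len(self.tails) != 2:
            raise ValueError(f"lipid {self.name!r} must have exactly 2 tails")
        if self.role == "sterol" and self.tails:
            raise ValueError(f"sterol {self.name!r} must have no tails")
        if len(self.tails) != len(self.saturation):
            raise ValueError(f"{self.name!r}: one saturation class per tail required")
        for sat in self.saturation:
            if sat not in ("saturated", "unsaturated"):
                raise ValueError(f"{self.name!r}: bad saturation class {sat!r}")

    @property
    def is_receptor(self) -> bool:
        return self.role in RECEPTOR_ROLES


@dataclass
class Trajectory:
    """Timed frames of in-plane particle coordinates in a periodic box.

    Attributes
    ----------
    species : dict
        Species definitions keyed by name.
    particle_species : ndarray of str, shape (n_particles,)
        Species name per particle; ordering fixed across frames.
    times : ndarray, shape (n_frames,)
        Frame times in us, strictly increasing.
    positions : ndarray, shape (n_frames, n_particles, 2)
        Lateral coordinates in nm.
    orientations : ndarray or None, shape (n_frames, n_particles)
        In-plane orientation angle (rad) for receptors, NaN elsewhere.
    box : BoxSpec
    """

    species: dict[str, Species]
    particle_species: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    box: BoxSpec
    orientations: np.ndarray | None = None
    particle_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.particle_species = np.asarray(self.particle_species, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.particle_ids is None:
            self.particle_ids = np.arange(self.n_particles)
        self.particle_ids = np.asarray(self.particle_ids, dtype=int)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise TrajectoryStructureError(
                f"positions must be (n_frames, n_particles, 2), got {self.positions.shape}"
            )
        if self.positions.shape[0] != self.times.shape[0]:
            raise TrajectoryStructureError("frame count does not match times")
        if self.positions.shape[1] != self.particle_species.shape[0]:
            raise TrajectoryStructureError("particle count inconsistent across tables")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryStructureError("frame times must be strictly increasing")
        for name in np.unique(self.particle_species.astype(str)):
            if name not in self.species:
                raise TrajectoryStructureError(f"particle references unknown species {name!r}")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            if self.orientations.shape != self.positions.shape[:2]:
                raise TrajectoryStructureError("orientations shape must be (n_frames, n_particles)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in us (median of successive differences)."""
        if self.n_frames < 2:
            raise TrajectoryStructureError("need >= 2 frames for a frame spacing")
        return float(np.median(np.diff(self.times)))

    def roles(self) -> np.ndarray:
        return np.array([self.species[str(s)].role for s in self.particle_species])

    def indices_where(self, *, species: str | None = None, role: str | None = None) -> np.ndarray:
        """Particle indices matching a species name and/or role tag."""
        mask = np.ones(self.n_particles, dtype=bool)
        if species is not None:
            mask &= self.particle_species.astype(str) == species
        if role is not None:
            mask &= self.roles() == role
        return np.flatnonzero(mask)

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.roles(), RECEPTOR_ROLES))

    @property
    def lipid_indices(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.roles(), ("lipid", "sterol")))

    def time_window(self, t_start: float, t_end: float) -> np.ndarray:
        """Frame indices with t in the half-open interval [t_start, t_end)."""
        return np.flatnonzero((self.times >= t_start) & (self.times < t_end))


def unwrap_trajectory(traj: Trajectory) -> tuple[Trajectory, np.ndarray]:
    """Return a continuous-coordinate copy plus a per-particle suspect flag.

    Particles whose frame-to-frame displacement reaches half the box on
    a periodic axis are flagged: their unwrapping is unreliable because
    the minimum image is ambiguous at that sampling density.
    """
    unwrapped, suspect = unwrap_positions(traj.positions, traj.box)
    if suspect.any():
        import warnings

        warnings.warn(
            f"{int(suspect.sum())} particle(s) moved >= L/2 between frames; "
            "unwrapping unreliable for those particles",
            stacklevel=2,
        )
    out = Trajectory(
        species=traj.species,
        particle_species=traj.particle_species,
        times=traj.times,
        positions=unwrapped,
        box=traj.box,
        orientations=traj.orientations,
        particle_ids=traj.particle_ids,
    )
    return out, suspect


# ---------------------------------------------------------------------------
# fixture format


_MAGIC = "OLIGOKIN-TRAJ 1"


def _fmt(x: float) -> str:
    return repr(float(x))


def save_trajectory(traj: Trajectory, path) -> None:
    """Write the fixture text format (bit-exact round trip via float repr).

    Positions are wrapped into the box on write, per the format contract.
    """
    path = Path(path)
    wrapped = wrap_positions(traj.positions, traj.box)
    has_theta = traj.orientations is not None
    lines = [_MAGIC, "units nm us rad"]
    lines.append("box " + " ".join(_fmt(L) for L in traj.box.lengths))
    lines.append("periodic " + " ".join("1" if p else "0" for p in traj.box.periodic))
    lines.append(f"species {len(traj.species)}")
    for sp in traj.species.values():
        tails = ",".join(sp.tails) if sp.tails else "-"
        sat = ",".join(sp.saturation) if sp.saturation else "-"
        lines.append(f"  {sp.name} {sp.role} {tails} {sat}")
    lines.append(f"particles {traj.n_particles}")
    for pid, name in zip(traj.particle_ids, traj.particle_species):
        lines.append(f"  {int(pid)} {name}")
    for f in range(traj.n_frames):
        lines.append(f"frame {_fmt(traj.times[f])}")
        for i in range(traj.n_particles):
            x, y = wrapped[f, i]
            row = f"  {_fmt(x)} {_fmt(y)}"
            if has_theta and math.isfinite(traj.orientations[f, i]):
                row += f" {_fmt(traj.orientations[f, i])}"
            lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def _load_fixture(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise TrajectoryParseError(f"{path}: line 1: not a fixture trajectory (bad magic)")
    i = 1
    box_lengths = periodic = None
    species: dict[str, Species] = {}
    particle_ids: list[int] = []
    particle_species: list[str] = []
    times: list[float] = []
    frames: list[list[tuple[float, ...]]] = []

    def err(msg: str) -> TrajectoryParseError:
        return TrajectoryParseError(f"{path}: line {i + 1}: {msg}")

    n = len(lines)
    while i < n:
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0]
        if key == "units":
            if tok[1:4] != ["nm", "us", "rad"]:
                raise err(f"unsupported units {tok[1:]}")
            i += 1
        elif key == "box":
            box_lengths = tuple(float(x) for x in tok[1:])
            i += 1
        elif key == "periodic":
            periodic = tuple(x == "1" for x in tok[1:])
            i += 1
        elif key == "species":
            count = int(tok[1])
            for _ in range(count):
                i += 1
                try:
                    name, role, tails, sat = lines[i].split()
                except ValueError as exc:
                    raise err("species row needs: name role tails saturation") from exc
                tails_t = () if tails == "-" else tuple(tails.split(","))
                sat_t = () if sat == "-" else tuple(sat.split(","))
                try:
                    species[name] = Species(name, role, tails_t, sat_t)
                except ValueError as exc:
                    raise err(str(exc)) from exc
            i += 1
        elif key == "particles":
            count = int(tok[1])
            for _ in range(count):
                i += 1
                try:
                    pid, name = lines[i].split()
                except ValueError as exc:
                    raise err("particle row needs: id species") from exc
                particle_ids.append(int(pid))
                particle_species.append(name)
            i += 1
        elif key == "frame":
            try:
                t = float(tok[1])
            except (IndexError, ValueError) as exc:
                raise err("frame line needs a time") from exc
            rows: list[tuple[float, ...]] = []
            for _ in range(len(particle_species)):
                i += 1
                if i >= n:
                    raise TrajectoryParseError(
                        f"{path}: frame at t={t}: truncated (fewer rows than particles)"
                    )
                vals = lines[i].split()
                if len(vals) not in (2, 3):
                    raise err("coordinate row needs 'x y' or 'x y theta'")
                try:
                    rows.append(tuple(float(v) for v in vals))
                except ValueError as exc:
                    raise err("non-numeric coordinate") from exc
            times.append(t)
            frames.append(rows)
            i += 1
        else:
            raise err(f"unknown directive {key!r}")

    if box_lengths is None:
        raise TrajectoryParseError(f"{path}: missing box line")
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames")
    npart = len(particle_species)
    positions = np.full((len(frames), npart, 2), np.nan)
    orientations = np.full((len(frames), npart), np.nan)
    any_theta = False
    for f, rows in enumerate(frames):
        for p, vals in enumerate(rows):
            positions[f, p] = vals[:2]
            if len(vals) == 3:
                orientations[f, p] = vals[2]
                any_theta = True
    t_arr = np.asarray(times)
    if t_arr.size > 1 and not np.all(np.diff(t_arr) > 0):
        raise TrajectoryStructureError(f"{path}: frame times are not strictly increasing")
    return Trajectory(
        species=species,
        particle_species=np.array(particle_species, dtype=object),
        times=t_arr,
        positions=positions,
        box=BoxSpec(box_lengths, periodic),
        orientations=orientations if any_theta else None,
        particle_ids=np.array(particle_ids, dtype=int),
    )


# ---------------------------------------------------------------------------
# standard MD formats (via MDAnalysis)


def _load_mdanalysis(topology, trajectory, species_map: dict | None) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    resnames = [str(r.resname) for r in u.residues]
    species: dict[str, Species] = {}
    species_map = species_map or {}
    for name in dict.fromkeys(resnames):
        if name in species_map:
            entry = species_map[name]
            if isinstance(entry, Species):
                species[name] = entry
            else:
                species[name] = Species(
                    name,
                    entry.get("role", "unknown"),
                    tuple(entry.get("tails", ())),
                    tuple(entry.get("saturation", ())),
                )
        else:
            species[name] = Species(name, "unknown")
    n_res = len(u.residues)
    times, coords = [], []
    for ts in u.trajectory:
        com = np.array([res.atoms.positions.mean(axis=0)[:2] for res in u.residues])
        coords.append(com / 10.0)  # A -> nm
        times.append(float(ts.time) / 1e6)  # ps -> us
    dims = u.dimensions
    if dims is None or not np.all(dims[:2] > 0):
        raise TrajectoryStructureError(f"{trajectory}: no periodic box information")
    box = BoxSpec((float(dims[0]) / 10.0, float(dims[1]) / 10.0))
    t = np.asarray(times)
    if t.size > 1 and np.all(np.diff(t) == 0):
        t = np.arange(t.size, dtype=float)  # formats without time stamps
    return Trajectory(
        species=species,
        particle_species=np.array(resnames, dtype=object),
        times=t,
        positions=np.asarray(coords),
        box=box,
        particle_ids=np.arange(n_res),
    )


def load_trajectory(path, format_hint: str | None = None, *, topology=None,
                    species_map: dict | None = None) -> Trajectory:
    """Load a trajectory from the fixture format or a standard MD pair.

    Parameters
    ----------
    path : path-like
        Fixture file, or the trajectory part (XTC/DCD) of an MD pair.
    format_hint : {'fixture', 'gro+xtc', 'pdb+dcd', None}
        Inferred from the suffix when None.
    topology : path-like, optional
        GRO/PDB coordinate file; required for MD formats.
    species_map : dict, optional
        Residue name -> Species (or dict with role/tails/saturation);
        unmapped residues are kept with role ``unknown``.
    """
    path = Path(path)
    if format_hint is None:
        suffix = path.suffix.lower()
        format_hint = "fixture" if suffix in ("", ".txt", ".traj") else "md"
    if format_hint == "fixture":
        return _load_fixture(path)
    if format_hint in ("md", "gro+xtc", "pdb+dcd"):
        if topology is None:
            raise ValueError("MD formats need a topology (GRO/PDB) file")
        return _load_mdanalysis(topology, path, species_map)
    raise ValueError(f"unknown format hint {format_hint!r}")
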