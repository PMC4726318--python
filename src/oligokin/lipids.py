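"""Lipid-shell and demixing analyses around membrane receptors.

Implements the in-plane radial distribution function g(r) of lipids
around receptor centres of mass, first-solvation-shell detection and
occupancy, receptor-lipid contact-count ratios by saturation class,
the saturated-unsaturated demixing contact fraction, and the fraction
of a lipid species bound inside receptor shells.

The 2D RDF uses the standard ideal-gas normalisation (annulus counts
over rho * annulus area, averaged over frames and references) so that
g -> 1 at large r for uniformly distributed targets; this replaces
arbitrary-units conventions and makes curves comparable across species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import minimum_image_displacement
from .trajectory import Trajectory

__all__ = [
    "RDFCurve",
    "ShellReport",
    "rdf2d",
    "shell_report",
    "lipid_contact_ratio",
    "mixing_contact_fraction",
    "bound_fraction",
    "DEFAULT_RECEPTOR_LIPID_CUTOFF",
    "DEFAULT_LIPID_LIPID_CUTOFF",
]

# bead-scale contact cutoffs (package conventions, configurable)
DEFAULT_RECEPTOR_LIPID_CUTOFF = 0.6  # nm
DEFAULT_LIPID_LIPID_CUTOFF = 1.1  # nm


@dataclass
class RDFCurve:
    """Radial distribution of a target species around reference receptors."""

    bin_edges: np.ndarray  # (B+1,) nm
    g: np.ndarray  # (B,)
    reference: str
    target: str
    n_frames: int
    density: float  # mean target number density (nm^-2)
    n_reference: int

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def first_peak(self) -> tuple[float, float]:
        """(r, g) of the global maximum."""
        i = int(np.argmax(self.g))
        return float(self.r[i]), float(self.g[i])


@dataclass
class ShellReport:
    """First solvation shell around the receptors."""

    outer_radius: float | None  # nm; None when no shell detectable
    core_radius: float | None  # excluded-core radius, nm
    width: float | None  # outer - core, nm
    occupancy: dict[str, float]  # per-species fraction of in-shell lipids

    @property
    def detectable(self) -> bool:
        return self.outer_radius is not None


def _lateral_distances(ref_pos: np.ndarray, target_pos: np.ndarray, box) -> np.ndarray:
    """(n_ref, n_target) lateral minimum-image distance matrix."""
    d = minimum_image_displacement(ref_pos[:, None, :], target_pos[None, :, :], box)
    return np.sqrt((d**2).sum(axis=-1))


def rdf2d(traj: Trajectory, target_species: str,
          reference_indices: np.ndarray | None = None,
          bin_width: float = 0.05, r_max: float | None = None,
          frames: np.ndarray | None = None) -> RDFCurve:
    """In-plane radial distribution function of lipids around receptor COMs.

    Counts in each annulus are normalised by the ideal-gas expectation
    rho * pi * (r_out^2 - r_in^2) per reference per frame; reference
    particles of the target species are never counted against themselves.
    """
    box = traj.box
    half = float(min(box.in_plane_lengths)) / 2
    if r_max is None:
        r_max = half
    if r_max > half + 1e-12:
        raise ValueError(f"r_max {r_max} nm exceeds half the box ({half} nm)")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    ref = traj.receptor_indices if reference_indices is None else np.asarray(reference_indices)
    targets = traj.indices_where(species=target_species)
    if ref.size == 0 or targets.size == 0:
        raise ValueError("need at least one reference and one target particle")
    targets = targets[~np.isin(targets, ref)]
    if targets.size == 0:
        raise ValueError("all target particles are references")
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(edges.size - 1)
    for f in frames:
        dist = _lateral_distances(traj.positions[f, ref], traj.positions[f, targets], box)
        counts += np.histogram(dist, bins=edges)[0]
    rho = targets.size / box.area
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    norm = rho * areas * ref.size * len(frames)
    return RDFCurve(
        bin_edges=edges,
        g=counts / norm,
        reference="receptors",
        target=target_species,
        n_frames=len(frames),
        density=rho,
        n_reference=int(ref.size),
    )


def shell_report(rdf: RDFCurve, traj: Trajectory,
                 lipid_species: list[str] | None = None,
                 reference_indices: np.ndarray | None = None,
                 frames: np.ndarray | None = None) -> ShellReport:
    """Locate the first solvation shell and measure per-species occupancy.

    The shell outer radius is the first local minimum of g after its
    global maximum where g has dropped below 1; the excluded-core radius
    is the largest r below the peak where g < 0.05 * peak. Occupancy is
    per-frame membership counting of lipids within the outer radius of
    the nearest reference.
    """
    g, r = rdf.g, rdf.r
    ipk = int(np.argmax(g))
    outer = None
    for i in range(ipk + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] <= g[i + 1] and g[i] < 1.0:
            outer = float(r[i])
            break
    if outer is None or g[ipk] <= 1.0:
        return ShellReport(None, None, None, {})
    peak = g[ipk]
    core = 0.0
    for i in range(ipk, -1, -1):
        if g[i] < 0.05 * peak:
            core = float(r[i])
            break
    occupancy: dict[str, float] = {}
    ref = traj.receptor_indices if reference_indices is None else np.asarray(reference_indices)
    if lipid_species is None:
        lipid_species = sorted(
            {str(s) for s in traj.particle_species[traj.lipid_indices]}
        )
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    in_shell = {sp: 0 for sp in lipid_species}
    for f in frames:
        for sp in lipid_species:
            tidx = traj.indices_where(species=sp)
            tidx = tidx[~np.isin(tidx, ref)]
            if tidx.size == 0:
                continue
            dist = _lateral_distances(traj.positions[f, ref], traj.positions[f, tidx], traj.box)
            in_shell[sp] += int((dist.min(axis=0) < outer).sum())
    total = sum(in_shell.values())
    if total:
        occupancy = {sp: c / total for sp, c in in_shell.items()}
    return ShellReport(outer_radius=outer, core_radius=core, width=outer - core,
                       occupancy=occupancy)


def lipid_contact_ratio(traj: Trajectory, groupings: dict[str, tuple[list[str], list[str]]] | None = None,
                        cutoff: float = DEFAULT_RECEPTOR_LIPID_CUTOFF,
                        receptor_indices: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Time series of receptor-lipid contact-count ratios.

    Each grouping maps a name to (numerator species, denominator
    species). Contacts are receptor-lipid particle pairs within the
    cutoff, normalised per available lipid particle of the class before
    the ratio is taken. Frames with zero denominator contacts yield NaN
    (flagged undefined).

    Default grouping: 'UNSAT/SAT' by tail saturation class (a lipid
    counts as unsaturated when any tail is unsaturated).
    """
    ref = traj.receptor_indices if receptor_indices is None else np.asarray(receptor_indices)
    if ref.size == 0:
        raise ValueError("trajectory contains no receptors")
    if groupings is None:
        unsat, sat = [], []
        for name, sp in traj.species.items():
            if sp.role != "lipid":
                continue
            (unsat if "unsaturated" in sp.saturation else sat).append(name)
        groupings = {"UNSAT/SAT": (sorted(unsat), sorted(sat))}

    def class_counts(species_list: list[str]) -> tuple[np.ndarray, int]:
        idx = np.concatenate(
            [traj.indices_where(species=s) for s in species_list]
        ) if species_list else np.array([], dtype=int)
        idx = idx[~np.isin(idx, ref)]
        if idx.size == 0:
            return np.zeros(traj.n_frames), 0
        out = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            dist = _lateral_distances(traj.positions[f, ref], traj.positions[f, idx], traj.box)
            out[f] = (dist < cutoff).sum()
        return out, int(idx.size)

    result: dict[str, np.ndarray] = {"times": traj.times.copy()}
    for name, (num_sp, den_sp) in groupings.items():
        num, n_num = class_counts(num_sp)
        den, n_den = class_counts(den_sp)
        with np.errstate(divide="ignore", invalid="ignore"):
            num_rate = num / n_num if n_num else np.zeros(traj.n_frames)
            den_rate = den / n_den if n_den else np.zeros(traj.n_frames)
            ratio = np.where(den_rate > 0, num_rate / np.where(den_rate > 0, den_rate, 1), np.nan)
        result[name] = ratio
    return result


def mixing_contact_fraction(traj: Trajectory, class_a: list[str], class_b: list[str],
                            cutoff: float = DEFAULT_LIPID_LIPID_CUTOFF) -> dict:
    """Demixing metric: fraction of lipid-lipid contacts that pair classes.

    f_AB(t) = (A-B contact pairs) / (all lipid-lipid contact pairs among
    A u B) per frame, with the random-mixing reference 2 x_A x_B. Values
    below the reference indicate saturated/unsaturated demixing. Frames
    without any lipid-lipid contact are NaN (flagged).
    """
    if not class_a or not class_b or set(class_a) & set(class_b):
        raise ValueError("classes must be disjoint and non-empty")
    idx_a = np.concatenate([traj.indices_where(species=s) for s in class_a])
    idx_b = np.concatenate([traj.indices_where(species=s) for s in class_b])
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both classes must have particles present")
    all_idx = np.concatenate([idx_a, idx_b])
    is_a = np.zeros(all_idx.size, dtype=bool)
    is_a[: idx_a.size] = True
    L = traj.box.in_plane_lengths
    f_ab = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pos = np.mod(traj.positions[f, all_idx], L)
        tree = cKDTree(pos, boxsize=L)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            f_ab[f] = np.nan
            continue
        cross = is_a[pairs[:, 0]] != is_a[pairs[:, 1]]
        f_ab[f] = cross.mean()
    x_a = idx_a.size / all_idx.size
    return {
        "times": traj.times.copy(),
        "f_ab": f_ab,
        "random_expectation": 2 * x_a * (1 - x_a),
        "undefined_frames": np.flatnonzero(np.isnan(f_ab)),
    }


def bound_fraction(traj: Trajectory, species: str, shell_radius: float,
                   receptor_indices: np.ndarray | None = None,
                   n_blocks: int = 5) -> dict:
    """Fraction of a lipid species inside any receptor's solvation shell.

    Membership is lateral distance to the nearest receptor COM below
    ``shell_radius``. Returns the per-frame series plus a time-averaged
    fraction with a block-averaged error.
    """
    if shell_radius <= 0:
        raise ValueError("shell radius must be positive")
    ref = traj.receptor_indices if receptor_indices is None else np.asarray(receptor_indices)
    if ref.size == 0:
        raise ValueError("trajectory contains no receptors")
    idx = traj.indices_where(species=species)
    idx = idx[~np.isin(idx, ref)]
    if idx.size == 0:
        raise ValueError(f"species {species!r} absent from trajectory")
    frac = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        dist = _lateral_distances(traj.positions[f, ref], traj.positions[f, idx], traj.box)
        frac[f] = (dist.min(axis=0) < shell_radius).mean()
    blocks = np.array_split(frac, min(n_blocks, frac.size))
    bm = np.array([b.mean() for b in blocks if b.size])
    err = float(np.std(bm, ddof=1) / np.sqrt(bm.size)) if bm.size > 1 else 0.0
    return {"times": traj.times.copy(), "fraction": frac,
            "mean": float(frac.mean()), "error": err}
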