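"""Receptor-receptor contact detection and oligomerisation kinetics.

Two receptors are in direct contact when the lateral minimum-image
distance between their centres of mass is strictly below the cutoff
(default 4.2 nm). The criterion is distance-only, so lipid-mediated
contacts are included implicitly. Oligomers are connected components of
the per-frame contact graph; aggregation kinetics are summarised as the
mean number of contacts per protomer over a late analysis window
(default: the final third of the trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import BoxSpec, minimum_image_displacement
from .trajectory import Trajectory

__all__ = [
    "ContactSeries",
    "OligomerPartition",
    "contact_matrix",
    "contacts_per_protomer",
    "oligomer_clusters",
    "classify_contacts",
    "compare_aggregation",
    "effective_time",
    "onset_radius",
    "pair_distance_series",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 4.2  # nm, centre-of-mass contact criterion
EFFECTIVE_TIME_FACTOR = 4.0  # coarse-grained friction speed-up convention


@dataclass
class ContactSeries:
    """Per-frame receptor contact matrices and per-protomer counts."""

    times: np.ndarray  # (F,)
    matrices: np.ndarray  # (F, R, R) bool
    counts: np.ndarray  # (F, R) int, row sums
    cutoff: float
    effective_time: bool = False

    @property
    def mean_per_frame(self) -> np.ndarray:
        return self.counts.mean(axis=1)


@dataclass
class OligomerPartition:
    """Connected-component partition of receptors for one frame."""

    labels: np.ndarray  # (R,) component id per receptor
    sizes: np.ndarray  # component sizes, one entry per component

    @property
    def size_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.sizes, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @property
    def order_per_receptor(self) -> np.ndarray:
        """Oligomer order (component size) each receptor belongs to."""
        return self.sizes[self.labels]


def contact_matrix(positions: np.ndarray, box: BoxSpec,
                   cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Boolean contact matrix for one frame of receptor COM positions.

    Strict inequality: a pair at exactly the cutoff is not a contact.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2:
        raise ValueError("expected (n_receptors, 2) positions")
    if cutoff >= min(box.in_plane_lengths) / 2:
        raise ValueError(
            f"cutoff {cutoff} nm >= half the box ({min(box.in_plane_lengths) / 2} nm): "
            "contacts ambiguous under periodic boundaries"
        )
    if pos.shape[0] == 0:
        raise ValueError("need at least one receptor")
    d = minimum_image_displacement(pos[:, None, :], pos[None, :, :], box)
    dist = np.sqrt((d**2).sum(axis=-1))
    mat = dist < cutoff
    np.fill_diagonal(mat, False)
    return mat


def _receptor_positions(traj: Trajectory, receptors: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    idx = traj.receptor_indices if receptors is None else np.asarray(receptors)
    if idx.size == 0:
        raise ValueError("trajectory contains no receptors")
    return idx, traj.positions[:, idx, :]


def contacts_per_protomer(trajs: Trajectory | list[Trajectory],
                          cutoff: float = DEFAULT_CUTOFF,
                          window: tuple[float, float] | None = None,
                          receptors: np.ndarray | None = None,
                          n_blocks: int = 5) -> tuple[list[ContactSeries], float, float]:
    """Windowed mean contacts per protomer with a replicate (or block) error.

    Parameters
    ----------
    trajs : Trajectory or list of Trajectory
        Replica runs of the same system.
    window : (t_start, t_end), optional
        Half-open analysis window in us; default is the final third of
        each run (the stable-contact regime).

    Returns
    -------
    series : list of ContactSeries
        Full per-frame series per replica (not windowed).
    mean : float
        Mean contacts per protomer over receptors, window frames and
        replicas.
    sem : float
        SEM over replicas when there are >= 3; otherwise a 5-block SEM
        within the (single or pooled) run.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    series: list[ContactSeries] = []
    replica_means = []
    windowed_frame_means = []
    for traj in trajs:
        idx, pos = _receptor_positions(traj, receptors)
        mats = np.empty((traj.n_frames, idx.size, idx.size), dtype=bool)
        for f in range(traj.n_frames):
            mats[f] = contact_matrix(pos[f], traj.box, cutoff)
        counts = mats.sum(axis=1)
        series.append(ContactSeries(traj.times, mats, counts, cutoff))
        if window is None:
            t0 = traj.times[0] + 2.0 / 3.0 * (traj.times[-1] - traj.times[0])
            t1 = np.inf
        else:
            t0, t1 = window
        sel = np.flatnonzero((traj.times >= t0) & (traj.times < t1))
        if window is not None and sel.size == 0:
            raise ValueError(f"empty analysis window {window} for run spanning "
                             f"[{traj.times[0]}, {traj.times[-1]}] us")
        if sel.size == 0:
            sel = np.array([traj.n_frames - 1])
        frame_means = counts[sel].mean(axis=1)
        replica_means.append(float(frame_means.mean()))
        windowed_frame_means.append(frame_means)
    mean = float(np.mean(replica_means))
    if len(replica_means) >= 3:
        sem = float(np.std(replica_means, ddof=1) / np.sqrt(len(replica_means)))
    else:
        pooled = np.concatenate(windowed_frame_means)
        blocks = np.array_split(pooled, min(n_blocks, pooled.size))
        bm = np.array([b.mean() for b in blocks if b.size])
        sem = float(np.std(bm, ddof=1) / np.sqrt(bm.size)) if bm.size > 1 else 0.0
    return series, mean, sem


def oligomer_clusters(matrix: np.ndarray) -> OligomerPartition:
    """Partition receptors into oligomers (connected contact components)."""
    mat = np.asarray(matrix, dtype=bool)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.array_equal(mat, mat.T) or mat.diagonal().any():
        raise ValueError("contact matrix must be symmetric with zero diagonal")
    n_comp, labels = connected_components(csr_matrix(mat), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return OligomerPartition(labels=labels, sizes=sizes)


def classify_contacts(matrix: np.ndarray, species_labels) -> dict:
    """Split contact edges into homomeric and heteromeric classes.

    ``species_labels`` gives 'A2A' or 'D2' per receptor. Returns counts
    and fractions for A2A-A2A, D2-D2 and A2A-D2 edges.
    """
    mat = np.asarray(matrix, dtype=bool)
    labels = np.asarray(species_labels, dtype=object).astype(str)
    if labels.shape[0] != mat.shape[0]:
        raise ValueError("one species label per receptor required")
    bad = set(labels) - {"A2A", "D2"}
    if bad:
        raise ValueError(f"unlabelled/unknown receptor species: {sorted(bad)}")
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    edge = mat[iu, ju]
    a, b = labels[iu[edge]], labels[ju[edge]]
    n_aa = int(np.sum((a == "A2A") & (b == "A2A")))
    n_dd = int(np.sum((a == "D2") & (b == "D2")))
    n_ad = int(edge.sum()) - n_aa - n_dd
    total = n_aa + n_dd + n_ad
    frac = (lambda x: x / total if total else 0.0)
    return {
        "A2A-A2A": n_aa,
        "D2-D2": n_dd,
        "A2A-D2": n_ad,
        "total": total,
        "fraction_homomeric": frac(n_aa + n_dd),
        "fraction_heteromeric": frac(n_ad),
    }


def compare_aggregation(runs_a: list[Trajectory], runs_b: list[Trajectory],
                        cutoff: float = DEFAULT_CUTOFF,
                        window: tuple[float, float] | None = None) -> dict:
    """Relative aggregation difference between two conditions.

    Computes windowed mean contacts per protomer per replica, the
    relative difference (mean_A - mean_B)/mean_B in percent, and a
    two-sided Welch t test on the per-replica means.
    """
    if not runs_a or not runs_b:
        raise ValueError("need >= 1 run per condition")

    def replica_means(runs):
        out = []
        for tr in runs:
            _, m, _ = contacts_per_protomer(tr, cutoff, window)
            out.append(m)
        return np.asarray(out)

    ma, mb = replica_means(runs_a), replica_means(runs_b)
    mean_a, mean_b = float(ma.mean()), float(mb.mean())
    result = {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "absolute_difference": mean_a - mean_b,
        "n_a": len(ma),
        "n_b": len(mb),
    }
    if mean_b == 0:
        result["relative_difference_pct"] = np.nan
        result["division_flagged"] = True
    else:
        result["relative_difference_pct"] = (mean_a - mean_b) / mean_b * 100.0
        result["division_flagged"] = False
    if len(ma) > 1 and len(mb) > 1 and (ma.std() > 0 or mb.std() > 0):
        t, p = stats.ttest_ind(ma, mb, equal_var=False)
        result["t"], result["p"] = float(t), float(p)
    else:
        result["t"], result["p"] = 0.0, 1.0
    return result


def effective_time(raw_time, factor: float = EFFECTIVE_TIME_FACTOR):
    """Convert raw coarse-grained time to effective time (x4 convention)."""
    t = np.asarray(raw_time, dtype=float)
    if np.any(t < 0):
        raise ValueError("raw time must be >= 0")
    out = t * factor
    return float(out) if np.isscalar(raw_time) or out.ndim == 0 else out


def onset_radius(cutoff: float = DEFAULT_CUTOFF, shell_width: float = 0.9) -> float:
    """Effective oligomerisation onset distance: cutoff + 2 shell widths.

    Two DHA-coated receptors begin to aggregate once their solvation
    shells touch, i.e. at the contact cutoff plus twice the in-plane
    shell width.
    """
    if cutoff <= 0 or shell_width < 0:
        raise ValueError("cutoff must be > 0 and shell_width >= 0")
    return cutoff + 2.0 * shell_width


def pair_distance_series(traj: Trajectory, i: int, j: int,
                         cutoff: float = DEFAULT_CUTOFF,
                         persistence: float = 0.1) -> dict:
    """Distance time series for a receptor pair plus first sustained contact.

    The onset is the first time the lateral COM distance stays strictly
    below the cutoff continuously for at least ``persistence`` us; None
    when no such stretch exists.
    """
    if i == j:
        raise ValueError("need two distinct receptors")
    span = traj.times[-1] - traj.times[0]
    if traj.n_frames > 1 and persistence > span:
        raise ValueError(f"persistence {persistence} us exceeds the run span {span} us")
    d = minimum_image_displacement(traj.positions[:, i, :], traj.positions[:, j, :], traj.box)
    dist = np.sqrt((d**2).sum(axis=-1))
    below = dist < cutoff
    onset = None
    f = 0
    while f < len(below):
        if below[f]:
            g = f
            while g + 1 < len(below) and below[g + 1]:
                g += 1
            stretch = traj.times[g] - traj.times[f]
            if stretch >= persistence or (traj.n_frames == 1 and below[0]):
                onset = float(traj.times[f])
                break
            f = g + 1
        else:
            f += 1
    return {"times": traj.times.copy(), "distance": dist, "onset": onset}
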