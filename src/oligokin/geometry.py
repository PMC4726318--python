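"""Periodic-box geometry for membrane-plane analyses.

All in-plane analyses (contacts, radial distributions, mean squared
displacements) use *lateral* minimum-image distances on a rectangular
periodic box. Lengths are in nm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoxSpec",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_positions",
    "unwrap_positions",
    "periodic_center_of_mass",
]


@dataclass(frozen=True)
class BoxSpec:
    """Rectangular simulation box.

    Parameters
    ----------
    lengths : tuple of float
        Edge length per axis in nm. Two entries for a planar membrane
        patch, three if an out-of-plane axis is carried along.
    periodic : tuple of bool
        Periodicity flag per axis. Membrane analyses require both
        in-plane axes to be periodic.
    """

    lengths: tuple[float, ...]
    periodic: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lengths = tuple(float(x) for x in self.lengths)
        object.__setattr__(self, "lengths", lengths)
        if self.periodic is None:
            object.__setattr__(self, "periodic", (True,) * len(lengths))
        else:
            object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))
        if len(self.periodic) != len(lengths):
            raise ValueError("periodic flags must match number of axes")
        if any(L <= 0 for L in lengths):
            raise ValueError(f"box lengths must be positive, got {lengths}")
        if not np.isfinite(lengths).all():
            raise ValueError("box lengths must be finite")

    @property
    def ndim(self) -> int:
        return len(self.lengths)

    @property
    def in_plane_lengths(self) -> np.ndarray:
        """The two membrane-plane edge lengths (first two axes)."""
        return np.asarray(self.lengths[:2])

    @property
    def area(self) -> float:
        return float(self.lengths[0] * self.lengths[1])

    def require_membrane_plane(self) -> None:
        if self.ndim < 2 or not (self.periodic[0] and self.periodic[1]):
            raise ValueError(
                "membrane analyses need a periodic 2D plane; "
                f"got periodic={self.periodic}"
            )


def _min_image(delta: np.ndarray, lengths: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Map displacement components onto (-L/2, L/2] on periodic axes."""
    delta = np.array(delta, dtype=float, copy=True)
    L = np.asarray(lengths, dtype=float)
    # ceil(d/L - 1/2) keeps +L/2 and maps -L/2 -> +L/2 (half-open convention)
    shift = np.ceil(delta / L - 0.5) * L
    wrapped = delta - shift
    if not periodic.all():
        free = ~periodic
        if np.any(np.abs(delta[..., free]) > L[free]):
            raise ValueError(
                "displacement exceeds box length on a non-periodic axis; geometry ambiguous"
            )
        wrapped[..., free] = delta[..., free]
    return wrapped


def minimum_image_displacement(p, q, box: BoxSpec) -> np.ndarray:
    """In-plane minimum-image displacement from ``p`` to ``q`` (nm).

    Components lie in (-L/2, L/2] on periodic axes. Inputs may be single
    points or arrays broadcasting to the same shape; only the first two
    axes (membrane plane) are considered. A displacement exceeding the
    box on a non-periodic axis raises (ambiguous geometry).
    """
    p = np.asarray(p, dtype=float)[..., :2]
    q = np.asarray(q, dtype=float)[..., :2]
    L = box.in_plane_lengths
    periodic = np.asarray(box.periodic[:2])
    return _min_image(q - p, L, periodic)


def minimum_image_distance(p, q, box: BoxSpec) -> np.ndarray:
    """Lateral minimum-image distance between points (nm)."""
    d = minimum_image_displacement(p, q, box)
    return np.sqrt((d**2).sum(axis=-1))


def wrap_positions(positions: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Wrap coordinates into [0, L) on periodic axes."""
    pos = np.array(positions, dtype=float, copy=True)
    L = np.asarray(box.lengths[: pos.shape[-1]])
    for ax in range(pos.shape[-1]):
        if box.periodic[ax]:
            pos[..., ax] = np.mod(pos[..., ax], L[ax])
    return pos


def unwrap_positions(positions: np.ndarray, box: BoxSpec) -> tuple[np.ndarray, np.ndarray]:
    """Remove periodic jumps from a (n_frames, n_particles, ndim) stack.

    Frame-to-frame displacements of the output equal the minimum-image
    displacements of the input, so trajectories become continuous and
    suitable for MSD estimation.

    Returns
    -------
    unwrapped : ndarray
        Continuous coordinates, same shape as input.
    suspect : ndarray of bool, shape (n_particles,)
        True for particles that moved >= L/2 along some periodic axis
        between consecutive frames (unwrapping unreliable).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3:
        raise ValueError("expected (n_frames, n_particles, ndim) array")
    nd = pos.shape[-1]
    L = np.asarray(box.lengths[:nd])
    periodic = np.asarray(box.periodic[:nd])
    raw = np.diff(pos, axis=0)
    steps = _min_image(raw, L, periodic)
    # a true displacement of exactly L/2 is indistinguishable from -L/2
    near_half = np.abs(np.abs(steps) - L / 2) < 1e-9
    suspect = np.any(near_half & periodic, axis=(0, 2))
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out, suspect


def periodic_center_of_mass(positions, weights, box: BoxSpec) -> np.ndarray:
    """Periodic-safe centre of mass via the circular-mean construction.

    Each periodic axis is mapped onto a circle and the weighted circular
    mean gives a seed point; the exact COM is then the linear average of
    minimum-image displacements from that seed. For clusters smaller
    than half the box this equals the naive COM recentred on any member.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[None, :]
    if pos.shape[0] == 0:
        raise ValueError("empty selection has no centre of mass")
    w = np.asarray(weights, dtype=float)
    if w.ndim == 0:
        w = np.full(pos.shape[0], float(w))
    if w.shape[0] != pos.shape[0]:
        raise ValueError("weights must match number of positions")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    nd = pos.shape[1]
    out = np.empty(nd)
    for ax in range(nd):
        L = box.lengths[ax]
        if box.periodic[ax]:
            theta = pos[:, ax] * (2 * np.pi / L)
            c = np.average(np.cos(theta), weights=w)
            s = np.average(np.sin(theta), weights=w)
            seed = (np.arctan2(s, c) % (2 * np.pi)) * L / (2 * np.pi)
            delta = _min_image(pos[:, ax] - seed, np.array([L]), np.array([True]))
            out[ax] = np.mod(seed + np.average(delta, weights=w), L)
        else:
            out[ax] = np.average(pos[:, ax], weights=w)
    return out
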