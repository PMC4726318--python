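"""Membrane composition accounting.

Translates phospholipid percentage tables into fatty-acyl tail censuses
(each phospholipid contributes two tails, cholesterol none), computes
the DHA (C22:6) share of total tails, and apportions integer particle
counts for the simulator.

Composition columns are read as counts per 100 phospholipids, so tail
percentages use the nominal 2 x 100 denominator. This is the convention
under which published brain-membrane model tables are internally
consistent for the C16:0 and C22:6 rows; columns that sum to 101 rather
than 100 (as printed tables sometimes do) are accepted within a +-1
tolerance and their tail percentages sum to the same excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .trajectory import Species

__all__ = [
    "MembraneComposition",
    "TailCensus",
    "tail_census",
    "dha_tail_fraction",
    "particle_counts",
    "preset",
    "PRESET_NAMES",
    "SPECIES_LIBRARY",
]

DHA_TAIL = "C22:6"

#: Tail assignments for the lipid species used in the model membranes.
#: SM: the sphingosine backbone is counted as one C18:1 chain and the
#: amide-linked acyl as C16:0 (one convention among several; only the
#: convention-robust C16:0 and C22:6 rows are relied on in tests).
SPECIES_LIBRARY: dict[str, Species] = {
    "DPPC": Species("DPPC", "lipid", ("C16:0", "C16:0"), ("saturated", "saturated")),
    "DSPC": Species("DSPC", "lipid", ("C18:0", "C18:0"), ("saturated", "saturated")),
    "DOPC": Species("DOPC", "lipid", ("C18:1", "C18:1"), ("unsaturated", "unsaturated")),
    "SDPC": Species("SDPC", "lipid", ("C22:6", "C18:0"), ("unsaturated", "saturated")),
    "SDPE": Species("SDPE", "lipid", ("C22:6", "C18:0"), ("unsaturated", "saturated")),
    "POPC": Species("POPC", "lipid", ("C16:0", "C18:1"), ("saturated", "unsaturated")),
    "SM": Species("SM", "lipid", ("C18:1", "C16:0"), ("unsaturated", "saturated")),
    "CHOL": Species("CHOL", "sterol"),
    "A2A": Species("A2A", "receptor_A2A"),
    "D2": Species("D2", "receptor_D2"),
}


@dataclass(frozen=True)
class MembraneComposition:
    """Phospholipid percentages plus a cholesterol fraction.

    ``phospholipids`` maps species name -> percent of phospholipids
    (columns read as counts per 100 phospholipids; sums within +-1 of
    100 are accepted). ``cholesterol`` is percent of *all* lipids.
    """

    phospholipids: dict[str, float]
    cholesterol: float = 0.0
    species: dict[str, Species] = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(SPECIES_LIBRARY)
        merged.update(self.species)
        object.__setattr__(self, "species", merged)
        total = sum(self.phospholipids.values())
        if abs(total - 100.0) > 1.0:
            raise ValueError(f"phospholipid percentages sum to {total}, expected 100 +- 1")
        if not (0 <= self.cholesterol < 100):
            raise ValueError("cholesterol percentage must be in [0, 100)")
        missing = [
            name
            for name in self.phospholipids
            if name not in self.species or self.species[name].role != "lipid"
        ]
        if missing:
            raise ValueError(f"species without (2-)tail assignment: {missing}")

    @property
    def phospholipid_total(self) -> float:
        return sum(self.phospholipids.values())


@dataclass(frozen=True)
class TailCensus:
    """Fatty-acyl tail counts per 100 phospholipids (exact rationals)."""

    counts: dict[str, Fraction]

    @property
    def total(self) -> Fraction:
        return sum(self.counts.values(), Fraction(0))

    @property
    def percentages(self) -> dict[str, Fraction]:
        """Percent per tail label against the nominal 200-tail total."""
        return {k: v / 2 for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tail": list(self.counts),
                "count_per_100_phospholipids": [float(v) for v in self.counts.values()],
                "percent": [float(v / 2) for v in self.counts.values()],
            }
        )


def tail_census(composition: MembraneComposition) -> TailCensus:
    """Count fatty-acyl tails per 100 phospholipids; cholesterol excluded."""
    counts: dict[str, Fraction] = {}
    for name, pct in composition.phospholipids.items():
        sp = composition.species[name]
        for tail in sp.tails:
            counts[tail] = counts.get(tail, Fraction(0)) + Fraction(pct).limit_denominator(10**6)
    return TailCensus(counts)


def round_half_away(x: float) -> int:
    """Round half away from zero (10.5 -> 11), unlike banker's rounding."""
    import math

    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def dha_tail_fraction(composition: MembraneComposition, rounding: str = "half-away") -> tuple[float, int]:
    """DHA (C22:6) share of total fatty-acyl tails.

    Returns the exact percentage and its integer-rounded report value.
    """
    census = tail_census(composition)
    exact = float(census.counts.get(DHA_TAIL, Fraction(0)) / 2)
    if rounding == "half-away":
        reported = round_half_away(exact)
    elif rounding == "nearest-even":
        reported = int(round(exact))
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return exact, reported


def particle_counts(composition: MembraneComposition, n_lipids: int) -> dict[str, int]:
    """Apportion ``n_lipids`` total lipids (cholesterol included) to species.

    Largest-remainder apportionment with deterministic ties broken by
    species name; counts sum exactly to ``n_lipids``.
    """
    shares: dict[str, Fraction] = {}
    chol = Fraction(composition.cholesterol).limit_denominator(10**6) / 100
    if chol > 0:
        shares["CHOL"] = chol * n_lipids
    pl_total = Fraction(composition.phospholipid_total).limit_denominator(10**6)
    remaining = (1 - chol) * n_lipids
    for name, pct in composition.phospholipids.items():
        if pct > 0:
            shares[name] = Fraction(pct).limit_denominator(10**6) / pl_total * remaining
    n_nonzero = len(shares)
    if n_lipids < n_nonzero:
        raise ValueError(f"n_lipids={n_lipids} cannot represent {n_nonzero} species")
    floors = {k: int(v) for k, v in shares.items()}
    leftover = n_lipids - sum(floors.values())
    order = sorted(shares, key=lambda k: (-(shares[k] - floors[k]), k))
    for k in order[:leftover]:
        floors[k] += 1
    dropped = [k for k, v in floors.items() if v == 0]
    if dropped:
        import warnings

        warnings.warn(f"species dropped at n_lipids={n_lipids}: {sorted(dropped)}", stacklevel=2)
    return floors


# ---------------------------------------------------------------------------
# named presets

_PRESETS = {
    # healthy-like brain model membrane: DHA-rich, 33% cholesterol
    "healthy": MembraneComposition(
        {"DPPC": 21, "DSPC": 7, "DOPC": 15, "SDPC": 21, "SM": 36}, cholesterol=33
    ),
    # diseased-like: DHA-poor, compensated with saturated lipids
    "diseased": MembraneComposition(
        {"DPPC": 33, "DSPC": 15, "DOPC": 11, "SDPC": 6, "SM": 36}, cholesterol=33
    ),
    # simplified very-high-DHA ternary mixture POPC:SDPE:CHOL = 30:50:20
    # (percent of all lipids -> 37.5:62.5 of phospholipids + 20% sterol)
    "ternary_high_dha": MembraneComposition(
        {"POPC": 37.5, "SDPE": 62.5}, cholesterol=20
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> MembraneComposition:
    """Named model-membrane composition: healthy / diseased / ternary_high_dha."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown composition preset {name!r}; have {PRESET_NAMES}") from None
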