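"""Assignment of observed unit cells to reference compounds.

Each automatically collected crystal either yields an indexed unit cell or
fails with a recorded failure mode (no diffraction, smeared diffraction,
multiple lattices, weak diffraction).  Indexed cells are matched against a
reference library using per-parameter tolerances — by default a maximum 1 A
deviation on each length and 10 deg on each angle — after optional Niggli
canonicalisation, which makes the comparison independent of the indexing
setting chosen by the processing software.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .cells import ReferenceCompound, UnitCell, niggli_reduce
from .errors import ConfigurationError, InputError

__all__ = [
    "Status",
    "CrystalObservation",
    "MatchResult",
    "UNIDENTIFIED",
    "match_cell",
    "classify_campaign",
]

#: Label used for indexed cells that match no library compound.
UNIDENTIFIED = "unidentified"


class Status(str, enum.Enum):
    """Outcome of one automated acquisition attempt."""

    INDEXED = "indexed"
    WEAK_DIFFRACTION = "weak_diffraction"
    NO_DIFFRACTION = "no_diffraction"
    MULTI_LATTICE = "multi_lattice"
    SMEARED = "smeared"


@dataclass(frozen=True)
class CrystalObservation:
    """One automated acquisition: status, observed cell, area, image reference."""

    crystal_id: str
    status: Status
    observed_cell: UnitCell | None = None
    rotation_range: float = 50.0
    image_ref: str | None = None
    area_um2: float | None = None

    def __post_init__(self) -> None:
        status = Status(self.status)
        object.__setattr__(self, "status", status)
        if status is Status.INDEXED and self.observed_cell is None:
            raise InputError(f"crystal {self.crystal_id}: indexed status requires a cell")
        if status is not Status.INDEXED and self.observed_cell is not None:
            raise InputError(f"crystal {self.crystal_id}: cell given for non-indexed status")
        if self.area_um2 is not None and not self.area_um2 > 0:
            raise InputError(f"crystal {self.crystal_id}: area must be positive")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one observed cell against the library.

    ``deviations`` holds |da|, |db|, |dc| in angstrom and |dalpha|, |dbeta|,
    |dgamma| in degrees against the assigned compound (ordered by sorted
    lengths); ``distance`` is the mean of the six deviations each scaled by
    its tolerance.  ``ambiguous`` flags observations for which more than one
    compound fell within tolerance.
    """

    crystal_id: str
    assigned: str
    deviations: tuple[float, float, float, float, float, float] = field(
        default=(0.0,) * 6
    )
    distance: float = float("inf")
    ambiguous: bool = False

    @property
    def identified(self) -> bool:
        return self.assigned != UNIDENTIFIED


def _sorted_parameters(cell: UnitCell) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Lengths sorted ascending, each angle following its opposite axis."""
    pairs = sorted(zip(cell.lengths, cell.angles))
    lengths = tuple(p[0] for p in pairs)
    angles = tuple(p[1] for p in pairs)
    return lengths, angles  # type: ignore[return-value]


def _fold_angles(angles: tuple[float, float, float]) -> tuple[float, float, float]:
    """Map each angle to its acute equivalent (theta -> min(theta, 180-theta)).

    The Niggli cell is discontinuous at the boundary between the all-acute
    and all-obtuse types: a lattice angle of exactly 90 deg reduces to the
    obtuse branch, while any noise can flip the reduced angles to their
    supplements.  Folding both cells onto acute angles makes the comparison
    continuous across that boundary.
    """
    return tuple(a if a <= 90.0 else 180.0 - a for a in angles)  # type: ignore[return-value]


_REDUCED_CACHE: dict[tuple[float, ...], UnitCell] = {}


def _reduced_cached(cell: UnitCell) -> UnitCell:
    # reference cells recur for every crystal of a campaign; memoise
    key = cell.parameters
    if key not in _REDUCED_CACHE:
        _REDUCED_CACHE[key] = niggli_reduce(cell)[0]
    return _REDUCED_CACHE[key]


def match_cell(
    observed: UnitCell,
    library: list[ReferenceCompound],
    tol_len: float = 1.0,
    tol_ang: float = 10.0,
    canonicalize: bool = True,
    crystal_id: str = "",
) -> MatchResult:
    """Match one observed cell against the reference library.

    A compound matches iff all three length deviations are within ``tol_len``
    and all three angle deviations within ``tol_ang``.  When several
    compounds match, the one with the smallest normalised distance wins and
    the result is flagged ``ambiguous``; ties break by lexicographic name.

    With ``canonicalize`` both cells are Niggli-reduced before comparison
    (robust to differing indexing settings); without it, the as-given
    parameters are compared after sorting lengths ascending.
    """
    if not library:
        raise ConfigurationError("reference library is empty")
    if not (tol_len > 0 and tol_ang > 0):
        raise ConfigurationError("tolerances must be positive")

    obs = niggli_reduce(observed)[0] if canonicalize else observed
    obs_len, obs_ang = _sorted_parameters(obs)
    if canonicalize:
        obs_ang = _fold_angles(obs_ang)

    candidates: list[tuple[float, str, tuple[float, ...]]] = []
    for comp in library:
        ref = _reduced_cached(comp.cell) if canonicalize else comp.cell
        ref_len, ref_ang = _sorted_parameters(ref)
        if canonicalize:
            ref_ang = _fold_angles(ref_ang)
        d_len = tuple(abs(o - r) for o, r in zip(obs_len, ref_len))
        d_ang = tuple(abs(o - r) for o, r in zip(obs_ang, ref_ang))
        if max(d_len) <= tol_len and max(d_ang) <= tol_ang:
            scaled = [d / tol_len for d in d_len] + [d / tol_ang for d in d_ang]
            distance = sum(scaled) / 6.0
            candidates.append((distance, comp.name, d_len + d_ang))

    if not candidates:
        return MatchResult(crystal_id=crystal_id, assigned=UNIDENTIFIED)
    candidates.sort(key=lambda t: (t[0], t[1]))
    distance, name, devs = candidates[0]
    return MatchResult(
        crystal_id=crystal_id,
        assigned=name,
        deviations=devs,  # type: ignore[arg-type]
        distance=distance,
        ambiguous=len(candidates) > 1,
    )


def classify_campaign(
    observations: list[CrystalObservation],
    library: list[ReferenceCompound],
    tol_len: float = 1.0,
    tol_ang: float = 10.0,
    canonicalize: bool = True,
) -> tuple[list[MatchResult], dict[Status, int]]:
    """Classify every observation of a campaign.

    Indexed observations are matched against the library; the other statuses
    are tallied but not matched.  Returns the match results (one per indexed
    observation, input order preserved) and a per-status tally that exactly
    partitions the input.
    """
    ids = [o.crystal_id for o in observations]
    if len(set(ids)) != len(ids):
        dupes = [i for i, n in Counter(ids).items() if n > 1]
        raise InputError(f"duplicate crystal ids: {dupes[:5]}")

    tally: dict[Status, int] = {s: 0 for s in Status}
    results: list[MatchResult] = []
    for obs in observations:
        tally[obs.status] += 1
        if obs.status is Status.INDEXED:
            assert obs.observed_cell is not None
            results.append(
                match_cell(
                    obs.observed_cell,
                    library,
                    tol_len=tol_len,
                    tol_ang=tol_ang,
                    canonicalize=canonicalize,
                    crystal_id=obs.crystal_id,
                )
            )
    return results, tally
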