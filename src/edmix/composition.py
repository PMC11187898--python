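"""Compound ratios and campaign statistics.

Two quantification modes are provided.  The *counting ratio* is a compound's
share of the identified crystals by number.  The *area-corrected ratio*
weights each identified crystal by its projected area: for compound ``comp``
it is ``S_comp / S_total`` where ``S_comp`` sums the areas of the crystals
assigned to the compound and ``S_total`` sums over all identified crystals.
Campaign-level statistics (identification rate, formulation ratios with an
explicit denominator policy) follow the three-way accounting of automated
campaigns: identified / indexed-but-unassigned / failed.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .classify import UNIDENTIFIED, CrystalObservation, MatchResult, Status
from .errors import UndefinedRatioError

__all__ = [
    "DenominatorPolicy",
    "CompositionReport",
    "counting_ratio",
    "area_corrected_ratio",
    "identification_rate",
    "formulation_ratio",
    "compare_to_input",
    "build_report",
]


class DenominatorPolicy(str, enum.Enum):
    """Choice of denominator for formulation (tablet-style) ratios.

    ``IDENTIFIED_PLUS_NONDIFFRACTING`` divides by identified plus
    non-diffracting grains, excluding weakly/undefined-diffracting ones — the
    appropriate policy when a large amorphous or undeclared-crystallinity
    fraction is expected.  ``IDENTIFIED_ONLY`` divides by identified crystals
    alone.
    """

    IDENTIFIED_ONLY = "identified_only"
    IDENTIFIED_PLUS_NONDIFFRACTING = "identified_plus_nondiffracting"


def counting_ratio(n_comp: int, n_total: int) -> float:
    """Percentage of identified crystals belonging to one compound.

    Returns the raw percentage; reports round to one decimal place.
    """
    if n_total <= 0:
        raise UndefinedRatioError("counting ratio undefined for zero identified crystals")
    if not 0 <= n_comp <= n_total:
        raise UndefinedRatioError(f"invalid counts: {n_comp}/{n_total}")
    return 100.0 * n_comp / n_total


def area_corrected_ratio(s_comp: float, s_total: float) -> float:
    """Percentage of summed crystal area belonging to one compound.

    ``s_total`` is the total area over *identified* crystals only.
    """
    if s_total <= 0:
        raise UndefinedRatioError("area ratio undefined for zero total area")
    if not 0 <= s_comp <= s_total * (1 + 1e-12):
        raise UndefinedRatioError(f"invalid areas: {s_comp}/{s_total}")
    return 100.0 * s_comp / s_total


def identification_rate(n_identified: int, n_selected: int) -> float:
    """Percentage of selected crystals that were successfully identified.

    Returns the raw percentage; reports round to the nearest integer.
    """
    if n_selected <= 0:
        raise UndefinedRatioError("identification rate undefined for empty campaign")
    if not 0 <= n_identified <= n_selected:
        raise UndefinedRatioError(f"invalid counts: {n_identified}/{n_selected}")
    return 100.0 * n_identified / n_selected


def formulation_ratio(
    n_comp: int,
    n_identified: int,
    n_no_diffraction: int,
    n_weak: int = 0,
    policy: DenominatorPolicy = DenominatorPolicy.IDENTIFIED_PLUS_NONDIFFRACTING,
) -> float:
    """Share of a formulation attributed to one crystalline compound.

    Under ``IDENTIFIED_PLUS_NONDIFFRACTING`` the denominator is
    ``n_identified + n_no_diffraction``; weakly-diffracting (undefined-status)
    grains are left out of the calculation entirely.  Under
    ``IDENTIFIED_ONLY`` the denominator is ``n_identified``.
    """
    if min(n_comp, n_identified, n_no_diffraction, n_weak) < 0:
        raise UndefinedRatioError("counts must be non-negative")
    policy = DenominatorPolicy(policy)
    if policy is DenominatorPolicy.IDENTIFIED_PLUS_NONDIFFRACTING:
        denom = n_identified + n_no_diffraction
    else:
        denom = n_identified
    if denom <= 0:
        raise UndefinedRatioError("formulation ratio has zero denominator")
    return 100.0 * n_comp / denom


@dataclass
class CompositionReport:
    """Per-compound ratios plus campaign statistics.

    ``table`` has one row per compound with columns ``compound, n_crystals,
    counting_ratio, area_um2, area_ratio, input_ratio, error`` (ratios in %,
    raw unrounded values; ``error`` is counting ratio minus input ratio in
    percentage points).  Missing areas leave ``area_ratio`` as NaN for the
    whole report only if no identified crystal carries an area.
    """

    table: pd.DataFrame
    n_selected: int
    n_identified: int
    denominator_policy: DenominatorPolicy = DenominatorPolicy.IDENTIFIED_ONLY
    status_tally: dict[str, int] = field(default_factory=dict)
    n_ambiguous: int = 0

    @property
    def identification_rate(self) -> float:
        return identification_rate(self.n_identified, self.n_selected)

    def rounded(self) -> pd.DataFrame:
        """Report table with the field's conventional rounding applied."""
        out = self.table.copy()
        for col in ("counting_ratio", "area_ratio", "input_ratio", "error"):
            if col in out:
                out[col] = out[col].round(1)
        out["area_um2"] = out["area_um2"].round(3)
        return out

    def to_json(self) -> str:
        payload = {
            "campaign": {
                "n_selected": self.n_selected,
                "n_identified": self.n_identified,
                "identification_rate_raw": self.identification_rate,
                "identification_rate": round(self.identification_rate),
                "denominator_policy": self.denominator_policy.value,
                "status_tally": dict(self.status_tally),
                "n_ambiguous": self.n_ambiguous,
            },
            "compounds": json.loads(self.table.to_json(orient="records")),
        }
        return json.dumps(payload, indent=2)


def build_report(
    matches: list[MatchResult],
    observations: list[CrystalObservation],
    compounds: list[str] | None = None,
    input_fractions: dict[str, float] | None = None,
    policy: DenominatorPolicy = DenominatorPolicy.IDENTIFIED_ONLY,
    drop_ambiguous: bool = False,
) -> CompositionReport:
    """Assemble the composition report for one classified campaign.

    ``n_selected`` counts every observation regardless of status;
    ``n_identified`` counts matches assigned to a compound.  Indexed
    observations that matched nothing contribute to ``n_selected`` only.
    Area ratios use the areas of identified crystals; crystals without a
    measured area fall back to counting (they contribute no area).
    """
    if drop_ambiguous:
        matches = [m for m in matches if not m.ambiguous]
    by_id = {o.crystal_id: o for o in observations}
    identified = [m for m in matches if m.identified]

    names = sorted(set(compounds or []) | {m.assigned for m in identified})
    rows = []
    n_identified = len(identified)
    areas_known = [
        m for m in identified if by_id.get(m.crystal_id) and by_id[m.crystal_id].area_um2
    ]
    s_total = sum(by_id[m.crystal_id].area_um2 for m in areas_known)  # type: ignore[misc]
    for name in names:
        mine = [m for m in identified if m.assigned == name]
        n = len(mine)
        s_comp = sum(
            by_id[m.crystal_id].area_um2
            for m in mine
            if by_id.get(m.crystal_id) and by_id[m.crystal_id].area_um2
        )
        row = {
            "compound": name,
            "n_crystals": n,
            "counting_ratio": counting_ratio(n, n_identified) if n_identified else math.nan,
            "area_um2": s_comp,
            "area_ratio": area_corrected_ratio(s_comp, s_total) if s_total > 0 else math.nan,
            "input_ratio": math.nan,
            "error": math.nan,
        }
        if input_fractions is not None:
            inp = float(input_fractions.get(name, 0.0))
            row["input_ratio"] = inp
            if n_identified:
                row["error"] = row["counting_ratio"] - inp
        rows.append(row)

    tally = {s.value: 0 for s in Status}
    for o in observations:
        tally[o.status.value] += 1

    table = pd.DataFrame(
        rows,
        columns=[
            "compound",
            "n_crystals",
            "counting_ratio",
            "area_um2",
            "area_ratio",
            "input_ratio",
            "error",
        ],
    )
    return CompositionReport(
        table=table,
        n_selected=len(observations),
        n_identified=n_identified,
        denominator_policy=DenominatorPolicy(policy),
        status_tally=tally,
        n_ambiguous=sum(1 for m in matches if m.ambiguous),
    )


def compare_to_input(
    report: CompositionReport, input_fractions: dict[str, float]
) -> tuple[dict[str, float], float]:
    """Per-compound error (observed minus input, percentage points) and the
    sample standard deviation of the per-compound (counting - area) differences.

    Compounds present in only one of the two name sets are treated as 0 % on
    the missing side.
    """
    tab = report.table.set_index("compound")
    names = sorted(set(tab.index) | set(input_fractions))
    errors = {}
    diffs = []
    for name in names:
        counting = tab["counting_ratio"].get(name, 0.0)
        counting = 0.0 if pd.isna(counting) else float(counting)
        area = tab["area_ratio"].get(name)
        errors[name] = counting - float(input_fractions.get(name, 0.0))
        if area is not None and not pd.isna(area):
            diffs.append(counting - float(area))
    if len(diffs) >= 2:
        mean = sum(diffs) / len(diffs)
        sigma = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1))
    else:
        sigma = 0.0
    return errors, sigma
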