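"""Readers and writers for the pipeline's plain-text formats.

* reference library: CSV with header
  ``name,a,b,c,alpha,beta,gamma,laue_group,density,source``
* observation table: CSV with header
  ``crystal_id,status,a,b,c,alpha,beta,gamma,rotation_range,image_ref``
  (cell fields empty for non-indexed statuses)
* match table: CSV with header
  ``crystal_id,assigned,distance,ambiguous,d_a,d_b,d_c,d_alpha,d_beta,d_gamma``
* reflection files: whitespace/comma-delimited ``h k l I sigma`` records with
  a minimal ``!CELL=``, ``!LAUE=``, ``!ID=`` header block modelled on
  XDS-ASCII conventions; ``!`` and ``#`` start comments.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import ReferenceCompound, UnitCell
from .classify import CrystalObservation, MatchResult, Status
from .errors import InputError
from .merge import ReflectionSet

__all__ = [
    "read_library",
    "write_library",
    "read_observations",
    "write_observations",
    "write_match_table",
    "read_match_table",
    "read_reflection_file",
    "write_reflection_file",
]

_LIB_COLUMNS = ["name", "a", "b", "c", "alpha", "beta", "gamma", "laue_group", "density", "source"]
_OBS_COLUMNS = [
    "crystal_id",
    "status",
    "a",
    "b",
    "c",
    "alpha",
    "beta",
    "gamma",
    "rotation_range",
    "image_ref",
]


def read_library(path: str | Path) -> list[ReferenceCompound]:
    df = pd.read_csv(path)
    missing = set(_LIB_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise InputError(f"library file missing columns: {sorted(missing)}")
    if df["name"].duplicated().any():
        raise InputError("compound names must be unique within a library")
    out = []
    for _, row in df.iterrows():
        density = row.get("density")
        out.append(
            ReferenceCompound(
                name=str(row["name"]),
                cell=UnitCell(*(float(row[c]) for c in ("a", "b", "c", "alpha", "beta", "gamma"))),
                laue_group=str(row["laue_group"]),
                density=None if density is None or pd.isna(density) else float(density),
                source=str(row.get("source", "") or ""),
            )
        )
    return out


def write_library(compounds: list[ReferenceCompound], path: str | Path) -> None:
    rows = [
        {
            "name": c.name,
            **dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), c.cell.parameters)),
            "laue_group": c.laue_group,
            "density": c.density,
            "source": c.source,
        }
        for c in compounds
    ]
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, index=False)


def read_observations(path: str | Path) -> list[CrystalObservation]:
    df = pd.read_csv(path)
    missing = set(_OBS_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise InputError(f"observation table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        status = Status(str(row["status"]))
        cell = None
        if status is Status.INDEXED:
            try:
                cell = UnitCell(
                    *(float(row[c]) for c in ("a", "b", "c", "alpha", "beta", "gamma"))
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise InputError(
                    f"crystal {row['crystal_id']}: indexed status requires a full cell"
                ) from exc
        image_ref = row.get("image_ref")
        area = row.get("area_um2")
        out.append(
            CrystalObservation(
                crystal_id=str(row["crystal_id"]),
                status=status,
                observed_cell=cell,
                rotation_range=float(row.get("rotation_range", 50.0) or 50.0),
                image_ref=None if image_ref is None or pd.isna(image_ref) else str(image_ref),
                area_um2=None if area is None or pd.isna(area) else float(area),
            )
        )
    return out


def write_observations(
    observations: list[CrystalObservation], path: str | Path, include_area: bool = True
) -> None:
    rows = []
    for o in observations:
        cell = o.observed_cell
        row = {
            "crystal_id": o.crystal_id,
            "status": o.status.value,
            **dict(
                zip(
                    ("a", "b", "c", "alpha", "beta", "gamma"),
                    cell.parameters if cell else (math.nan,) * 6,
                )
            ),
            "rotation_range": o.rotation_range,
            "image_ref": o.image_ref or "",
        }
        if include_area:
            row["area_um2"] = o.area_um2
        rows.append(row)
    cols = _OBS_COLUMNS + (["area_um2"] if include_area else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_match_table(matches: list[MatchResult], path: str | Path) -> None:
    rows = []
    for m in matches:
        d = m.deviations if m.identified else (math.nan,) * 6
        rows.append(
            {
                "crystal_id": m.crystal_id,
                "assigned": m.assigned,
                "distance": m.distance if m.identified else math.nan,
                "ambiguous": m.ambiguous,
                "d_a": d[0],
                "d_b": d[1],
                "d_c": d[2],
                "d_alpha": d[3],
                "d_beta": d[4],
                "d_gamma": d[5],
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "crystal_id",
            "assigned",
            "distance",
            "ambiguous",
            "d_a",
            "d_b",
            "d_c",
            "d_alpha",
            "d_beta",
            "d_gamma",
        ],
    ).to_csv(path, index=False)


def read_match_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_reflection_file(path: str | Path) -> ReflectionSet:
    """Parse one XDS-ASCII-style reflection file."""
    dataset_id = Path(path).stem
    cell = None
    laue = "-1"
    hkl, inten, sig = [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(("!", "#")):
            body = line.lstrip("!#").strip()
            if body.upper().startswith("CELL="):
                vals = [float(x) for x in re.split(r"[,\s]+", body[5:].strip()) if x]
                if len(vals) != 6:
                    raise InputError(f"{path}:{lineno}: !CELL= needs six values")
                cell = UnitCell(*vals)
            elif body.upper().startswith("LAUE="):
                laue = body[5:].strip()
            elif body.upper().startswith("ID="):
                dataset_id = body[3:].strip()
            continue
        fields = [x for x in re.split(r"[,\s]+", line) if x]
        if len(fields) < 5:
            raise InputError(f"{path}:{lineno}: expected 'h k l I sigma'")
        hkl.append([int(fields[0]), int(fields[1]), int(fields[2])])
        inten.append(float(fields[3]))
        sig.append(float(fields[4]))
    if cell is None:
        raise InputError(f"{path}: missing !CELL= header")
    if not hkl:
        raise InputError(f"{path}: no reflection records")
    return ReflectionSet(
        dataset_id=dataset_id,
        cell=cell,
        laue_group=laue,
        hkl=np.array(hkl),
        intensity=np.array(inten),
        sigma=np.array(sig),
    )


def write_reflection_file(rs: ReflectionSet, path: str | Path) -> None:
    lines = [
        f"!ID= {rs.dataset_id}",
        "!CELL= " + " ".join(f"{x:.4f}" for x in rs.cell.parameters),
        f"!LAUE= {rs.laue_group}",
        "!  h  k  l  I  sigma",
    ]
    for (h, k, l), i, s in zip(rs.hkl, rs.intensity, rs.sigma):
        lines.append(f"{h:4d} {k:4d} {l:4d} {i:14.4f} {s:12.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
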