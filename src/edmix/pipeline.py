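"""Run configuration, pipeline orchestration and report writing.

``run_pipeline`` ties the stages together: classify every observation
against the library, re-measure crystal areas from images when present,
assemble the composition report, and optionally select the best merge subset
per compound from reflection files.  Per-crystal failures are logged and
tallied, never fatal; configuration errors are fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import yaml

from . import io as edio
from .area import crystal_area, segment_particles
from .classify import CrystalObservation, Status, classify_campaign
from .composition import CompositionReport, DenominatorPolicy, build_report
from .errors import ConfigurationError, EdmixError, MissingCrystalError
from .merge import MergeScore, best_subset

logger = logging.getLogger("edmix")

__all__ = ["RunConfig", "run_pipeline", "write_report", "side_by_side_table"]


@dataclass
class RunConfig:
    """Validated knobs of one pipeline run."""

    library: str = ""
    observations: str = ""
    output_dir: str = "edmix_out"
    tol_len: float = 1.0
    tol_ang: float = 10.0
    canonicalize: bool = True
    denominator_policy: str = DenominatorPolicy.IDENTIFIED_ONLY.value
    drop_ambiguous: bool = False
    pixel_size: float = 0.01
    threshold: float | str = "auto"
    min_particle_px: int = 10
    connectivity: int = 8
    selection: str = "nearest_center"
    d_min: float = 1.0
    k_max: int = 3
    strategy: str = "exhaustive"
    cc_seed: int = 0
    seed: int = 0
    reflection_files: list[str] = field(default_factory=list)
    input_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tol_len <= 0 or self.tol_ang <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.d_min <= 0:
            raise ConfigurationError("d_min must be positive")
        if self.k_max < 1:
            raise ConfigurationError("k_max must be at least 1")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if self.strategy not in ("exhaustive", "greedy"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.selection not in ("largest", "nearest_center", "sum"):
            raise ConfigurationError(f"unknown selection {self.selection!r}")
        DenominatorPolicy(self.denominator_policy)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _measure_areas(
    observations: list[CrystalObservation], config: RunConfig, base_dir: Path
) -> list[CrystalObservation]:
    """Replace each observation's area with one segmented from its image."""
    out = []
    for obs in observations:
        if not obs.image_ref:
            out.append(obs)
            continue
        path = Path(obs.image_ref)
        if not path.is_absolute():
            path = base_dir / path
        try:
            img = iio.imread(path)
            meas = segment_particles(
                img,
                threshold=config.threshold,
                min_particle_px=config.min_particle_px,
                connectivity=config.connectivity,
                pixel_size=config.pixel_size,
                image_ref=str(path),
            )
            area = crystal_area(meas, selection=config.selection)
            out.append(
                CrystalObservation(
                    crystal_id=obs.crystal_id,
                    status=obs.status,
                    observed_cell=obs.observed_cell,
                    rotation_range=obs.rotation_range,
                    image_ref=obs.image_ref,
                    area_um2=area,
                )
            )
            logger.info("crystal %s: area %.4f um2 from %s", obs.crystal_id, area, path.name)
        except (MissingCrystalError, FileNotFoundError, OSError) as exc:
            logger.warning("crystal %s: area unavailable (%s); counting fallback", obs.crystal_id, exc)
            out.append(
                CrystalObservation(
                    crystal_id=obs.crystal_id,
                    status=obs.status,
                    observed_cell=obs.observed_cell,
                    rotation_range=obs.rotation_range,
                    image_ref=obs.image_ref,
                    area_um2=None,
                )
            )
    return out


def run_pipeline(
    config: RunConfig,
) -> tuple[CompositionReport, dict[str, MergeScore]]:
    """Execute classify -> area -> composition -> optional merge selection."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    library = edio.read_library(config.library)
    observations = edio.read_observations(config.observations)
    logger.info("loaded %d compounds, %d observations", len(library), len(observations))

    if any(o.image_ref for o in observations):
        observations = _measure_areas(observations, config, Path(config.observations).parent)

    matches, tally = classify_campaign(
        observations,
        library,
        tol_len=config.tol_len,
        tol_ang=config.tol_ang,
        canonicalize=config.canonicalize,
    )
    for m in matches:
        logger.info("crystal %s -> %s", m.crystal_id, m.assigned)
    edio.write_match_table(matches, out_dir / "matches.csv")

    report = build_report(
        matches,
        observations,
        compounds=[c.name for c in library],
        input_fractions=config.input_fractions or None,
        policy=DenominatorPolicy(config.denominator_policy),
        drop_ambiguous=config.drop_ambiguous,
    )
    write_report(report, out_dir)

    merge_results: dict[str, MergeScore] = {}
    if config.reflection_files:
        sets = [edio.read_reflection_file(p) for p in config.reflection_files]
        by_compound: dict[str, list] = {}
        for rs in sets:
            # group reflection sets with the compound whose cell they carry
            best_name, best_dist = None, float("inf")
            for comp in library:
                d = max(
                    abs(x - y) for x, y in zip(rs.cell.lengths, comp.cell.lengths)
                )
                if d < best_dist:
                    best_name, best_dist = comp.name, d
            by_compound.setdefault(best_name or rs.dataset_id, []).append(rs)
        for name, group in sorted(by_compound.items()):
            try:
                merge_results[name] = best_subset(
                    group,
                    k_max=min(config.k_max, len({g.dataset_id for g in group})),
                    d_min=config.d_min,
                    strategy=config.strategy,
                    cc_seed=config.cc_seed,
                )
            except EdmixError as exc:
                logger.warning("merge selection failed for %s: %s", name, exc)
        _write_merge_table(merge_results, out_dir / "merge_selection.csv")

    return report, merge_results


def write_report(report: CompositionReport, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.rounded().to_csv(out_dir / "composition.csv", index=False)
    (out_dir / "composition.json").write_text(report.to_json())


def _write_merge_table(results: dict[str, MergeScore], path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "compound": name,
            "subset": "+".join(ms.subset),
            "completeness": round(ms.completeness, 2),
            "multiplicity": round(ms.multiplicity, 3),
            "r_merge": round(ms.r_merge, 5),
            "r_meas": round(ms.r_meas, 5),
            "cc_half": round(ms.cc_half, 5),
            "score": round(ms.score, 5),
        }
        for name, ms in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def side_by_side_table(report: CompositionReport) -> str:
    """Input-vs-observed comparison as fixed-width text, one compound per row."""
    tab = report.rounded()
    lines = [
        f"{'compound':<26}{'input %':>9}{'counting %':>12}{'area-corr %':>13}{'error':>8}",
        "-" * 68,
    ]
    for _, row in tab.iterrows():
        def fmt(v, width):
            import math as _m

            if v is None or (isinstance(v, float) and _m.isnan(v)):
                return f"{'-':>{width}}"
            return f"{v:>{width}.1f}"

        lines.append(
            f"{row['compound']:<26}"
            + fmt(row["input_ratio"], 9)
            + fmt(row["counting_ratio"], 12)
            + fmt(row["area_ratio"], 13)
            + fmt(row["error"], 8)
        )
    lines.append("-" * 68)
    lines.append(
        f"identified {report.n_identified}/{report.n_selected} crystals "
        f"({report.identification_rate:.0f}%)"
    )
    return "\n".join(lines)
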