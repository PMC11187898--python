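"""Projected crystal area from grayscale images.

Mirrors the classic particle-analysis recipe: binarise the image at a global
threshold (manual or Otsu), label connected components, discard specks below
a minimum pixel count, and convert the selected particle's pixel count to
square micrometres via the pixel size.  The acquisition centres the target
crystal in the frame, so the default particle selection is the component
whose centroid lies nearest the image centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigurationError, MissingCrystalError, NoThresholdError

__all__ = ["ParticleMeasurement", "segment_particles", "crystal_area", "size_filter_flags"]

#: Equivalent-circle diameter window (um) within which crystals were picked.
SIZE_WINDOW_UM = (0.2, 1.5)


@dataclass
class ParticleMeasurement:
    """Particles found in one image.

    ``areas_px`` are pixel counts of the surviving connected components
    (each >= ``min_particle_px``); ``centroids_px`` their (row, col)
    centroids; ``area_um2`` is the area of the default-selected particle
    (nearest the image centre), 0 when no particle survived.
    """

    image_ref: str
    n_particles: int
    areas_px: list[int]
    threshold_used: float
    pixel_size: float
    area_um2: float = 0.0
    auto_threshold: bool = False
    centroids_px: list[tuple[float, float]] = field(default_factory=list)
    image_shape: tuple[int, int] = (0, 0)


def segment_particles(
    image: np.ndarray,
    threshold: float | str = "auto",
    min_particle_px: int = 10,
    connectivity: int = 8,
    pixel_size: float = 1.0,
    invert: bool = False,
    image_ref: str = "",
) -> ParticleMeasurement:
    """Binarise, label and measure particles in a grayscale image.

    In the default dark-field convention pixels with intensity >= threshold
    are foreground; ``invert`` selects the bright-field convention
    (<= threshold).  ``threshold='auto'`` uses Otsu's between-class variance
    maximisation.  Components with fewer than ``min_particle_px`` pixels are
    discarded.  ``connectivity`` is 4 (edge-connected) or 8 (edge or corner).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise NoThresholdError("image must be a non-empty 2-D grayscale array")
    if connectivity not in (4, 8):
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity}")

    if threshold == "auto":
        if np.ptp(img) == 0:
            raise NoThresholdError("cannot auto-threshold a constant image")
        thr = float(threshold_otsu(img))
        auto = True
    else:
        thr = float(threshold)  # type: ignore[arg-type]
        if not np.isfinite(thr):
            raise NoThresholdError(f"threshold must be finite, got {thr}")
        auto = False

    mask = (img <= thr) if invert else (img >= thr)
    labels = label(mask, connectivity=1 if connectivity == 4 else 2)
    areas: list[int] = []
    centroids: list[tuple[float, float]] = []
    for region in regionprops(labels):
        if region.area >= min_particle_px:
            areas.append(int(region.area))
            centroids.append(tuple(region.centroid))  # type: ignore[arg-type]

    meas = ParticleMeasurement(
        image_ref=image_ref,
        n_particles=len(areas),
        areas_px=areas,
        threshold_used=thr,
        pixel_size=float(pixel_size),
        auto_threshold=auto,
        centroids_px=centroids,
        image_shape=img.shape,  # type: ignore[arg-type]
    )
    if areas:
        meas.area_um2 = crystal_area(meas, selection="nearest_center")
    return meas


def crystal_area(meas: ParticleMeasurement, selection: str = "nearest_center") -> float:
    """Area in um^2 of the selected particle.

    ``selection`` is ``largest``, ``nearest_center`` (centroid closest to the
    image centre; ties break by smallest label index) or ``sum`` (all
    particles).  Raises :class:`MissingCrystalError` when no particle exists
    and a single particle is required — callers treat the crystal's area as
    absent and fall back to counting.
    """
    if selection not in ("largest", "nearest_center", "sum"):
        raise ConfigurationError(f"unknown selection {selection!r}")
    if selection == "sum":
        return sum(meas.areas_px) * meas.pixel_size**2
    if meas.n_particles == 0:
        raise MissingCrystalError(f"no particle found in {meas.image_ref or 'image'}")
    if selection == "largest":
        idx = max(range(meas.n_particles), key=lambda i: (meas.areas_px[i], -i))
    else:
        cy, cx = (meas.image_shape[0] - 1) / 2.0, (meas.image_shape[1] - 1) / 2.0
        # tie-break deterministically on the smallest label index
        idx = min(
            range(meas.n_particles),
            key=lambda i: (
                math.hypot(meas.centroids_px[i][0] - cy, meas.centroids_px[i][1] - cx),
                i,
            ),
        )
    return meas.areas_px[idx] * meas.pixel_size**2


def size_filter_flags(
    meas: ParticleMeasurement, window_um: tuple[float, float] = SIZE_WINDOW_UM
) -> list[bool]:
    """Flag particles whose equivalent-circle diameter falls outside the
    picking window (default 0.2–1.5 um), per particle."""
    lo, hi = window_um
    flags = []
    for a_px in meas.areas_px:
        d = 2.0 * math.sqrt(a_px * meas.pixel_size**2 / math.pi)
        flags.append(not lo <= d <= hi)
    return flags
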