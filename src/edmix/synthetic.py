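"""Synthetic campaign generator.

Emulates a full automated electron-diffraction campaign on a crystalline
mixture so every other module is testable without instrument data: a
reference library, per-crystal observations with noisy cells and failure
modes, grayscale crystal images, and partial-wedge reflection lists.

The defaults model the study conditions of a well-behaved amino-acid
mixture: nine compounds at fractions between 5 and 23 %, Gaussian cell noise
well inside the matching tolerances (sigma 0.1 A / 0.3 deg), a 75 % indexing
success rate (15 % no diffraction, 5 % weak, 3 % multiple lattices, 2 %
smeared), and a truncated log-normal crystal-area distribution spanning the
0.2–1.5 um picking window.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .cells import ReferenceCompound, UnitCell
from .classify import CrystalObservation, Status
from .errors import GenerationError, SpecError
from .merge import ReflectionSet, count_theoretical_unique, resolution, _map_many

__all__ = [
    "MixtureSpec",
    "default_library",
    "default_fractions",
    "generate_campaign",
    "render_crystal_image",
    "generate_reflections",
]

#: Mixture-C-style volume fractions (percent) used as generator defaults.
_DEFAULT_FRACTIONS = {
    "L-Glutamic acid": 17.7,
    "L-Alanine": 5.4,
    "L-Tyrosine": 8.6,
    "L-Serine": 5.0,
    "L-Valine": 12.7,
    "L-Cysteine": 23.0,
    "L-Threonine": 5.0,
    "L-Aspartic acid": 10.2,
    "L-Glutamine": 12.4,
}


def default_library() -> list[ReferenceCompound]:
    """The packaged nine-compound amino-acid reference library."""
    from .io import read_library  # local import to avoid a cycle

    with resources.as_file(
        resources.files("edmix.data") / "mixture_c_library.csv"
    ) as path:
        return read_library(path)


def default_fractions() -> dict[str, float]:
    return dict(_DEFAULT_FRACTIONS)


@dataclass
class MixtureSpec:
    """Recipe for one synthetic campaign.

    ``compounds`` pairs each reference compound with its fraction in percent
    (must sum to 100); ``fraction_basis`` states whether fractions are shares
    of crystal counts or of total area.  ``cell_noise`` is (sigma_len A,
    sigma_ang deg) of independent Gaussian noise per cell parameter.  Failure
    probabilities must sum to at most 1; the remainder indexes successfully.
    ``area_model`` is (mu, sigma) of a log-normal in um^2 truncated to
    ``area_range``.
    """

    compounds: list[tuple[ReferenceCompound, float]]
    fraction_basis: str = "count"
    n_crystals: int = 1000
    cell_noise: tuple[float, float] = (0.1, 0.3)
    p_no_diffraction: float = 0.15
    p_weak: float = 0.05
    p_multi: float = 0.03
    p_smeared: float = 0.02
    area_model: tuple[float, float] = (math.log(0.3), 0.6)
    area_range: tuple[float, float] = (0.05, 1.8)
    failure_multipliers: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.compounds)
        if not self.compounds or abs(total - 100.0) > 1e-6:
            raise SpecError(f"fractions must sum to 100, got {total}")
        probs = (self.p_no_diffraction, self.p_weak, self.p_multi, self.p_smeared)
        if any(p < 0 for p in probs) or sum(probs) > 1:
            raise SpecError("failure probabilities must be non-negative and sum to <= 1")
        if self.fraction_basis not in ("count", "area"):
            raise SpecError(f"unknown fraction basis {self.fraction_basis!r}")
        if self.n_crystals <= 0:
            raise SpecError("n_crystals must be positive")

    @classmethod
    def default(cls, n_crystals: int = 1000, seed: int = 0, **kwargs) -> "MixtureSpec":
        lib = {c.name: c for c in default_library()}
        compounds = [(lib[name], frac) for name, frac in _DEFAULT_FRACTIONS.items()]
        return cls(compounds=compounds, n_crystals=n_crystals, seed=seed, **kwargs)


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_campaign(
    spec: MixtureSpec,
) -> tuple[list[CrystalObservation], pd.DataFrame]:
    """Draw one campaign: observations plus a truth table.

    Each crystal draws its generating compound from the mixture fractions
    (count basis: directly; area basis: proportional to fraction divided by
    the compound's mean area so that *area* shares match the fractions), a
    status from the failure probabilities (optionally modulated per compound),
    an observed cell equal to the reference plus independent Gaussian noise
    per parameter, and an area from the truncated log-normal.  The truth
    table records the generating compound, true area and status for every
    crystal.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    comps = [c for c, _ in spec.compounds]
    fracs = np.array([f for _, f in spec.compounds], dtype=float)
    weights = fracs / fracs.sum()
    if spec.fraction_basis == "area":
        # with a compound-independent area law the mean area is common, so
        # area-basis weights equal count weights; kept explicit for clarity
        mean_area = np.full(len(comps), math.exp(spec.area_model[0] + spec.area_model[1] ** 2 / 2))
        weights = (fracs / mean_area) / (fracs / mean_area).sum()

    choice = rng.choice(len(comps), size=spec.n_crystals, p=weights)
    areas = _truncated_lognormal(
        rng, spec.area_model[0], spec.area_model[1], *spec.area_range, spec.n_crystals
    )
    sigma_len, sigma_ang = spec.cell_noise

    observations: list[CrystalObservation] = []
    truth_rows = []
    statuses = [
        Status.NO_DIFFRACTION,
        Status.WEAK_DIFFRACTION,
        Status.MULTI_LATTICE,
        Status.SMEARED,
    ]
    base_probs = np.array(
        [spec.p_no_diffraction, spec.p_weak, spec.p_multi, spec.p_smeared]
    )
    for i in range(spec.n_crystals):
        comp = comps[choice[i]]
        mult = spec.failure_multipliers.get(comp.name, 1.0)
        probs = np.clip(base_probs * mult, 0, None)
        if probs.sum() > 1:
            probs = probs / probs.sum()
        u = rng.random()
        status = Status.INDEXED
        acc = 0.0
        for s, p in zip(statuses, probs):
            acc += p
            if u < acc:
                status = s
                break
        cid = f"xtal_{i:05d}"
        cell = None
        if status is Status.INDEXED:
            ref = comp.cell
            for _ in range(100):
                try:
                    cell = UnitCell(
                        *(np.array(ref.lengths) + rng.normal(0, sigma_len, 3) if sigma_len else ref.lengths),
                        *(np.array(ref.angles) + rng.normal(0, sigma_ang, 3) if sigma_ang else ref.angles),
                    )
                    break
                except Exception:
                    cell = None
            if cell is None:  # pragma: no cover - would need absurd noise
                raise GenerationError("could not draw a valid noisy cell")
        observations.append(
            CrystalObservation(
                crystal_id=cid,
                status=status,
                observed_cell=cell,
                rotation_range=50.0,
                area_um2=float(areas[i]),
            )
        )
        truth_rows.append(
            {
                "crystal_id": cid,
                "true_compound": comp.name,
                "true_area_um2": float(areas[i]),
                "status": status.value,
            }
        )
    return observations, pd.DataFrame(truth_rows)


def render_crystal_image(
    area_um2: float,
    pixel_size: float = 0.01,
    image_size: int = 256,
    noise_sd: float = 10.0,
    seed: int = 0,
    background: float = 40.0,
    foreground: float = 200.0,
) -> tuple[np.ndarray, int]:
    """Render one crystal as a filled ellipse on a noisy background.

    The ellipse has the requested area (um^2, converted via ``pixel_size`` in
    um/pixel), random axis ratio in [1, 3] and random orientation, and sits
    near the image centre.  Foreground/background contrast must be at least
    5x ``noise_sd``.  Returns the noisy uint8-range float image and the true
    rasterised pixel count (recorded in truth tables).
    """
    if area_um2 <= 0:
        raise GenerationError("requested crystal area must be positive")
    if foreground - background < 5 * noise_sd:
        raise GenerationError("contrast must be at least 5x the noise level")
    rng = np.random.default_rng(seed)
    n_px = area_um2 / pixel_size**2
    ecc = rng.uniform(1.0, 3.0)
    a_px = math.sqrt(n_px * ecc / math.pi)
    b_px = math.sqrt(n_px / (ecc * math.pi))
    if 2 * a_px > image_size - 4:
        raise GenerationError(
            f"crystal of {area_um2} um^2 does not fit a {image_size}px frame "
            f"at {pixel_size} um/px"
        )
    theta = rng.uniform(0, math.pi)
    jitter = rng.integers(-2, 3, size=2)
    center = (image_size // 2 + int(jitter[0]), image_size // 2 + int(jitter[1]))
    rr, cc = draw_ellipse(*center, a_px, b_px, shape=(image_size, image_size), rotation=theta)
    img = np.full((image_size, image_size), background, dtype=float)
    img[rr, cc] = foreground
    true_px = len(rr)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return np.clip(img, 0, 255), true_px


def generate_reflections(
    compound: ReferenceCompound,
    d_min: float = 1.0,
    wedge_fraction: float = 0.3,
    scale: float = 1.0,
    noise_frac: float = 0.05,
    seed: int = 0,
    dataset_id: str | None = None,
    intensity_seed: int | None = None,
) -> ReflectionSet:
    """Reflection list for one partial wedge of a compound's lattice.

    True intensities per unique reflection are drawn once per compound from
    an exponential (Wilson-like) distribution — pass the same
    ``intensity_seed`` for every wedge of a compound so wedges share ground
    truth.  The wedge observes a random subset of the uniques of expected
    size ``wedge_fraction * N``, each 1–2 times, with multiplicative Gaussian
    noise: ``I_obs = scale * I_true * (1 + eps)``, ``eps ~ N(0, noise_frac)``,
    and ``sigma = noise_frac * scale * I_true`` clamped above zero.
    """
    if not 0 < wedge_fraction <= 1:
        raise GenerationError("wedge_fraction must lie in (0, 1]")
    cell = compound.cell
    laue = compound.laue_group
    # enumerate the unique reflections once (also validates d_min scale)
    count_theoretical_unique(cell, laue, d_min)
    hmax = [int(length / d_min) + 1 for length in cell.lengths]
    axes = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[(grid != 0).any(axis=1)]
    grid = grid[resolution(grid, cell) >= d_min]
    uniques = np.unique(_map_many(grid, laue), axis=0)

    int_rng = np.random.default_rng(
        intensity_seed
        if intensity_seed is not None
        else zlib.crc32(compound.name.encode()) % 2**31
    )
    i_true = int_rng.exponential(100.0, size=len(uniques))

    rng = np.random.default_rng(seed)
    observed = rng.random(len(uniques)) < wedge_fraction
    idx = np.flatnonzero(observed)
    if len(idx) == 0:
        idx = np.array([int(rng.integers(len(uniques)))])
    repeats = rng.integers(1, 3, size=len(idx))
    rows = np.repeat(idx, repeats)
    i_base = scale * i_true[rows]
    eps = rng.normal(0, noise_frac, size=len(rows)) if noise_frac > 0 else 0.0
    i_obs = i_base * (1 + eps)
    sig = np.maximum(noise_frac * i_base, 1e-6 * max(scale, 1e-9) * 100.0)
    return ReflectionSet(
        dataset_id=dataset_id or f"{compound.name}_w{seed}",
        cell=cell,
        laue_group=laue,
        hkl=uniques[rows],
        intensity=i_obs,
        sigma=sig,
    )
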