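"""Lattice primitives: unit cells, metric tensors and Niggli reduction.

A unit cell is described by the six parameters (a, b, c, alpha, beta, gamma)
with lengths in angstroms and angles in degrees.  Cells are compared
setting-independently by first reducing them to the canonical Niggli cell,
computed here with the iterative Krivy–Gruber algorithm on the lattice metric.

Transformation matrices follow the column-vector basis convention: a matrix
``M`` with integer entries and determinant +-1 maps the input basis
``(a, b, c)`` to the new basis ``(a, b, c) @ M``, so the metric transforms as
``G' = M.T @ G @ M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidCellError, ReductionError

__all__ = [
    "UnitCell",
    "MetricTensor",
    "ReferenceCompound",
    "cell_volume",
    "cell_to_metric",
    "metric_to_cell",
    "niggli_reduce",
    "is_niggli_reduced",
]

#: Relative tolerance for Niggli inequality comparisons (standard choice to
#: avoid cycling between nearly-equal branches).
NIGGLI_EPS_REL = 1e-5

_MAX_ITER = 1000


@dataclass(frozen=True)
class UnitCell:
    """Six lattice parameters; the identity card of a crystal form.

    Lengths in angstroms (positive), angles in degrees in the open
    interval (0, 180).  The angle triple must additionally yield a real,
    positive cell volume.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidCellError(f"cell length {name}={v!r} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 < v < 180):
                raise InvalidCellError(
                    f"cell angle {name}={v!r} must lie in the open interval (0, 180)"
                )
        # the discriminant equals (V / abc)^2; require it comfortably positive
        # so that near-coplanar axis triples are rejected as degenerate
        if self._volume_discriminant() <= 1e-6:
            raise InvalidCellError(
                f"angle triple ({self.alpha}, {self.beta}, {self.gamma}) "
                "does not describe a real lattice (degenerate or negative volume)"
            )

    def _volume_discriminant(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def volume(self) -> float:
        """Cell volume in cubic angstroms."""
        return cell_volume(self)

    def metric(self) -> "MetricTensor":
        return cell_to_metric(self)

    def niggli(self) -> "UnitCell":
        """Canonical Niggli-reduced cell of this lattice."""
        return niggli_reduce(self)[0]

    def isclose(self, other: "UnitCell", tol_len: float = 1e-6, tol_ang: float = 1e-4) -> bool:
        return all(
            abs(x - y) <= tol_len for x, y in zip(self.lengths, other.lengths)
        ) and all(abs(x - y) <= tol_ang for x, y in zip(self.angles, other.angles))


@dataclass(frozen=True)
class ReferenceCompound:
    """A named compound with its reference cell and matching metadata.

    ``laue_group`` uses the labels understood by :mod:`edmix.merge`
    (-1, 2/m, mmm, 4/m, 4/mmm, -3, -3m, 6/m, 6/mmm, m-3, m-3m).
    ``density`` (g/cm^3) is optional metadata used only by the synthetic
    generator; ``source`` is free text such as a CSD refcode.
    """

    name: str
    cell: UnitCell
    laue_group: str = "-1"
    density: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidCellError("compound name must be non-empty")
        if self.density is not None and not self.density > 0:
            raise InvalidCellError(f"density must be positive, got {self.density!r}")


class MetricTensor:
    """Symmetric 3x3 lattice metric G with G[i,j] = e_i . e_j.

    The six independent entries are (a^2, b^2, c^2, b.c cos(alpha),
    a.c cos(beta), a.b cos(gamma)).  Must be positive definite; round-trips
    with :class:`UnitCell` to within 1e-9 relative tolerance.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        g = np.asarray(matrix, dtype=float)
        if g.shape != (3, 3) or not np.allclose(g, g.T, rtol=0, atol=1e-9 * max(1.0, abs(g).max())):
            raise InvalidCellError("metric tensor must be a symmetric 3x3 matrix")
        g = 0.5 * (g + g.T)
        try:
            np.linalg.cholesky(g)
        except np.linalg.LinAlgError:
            raise InvalidCellError("metric tensor is not positive definite") from None
        self.matrix = g

    @property
    def entries(self) -> tuple[float, float, float, float, float, float]:
        g = self.matrix
        return (g[0, 0], g[1, 1], g[2, 2], g[1, 2], g[0, 2], g[0, 1])

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.matrix)))

    def cell(self) -> UnitCell:
        return metric_to_cell(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MetricTensor({self.matrix!r})"


def cell_volume(cell: UnitCell) -> float:
    """Triclinic volume ``abc * sqrt(1 - cos^2a - cos^2b - cos^2g + 2 cosa cosb cosg)``."""
    disc = cell._volume_discriminant()
    if disc <= 0:
        raise InvalidCellError("degenerate angle triple")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def cell_to_metric(cell: UnitCell) -> MetricTensor:
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    g = np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )
    return MetricTensor(g)


def metric_to_cell(metric: MetricTensor) -> UnitCell:
    g = metric.matrix
    a, b, c = (math.sqrt(g[i, i]) for i in range(3))
    cos_alpha = g[1, 2] / (b * c)
    cos_beta = g[0, 2] / (a * c)
    cos_gamma = g[0, 1] / (a * b)
    for name, cv in (("alpha", cos_alpha), ("beta", cos_beta), ("gamma", cos_gamma)):
        if abs(cv) >= 1:
            raise InvalidCellError(f"metric implies |cos {name}| >= 1")
    return UnitCell(
        a,
        b,
        c,
        math.degrees(math.acos(cos_alpha)),
        math.degrees(math.acos(cos_beta)),
        math.degrees(math.acos(cos_gamma)),
    )


# Krivy–Gruber step matrices, column-vector convention.
_M_SWAP_AB = np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]])
_M_SWAP_BC = np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]])


def niggli_reduce(
    cell: UnitCell, eps_rel: float = NIGGLI_EPS_REL, max_iter: int = _MAX_ITER
) -> tuple[UnitCell, np.ndarray]:
    """Reduce ``cell`` to its canonical Niggli cell.

    Returns ``(reduced_cell, M)`` where ``M`` is the integer transformation
    (determinant +-1, column-vector convention) taking the input basis to the
    reduced basis, i.e. ``G_reduced = M.T @ G_input @ M``.

    Implements the iterative Krivy–Gruber reduction on the metric tensor with
    a relative tolerance ``eps_rel`` on the inequality comparisons.

    Raises
    ------
    ReductionError
        If the iteration does not terminate within ``max_iter`` steps.
    """
    g = cell_to_metric(cell).matrix.copy()
    total = np.eye(3, dtype=int)
    eps = eps_rel * (g[0, 0] + g[1, 1] + g[2, 2]) / 3.0

    def apply(m: np.ndarray) -> None:
        nonlocal g, total
        g = m.T @ g @ m
        total = total @ m

    for _ in range(max_iter):
        A, B, C = g[0, 0], g[1, 1], g[2, 2]
        xi, eta, zeta = 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]

        # step 1: order a <= b
        if A > B + eps or (abs(A - B) <= eps and abs(xi) > abs(eta) + eps):
            apply(_M_SWAP_AB)
            continue
        # step 2: order b <= c
        if B > C + eps or (abs(B - C) <= eps and abs(eta) > abs(zeta) + eps):
            apply(_M_SWAP_BC)
            continue
        # steps 3/4: fix the signs of the off-diagonal terms
        neg = [x < -eps for x in (xi, eta, zeta)]
        nonzero = [abs(x) > eps for x in (xi, eta, zeta)]
        if all(nonzero) and sum(neg) % 2 == 0:
            # step 3 (all-acute branch): strictly nonzero product with an even
            # number of negative terms -> make all three positive
            f = [-1 if n else 1 for n in neg]
            if f != [1, 1, 1]:
                apply(np.diag(f))
                continue
        else:
            # step 4 (all-obtuse branch): make every term non-positive; a zero
            # term absorbs the leftover sign flip needed for det = +1
            f = [1, 1, 1]
            r = -1
            for idx, x in enumerate((xi, eta, zeta)):
                if x > eps:
                    f[idx] = -1
                elif not x < -eps:
                    r = idx
            if f[0] * f[1] * f[2] < 0:
                if r < 0:  # pragma: no cover - would indicate a logic bug
                    raise ReductionError("sign normalisation failed")
                f[r] = -1
            if f != [1, 1, 1]:
                apply(np.diag(f))
                continue
        # step 5
        if abs(xi) > B + eps or (abs(xi - B) <= eps and 2 * eta < zeta - eps) or (
            abs(xi + B) <= eps and zeta < -eps
        ):
            s = 1 if xi > 0 else -1
            apply(np.array([[1, 0, 0], [0, 1, -s], [0, 0, 1]]))
            continue
        # step 6
        if abs(eta) > A + eps or (abs(eta - A) <= eps and 2 * xi < zeta - eps) or (
            abs(eta + A) <= eps and zeta < -eps
        ):
            s = 1 if eta > 0 else -1
            apply(np.array([[1, 0, -s], [0, 1, 0], [0, 0, 1]]))
            continue
        # step 7
        if abs(zeta) > A + eps or (abs(zeta - A) <= eps and 2 * xi < eta - eps) or (
            abs(zeta + A) <= eps and eta < -eps
        ):
            s = 1 if zeta > 0 else -1
            apply(np.array([[1, -s, 0], [0, 1, 0], [0, 0, 1]]))
            continue
        # step 8
        total_sum = xi + eta + zeta + A + B
        if total_sum < -eps or (abs(total_sum) <= eps and 2 * (A + eta) + zeta > eps):
            apply(np.array([[1, 0, 1], [0, 1, 1], [0, 0, 1]]))
            continue
        # converged
        det = int(round(np.linalg.det(total)))
        if det not in (-1, 1):  # pragma: no cover - would indicate a logic bug
            raise ReductionError(f"transformation determinant {det} is not +-1")
        return metric_to_cell(MetricTensor(g)), total

    raise ReductionError(f"Niggli reduction did not converge within {max_iter} iterations")


def is_niggli_reduced(cell: UnitCell, eps_rel: float = NIGGLI_EPS_REL) -> bool:
    """True if ``cell`` already satisfies the Niggli conditions (up to tolerance)."""
    reduced, _ = niggli_reduce(cell, eps_rel=eps_rel)
    return cell.isclose(reduced, tol_len=1e-6 * max(cell.lengths), tol_ang=1e-4)
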