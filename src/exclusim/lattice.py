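"""Lattice geometry, the graph metric, and hard-core exclusion rules.

Cells of two types (1 = tumor, 2 = normal) live on the vertices of an L x L
square grid of unit squares.  Coordinates are 0-based ``(row, col)``.  The
distance between vertices is the graph metric -- the minimal number of unit
edges connecting them, i.e. the L1 (Manhattan) distance.

A configuration is *admissible* when every vertex holds at most one cell and
every pair of cells of types ``i`` and ``j`` sits at graph distance at least
``D(i, j)``, the exclusion distance for that type pair.  ``D(i, i)`` is the
self-exclusion diameter and encodes the degree of contact inhibition of type
``i``: the larger it is, the sparser the densest single-type packing.  Border
vertices (row or col in ``{0, L-1}``) are kept permanently empty to suppress
boundary effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: Cell-type codes used throughout the package.
EMPTY, TUMOR, NORMAL = 0, 1, 2

#: A lattice vertex as a 0-based (row, col) pair.
Site = tuple[int, int]


@dataclass(frozen=True)
class ExclusionRule:
    """Minimal allowed graph distances ``D(i, j)`` between cell types.

    The defaults are the co-culture parameterisation: tumor cells tolerate
    adjacent vertices (``d11 = 1``), normal cells pack at best into a
    checkerboard (``d22 = 2``), and mixed pairs keep distance 3 (``d12 = 3``).
    The table is symmetric by construction (``D(1,2) = D(2,1)``).
    """

    d11: int = 1
    d12: int = 3
    d22: int = 2

    def __post_init__(self) -> None:
        for name in ("d11", "d12", "d22"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"exclusion distance {name} must be a positive integer, got {v!r}")

    def d(self, i: int, j: int) -> int:
        """Exclusion distance between cell types ``i`` and ``j`` (symmetric)."""
        if {i, j} == {1}:
            return self.d11
        if {i, j} == {2}:
            return self.d22
        if {i, j} == {1, 2}:
            return self.d12
        raise ValueError(f"cell types must be in {{1, 2}}, got ({i}, {j})")

    def as_matrix(self) -> np.ndarray:
        """3x3 integer matrix M with M[i, j] = D(i, j) for i, j in {1, 2}.

        Row/column 0 is unused padding so type codes index directly.
        """
        m = np.zeros((3, 3), dtype=np.int64)
        m[1, 1] = self.d11
        m[1, 2] = m[2, 1] = self.d12
        m[2, 2] = self.d22
        return m

    @property
    def max_d(self) -> int:
        return max(self.d11, self.d12, self.d22)


@dataclass
class LatticeConfig:
    """An L x L occupancy state: 0 empty, 1 tumor cell, 2 normal cell.

    The array is the authoritative state; helper methods give convenient
    views.  Invariants (checkable with :func:`is_admissible`): at most one
    cell per vertex, empty border, pairwise exclusion distances respected.
    """

    L: int
    state: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.state is None:
            self.state = np.zeros((self.L, self.L), dtype=np.int8)
        else:
            self.state = np.asarray(self.state, dtype=np.int8)
            if self.state.shape != (self.L, self.L):
                raise ValueError(f"state shape {self.state.shape} != ({self.L}, {self.L})")
            if not np.isin(self.state, (0, 1, 2)).all():
                raise ValueError("state entries must be in {0, 1, 2}")

    @classmethod
    def empty(cls, L: int) -> "LatticeConfig":
        return cls(L=L)

    def copy(self) -> "LatticeConfig":
        return LatticeConfig(L=self.L, state=self.state.copy())

    def occupied_sites(self, cell_type: Optional[int] = None) -> list[Site]:
        """Sites holding a cell (of ``cell_type`` if given), row-major order."""
        if cell_type is None:
            rows, cols = np.nonzero(self.state)
        else:
            rows, cols = np.nonzero(self.state == cell_type)
        return [(int(r), int(c)) for r, c in zip(rows, cols)]

    def counts(self) -> tuple[int, int]:
        """(tumor count, normal count)."""
        return int((self.state == TUMOR).sum()), int((self.state == NORMAL).sum())

    def densities(self, interior_only: bool = False) -> tuple[float, float]:
        """Occupied fraction per type; denominator L^2 (or (L-2)^2 interior)."""
        n1, n2 = self.counts()
        denom = (self.L - 2) ** 2 if interior_only else self.L**2
        return n1 / denom, n2 / denom

    def is_border(self, x: Site) -> bool:
        r, c = x
        return r in (0, self.L - 1) or c in (0, self.L - 1)


def graph_distance(a: Site, b: Site) -> int:
    """Graph metric on the square grid: minimal number of unit edges = L1 distance."""
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


def ring_sites(x: Site, d: int, L: int) -> set[Site]:
    """All grid sites at graph distance exactly ``d`` from ``x``.

    An interior site far from the edges has 4*d such sites (the L1 diamond
    shell); the set is truncated near edges.
    """
    if d < 1:
        raise ValueError("ring radius must be >= 1")
    r0, c0 = x
    out: set[Site] = set()
    for dr in range(-d, d + 1):
        rem = d - abs(dr)
        for dc in (-rem, rem) if rem else (0,):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < L and 0 <= c < L:
                out.add((r, c))
    return out


def _neighbourhood(x: Site, radius: int, L: int) -> Iterator[Site]:
    """Sites within graph distance ``radius`` of x (excluding x), in-grid."""
    r0, c0 = x
    for dr in range(-radius, radius + 1):
        rem = radius - abs(dr)
        for dc in range(-rem, rem + 1):
            if dr == 0 and dc == 0:
                continue
            r, c = r0 + dr, c0 + dc
            if 0 <= r < L and 0 <= c < L:
                yield (r, c)


def is_admissible(config: LatticeConfig, rule: ExclusionRule) -> bool:
    """True iff all borders are empty and all cell pairs respect D(i, j).

    Scans the radius-(max D - 1) neighbourhood of every cell, so the cost is
    O(#cells * max_d^2) rather than quadratic in the cell count.
    """
    s = config.state
    L = config.L
    if s[0, :].any() or s[-1, :].any() or s[:, 0].any() or s[:, -1].any():
        return False
    radius = rule.max_d - 1
    if radius == 0:
        return True
    dmat = rule.as_matrix()
    for x in config.occupied_sites():
        i = int(s[x])
        for y in _neighbourhood(x, radius, L):
            j = int(s[y])
            if j and graph_distance(x, y) < dmat[i, j]:
                return False
    return True


def can_place(
    config: LatticeConfig,
    x: Site,
    cell_type: int,
    rule: ExclusionRule,
    ignore: Optional[Site] = None,
) -> bool:
    """Can a cell of ``cell_type`` occupy the empty vertex ``x`` admissibly?

    This is the indicator I(i) of the dynamics: it is False on border
    vertices and whenever some existing cell of type ``j`` lies closer than
    ``D(cell_type, j)``.  ``ignore`` names one occupied site to disregard --
    the would-be migrating cell, which vacates its vertex in the same move.
    """
    if config.state[x] != EMPTY and x != ignore:
        raise ValueError(f"site {x} is occupied and not the ignored site")
    if config.is_border(x):
        return False
    dmat = rule.as_matrix()
    radius = max(dmat[cell_type, 1], dmat[cell_type, 2]) - 1
    for y in _neighbourhood(x, radius, config.L):
        if y == ignore:
            continue
        j = int(config.state[y])
        if j and graph_distance(x, y) < dmat[cell_type, j]:
            return False
    return True


def count_donors(config: LatticeConfig, x: Site, cell_type: int, rule: ExclusionRule) -> int:
    """n_i(x): type-i cells on the ring at distance D(i, i) from the empty x.

    These are the nearest admissibly-placed potential parents/migrants for
    an occupation of ``x`` by type ``i``.
    """
    if config.state[x] != EMPTY:
        raise ValueError(f"site {x} is not empty")
    d = rule.d(cell_type, cell_type)
    return sum(1 for y in ring_sites(x, d, config.L) if config.state[y] == cell_type)


def donor_sites(config: LatticeConfig, x: Site, cell_type: int, rule: ExclusionRule) -> list[Site]:
    """The sites counted by :func:`count_donors`, in sorted order."""
    d = rule.d(cell_type, cell_type)
    return sorted(y for y in ring_sites(x, d, config.L) if config.state[y] == cell_type)


def count_empty_receivers(
    config: LatticeConfig, x: Site, rule: ExclusionRule
) -> tuple[int, list[Site]]:
    """n_e(x) for the cell at x: admissible empty destinations on its ring.

    The ring radius is the self-exclusion diameter D(i, i) of the occupant's
    type; a destination counts when placing the cell there (with its source
    vacated) keeps the configuration admissible.
    """
    i = int(config.state[x])
    if i not in (TUMOR, NORMAL):
        raise ValueError(f"site {x} holds no cell")
    d = rule.d(i, i)
    receivers = sorted(
        y
        for y in ring_sites(x, d, config.L)
        if config.state[y] == EMPTY and can_place(config, y, i, rule, ignore=x)
    )
    return len(receivers), receivers
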