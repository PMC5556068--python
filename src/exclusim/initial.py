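"""Admissible initial configurations and synthetic data fixtures.

Random initial states are built by uniform random sequential insertion with
admissibility rejection, placing the larger-exclusion species first (order
configurable).  The module also generates the synthetic inputs the analysis
layer is exercised on: labeled point patterns emulating a post-confluence
co-culture field (dense tumor clusters in a spaced normal-cell background)
and noisy logistic growth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import EMPTY, ExclusionRule, LatticeConfig, can_place

__all__ = [
    "InitSpec",
    "SyntheticPatternSpec",
    "PointPattern",
    "random_admissible_init",
    "dense_packing",
    "single_type_capacity",
    "synthetic_point_pattern",
    "synthetic_growth_curve",
    "logistic",
]


class InfeasibleInitError(RuntimeError):
    """Raised when a target cell count cannot be placed admissibly."""


@dataclass
class InitSpec:
    """Target initial densities (fractions of all L^2 vertices) and placement policy."""

    density1: float = 0.01
    density2: float = 0.09
    seed: int = 0
    order: tuple[int, ...] = (2, 1)  # larger-exclusion species first aids feasibility
    max_attempts_per_cell: int = 500

    def __post_init__(self) -> None:
        if self.density1 < 0 or self.density2 < 0:
            raise ValueError("densities must be nonnegative")
        if self.density1 + self.density2 > 1:
            raise ValueError("total density exceeds 1")
        if sorted(self.order) != [1, 2]:
            raise ValueError("order must be a permutation of (1, 2)")

    def density(self, i: int) -> float:
        return self.density1 if i == 1 else self.density2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def single_type_capacity(cell_type_d: int, L: int) -> int:
    """Maximal single-type cell count on the interior under self-exclusion d.

    Known optimal L1-metric packings: density 2/d^2 of the plane for even d
    and 2/(d^2 + 1) for odd d (d = 1: full occupancy; d = 2: checkerboard,
    one half).  Applied to the (L-2)^2 interior as a feasibility ceiling.
    """
    interior = (L - 2) ** 2
    d = cell_type_d
    if d == 1:
        return interior
    frac = 2 / d**2 if d % 2 == 0 else 2 / (d**2 + 1)
    return int(math.ceil(interior * frac))


def random_admissible_init(L: int, rule: ExclusionRule, spec: InitSpec) -> LatticeConfig:
    """Uniform random sequential insertion of round(density_i * L^2) cells per type.

    Each cell is proposed at a uniformly random interior vertex and accepted
    iff the placement is admissible; after ``max_attempts_per_cell``
    consecutive rejections the initialisation fails (jamming).  Targets above
    90% of the analytic single-type packing capacity are refused up front.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    config = LatticeConfig.empty(L)
    for i in spec.order:
        target = _round_half_up(spec.density(i) * L**2)
        cap = single_type_capacity(rule.d(i, i), L)
        if target > 0.9 * cap:
            raise InfeasibleInitError(
                f"type {i}: target count {target} exceeds 90% of the single-type "
                f"packing capacity {cap} for D({i},{i})={rule.d(i, i)} on L={L}"
            )
        placed = 0
        while placed < target:
            for _ in range(spec.max_attempts_per_cell):
                r = int(rng.integers(1, L - 1))
                c = int(rng.integers(1, L - 1))
                if config.state[r, c] == EMPTY and can_place(config, (r, c), i, rule):
                    config.state[r, c] = i
                    placed += 1
                    break
            else:
                raise InfeasibleInitError(
                    f"type {i}: jammed after {spec.max_attempts_per_cell} attempts "
                    f"with {placed}/{target} cells placed"
                )
    return config


def dense_packing(cell_type: int, L: int, rule: ExclusionRule) -> LatticeConfig:
    """Densest single-type packing of the interior for self-exclusion 1 or 2.

    D(i, i) = 1: every interior vertex occupied.  D(i, i) = 2: the
    even-parity checkerboard of the interior (density 1/2 of the interior).
    Larger self-exclusion diameters have no construction defined here.
    """
    d = rule.d(cell_type, cell_type)
    config = LatticeConfig.empty(L)
    interior = slice(1, L - 1)
    if d == 1:
        config.state[interior, interior] = cell_type
    elif d == 2:
        rows, cols = np.meshgrid(np.arange(1, L - 1), np.arange(1, L - 1), indexing="ij")
        mask = (rows + cols) % 2 == 0
        config.state[rows[mask], cols[mask]] = cell_type
    else:
        raise ValueError(f"dense packing not defined for D(i,i)={d} > 2")
    return config


# ---------------------------------------------------------------------------
# Synthetic point patterns (centroid fields emulating co-culture micrographs)
# ---------------------------------------------------------------------------


@dataclass
class PointPattern:
    """Typed cell-centroid coordinates (micrometres) on a square field."""

    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray
    field_um: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=int)
        if not (len(self.x) == len(self.y) == len(self.cell_type)):
            raise ValueError("coordinate/type arrays must have equal length")
        if len(self.x) and (
            self.x.min() < 0
            or self.y.min() < 0
            or self.x.max() > self.field_um
            or self.y.max() > self.field_um
        ):
            raise ValueError("coordinates outside the field extent")
        if not np.isin(self.cell_type, (1, 2)).all():
            raise ValueError("cell types must be 1 or 2")

    def points_of(self, cell_type: int) -> np.ndarray:
        m = self.cell_type == cell_type
        return np.column_stack([self.x[m], self.y[m]])

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class SyntheticPatternSpec:
    """Parameters of the synthetic post-confluence co-culture field.

    Tumor cells (type 1) form dense discs with short hard-core spacing;
    normal cells (type 2) fill the remaining field as a hard-core background
    with a larger minimal spacing.  Defaults mimic a 400 um field of view
    with one tumor cluster: nucleus-scale spacings of ~8 um within the
    cluster versus ~18 um in the contact-inhibited background.
    """

    field_um: float = 400.0
    n_clusters: int = 1
    cluster_radius_um: float = 35.0
    cluster_spacing_um: float = 8.0
    cluster_intensity: float = 0.012  # proposal intensity, points per um^2
    background_spacing_um: float = 18.0
    background_intensity: float = 0.004
    clearance_um: float = 12.0  # minimal tumor-normal separation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be nonnegative")
        if self.cluster_spacing_um < 0 or self.background_spacing_um < 0:
            raise ValueError("spacings must be nonnegative")


def _hard_core_fill(
    rng: np.random.Generator,
    n_proposals: int,
    sampler,
    spacing: float,
    existing: np.ndarray,
    clearance: float,
) -> np.ndarray:
    """Sequential hard-core thinning: accept proposals respecting spacings."""
    accepted: list[np.ndarray] = []
    for _ in range(n_proposals):
        p = sampler()
        if accepted:
            d2 = ((np.array(accepted) - p) ** 2).sum(axis=1)
            if d2.min() < spacing**2:
                continue
        if len(existing) and clearance > 0:
            d2 = ((existing - p) ** 2).sum(axis=1)
            if d2.min() < clearance**2:
                continue
        accepted.append(p)
    return np.array(accepted) if accepted else np.empty((0, 2))


def synthetic_point_pattern(spec: SyntheticPatternSpec) -> PointPattern:
    """Generate a labeled centroid field with the post-confluence signature.

    Type-1 points are packed densely inside the cluster discs, type-2 points
    form a spaced background outside them, so same-type pairwise distance
    histograms peak at a shorter distance for type 1 than for type 2 -- the
    signature that distinguishes a tolerant (weakly contact-inhibited) cell
    line from a strongly inhibited one.  Reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    F = spec.field_um
    R = spec.cluster_radius_um
    margin = min(R + spec.clearance_um, F / 2)
    centers = rng.uniform(margin, F - margin, size=(spec.n_clusters, 2))

    tumor_pts = np.empty((0, 2))
    for center in centers:
        area = math.pi * R**2
        n_prop = rng.poisson(spec.cluster_intensity * area * 4)

        def in_disc() -> np.ndarray:
            while True:
                p = center + rng.uniform(-R, R, size=2)
                if ((p - center) ** 2).sum() <= R**2 and 0 <= p[0] <= F and 0 <= p[1] <= F:
                    return p

        pts = _hard_core_fill(
            rng, n_prop, in_disc, spec.cluster_spacing_um, tumor_pts, spec.cluster_spacing_um
        )
        tumor_pts = np.vstack([tumor_pts, pts]) if len(pts) else tumor_pts

    n_prop = rng.poisson(spec.background_intensity * F**2 * 4)

    def in_field() -> np.ndarray:
        return rng.uniform(0, F, size=2)

    normal_pts = _hard_core_fill(
        rng, n_prop, in_field, spec.background_spacing_um, tumor_pts, spec.clearance_um
    )

    x = np.concatenate([tumor_pts[:, 0], normal_pts[:, 0]])
    y = np.concatenate([tumor_pts[:, 1], normal_pts[:, 1]])
    t = np.concatenate([np.ones(len(tumor_pts), int), np.full(len(normal_pts), 2, int)])
    return PointPattern(x=x, y=y, cell_type=t, field_um=F)


# ---------------------------------------------------------------------------
# Synthetic growth curves
# ---------------------------------------------------------------------------


def logistic(t, K: float, rate: float, tau: float):
    """Three-parameter logistic N(t) = K / (1 + exp(-rate * (t - tau)))."""
    return K / (1.0 + np.exp(-rate * (np.asarray(t, dtype=float) - tau)))


def synthetic_growth_curve(
    K: float,
    rate: float,
    tau: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Logistic growth samples with additive Gaussian noise.

    Returns a pandas DataFrame with columns ``time`` and ``value``; at
    ``t = tau`` the noiseless curve equals K/2 by construction.
    """
    import pandas as pd

    if K <= 0 or rate <= 0:
        raise ValueError("K and rate must be positive")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    values = logistic(times, K, rate, tau)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(times))
    return pd.DataFrame({"time": times, "value": values})
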