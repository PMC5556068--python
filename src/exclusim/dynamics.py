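"""Discrete-time Markov chain on admissible two-type lattice configurations.

One transition: a vertex x is selected uniformly over all L^2 vertices.

* If x holds a cell of type i, it stays (quiescence) with probability
  alpha_i / Q, dies with rho_i / Q, or migrates to one of its n_e admissible
  empty ring destinations, each with delta_i / Q, where
  Q = alpha_i + n_e * delta_i + rho_i.
* If x is empty, it stays empty with probability (rho_1 + rho_2) / R; a type-i
  cell appears through division with probability n_i * alpha_i * I(i) / R or
  through migration of one of the n_i ring donors with delta_i * I(i) / R
  each (the chosen donor's vertex is vacated), where
  R = rho_1 + rho_2 + sum_i n_i * (alpha_i + delta_i) * I(i)
  and I(i) indicates that x can admissibly receive type i.
  Border vertices have I == 0 and always stay empty.

This module houses the exact per-vertex outcome distributions (the analytic
reference used as an oracle in tests) and the run/sweep drivers, which by
default delegate the inner loop to the numba kernels in
:mod:`exclusim.kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import kernels
from .lattice import (
    EMPTY,
    ExclusionRule,
    LatticeConfig,
    Site,
    can_place,
    count_empty_receivers,
    donor_sites,
)

__all__ = [
    "RateSet",
    "ModelParams",
    "UpdateDistribution",
    "Trajectory",
    "occupied_update_distribution",
    "empty_update_distribution",
    "step",
    "run",
    "sweep_alpha_ratio",
    "COCULTURE_RATES",
]


@dataclass(frozen=True)
class RateSet:
    """Per-type division (alpha), migration (delta) and death (rho) weights.

    The rates are dimensionless weights entering the per-vertex outcome
    distributions; they are not rates per unit physical time.  Defaults are
    the co-culture simulation values alpha = 0.1, rho = 0.01, delta = 0.001
    for both types.
    """

    alpha1: float = 0.1
    alpha2: float = 0.1
    delta1: float = 0.001
    delta2: float = 0.001
    rho1: float = 0.01
    rho2: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "delta1", "delta2", "rho1", "rho2"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")
        for i in (1, 2):
            if self.alpha(i) + self.rho(i) <= 0:
                raise ValueError(
                    f"type {i}: alpha + rho must be positive or the occupied-vertex "
                    "normalizer Q can vanish"
                )

    def alpha(self, i: int) -> float:
        return self.alpha1 if i == 1 else self.alpha2

    def delta(self, i: int) -> float:
        return self.delta1 if i == 1 else self.delta2

    def rho(self, i: int) -> float:
        return self.rho1 if i == 1 else self.rho2

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(alpha, delta, rho) as length-3 arrays indexed by type code."""
        a = np.array([0.0, self.alpha1, self.alpha2])
        d = np.array([0.0, self.delta1, self.delta2])
        r = np.array([0.0, self.rho1, self.rho2])
        return a, d, r


#: The co-culture study rates (equal for both types).
COCULTURE_RATES = RateSet()


@dataclass
class ModelParams:
    """Full parameterisation of one simulation run."""

    L: int = 200
    rule: ExclusionRule = field(default_factory=ExclusionRule)
    rates: RateSet = field(default_factory=RateSet)
    seed: int = 0
    n_steps: int = 100_000
    record_every: int = 1_000
    init_density: tuple[float, float] = (0.01, 0.09)
    snapshot_steps: tuple[int, ...] = ()
    interior_density: bool = False  # densities over (L-2)^2 instead of L^2

    def __post_init__(self) -> None:
        if self.L < 2 * self.rule.max_d + 2:
            raise ValueError(f"L={self.L} too small for max exclusion distance {self.rule.max_d}")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class UpdateDistribution:
    """Exact outcome distribution at one selected vertex.

    ``outcomes`` maps event tuples to probabilities.  Event tuples:
    ``("quiescence",)``, ``("death",)``, ``("migrate_out", site)``,
    ``("stay_empty",)``, ``("birth", i)``, ``("migrate_in", i, site)``.
    ``normalizer`` is the value Q (occupied vertex) or R (empty vertex).
    """

    outcomes: dict[tuple, float]
    normalizer: float

    def total(self) -> float:
        return sum(self.outcomes.values())

    def probability(self, kind: str) -> float:
        """Total probability of all outcomes of the given kind."""
        return sum(p for ev, p in self.outcomes.items() if ev[0] == kind)

    def sample(self, rng: np.random.Generator) -> tuple:
        events = list(self.outcomes)
        probs = np.fromiter(self.outcomes.values(), dtype=float)
        idx = rng.choice(len(events), p=probs / probs.sum())
        return events[idx]


def occupied_update_distribution(
    config: LatticeConfig, x: Site, params: ModelParams
) -> UpdateDistribution:
    """Outcome distribution at an occupied vertex: quiescence, death, migration."""
    i = int(config.state[x])
    if i == EMPTY:
        raise ValueError(f"site {x} is empty")
    a, d, ro = params.rates.alpha(i), params.rates.delta(i), params.rates.rho(i)
    n_e, receivers = count_empty_receivers(config, x, params.rule)
    q = a + n_e * d + ro
    if q <= 0:
        raise ValueError(f"normalizer Q vanished at {x} (all rates zero for type {i})")
    outcomes: dict[tuple, float] = {("quiescence",): a / q, ("death",): ro / q}
    for y in receivers:
        outcomes[("migrate_out", y)] = d / q
    return UpdateDistribution(outcomes=outcomes, normalizer=q)


def empty_update_distribution(
    config: LatticeConfig, x: Site, params: ModelParams
) -> UpdateDistribution:
    """Outcome distribution at an empty vertex: stay empty, birth, immigration.

    On border vertices no type may be placed, so the vertex stays empty with
    probability 1.
    """
    if config.state[x] != EMPTY:
        raise ValueError(f"site {x} is occupied")
    rates = params.rates
    rho_sum = rates.rho1 + rates.rho2
    weights: dict[tuple, float] = {("stay_empty",): rho_sum}
    for i in (1, 2):
        if not can_place(config, x, i, params.rule):
            continue
        donors = donor_sites(config, x, i, params.rule)
        if not donors:
            continue
        n_i = len(donors)
        weights[("birth", i)] = n_i * rates.alpha(i)
        for y in donors:
            weights[("migrate_in", i, y)] = rates.delta(i)
    big_r = sum(weights.values())
    if big_r <= 0:
        # rho_1 + rho_2 == 0 and no occupation possible: stay empty surely.
        return UpdateDistribution(outcomes={("stay_empty",): 1.0}, normalizer=0.0)
    return UpdateDistribution(
        outcomes={ev: w / big_r for ev, w in weights.items()}, normalizer=big_r
    )


def apply_event(config: LatticeConfig, x: Site, event: tuple) -> None:
    """Apply a sampled event at vertex x in place."""
    kind = event[0]
    if kind in ("quiescence", "stay_empty"):
        return
    if kind == "death":
        config.state[x] = EMPTY
    elif kind == "migrate_out":
        t = config.state[x]
        config.state[x] = EMPTY
        config.state[event[1]] = t
    elif kind == "birth":
        config.state[x] = event[1]
    elif kind == "migrate_in":
        config.state[event[2]] = EMPTY
        config.state[x] = event[1]
    else:
        raise ValueError(f"unknown event {event!r}")


def step(
    config: LatticeConfig, params: ModelParams, rng: np.random.Generator
) -> tuple[LatticeConfig, tuple[Site, tuple]]:
    """One reference-implementation transition (in place); returns (config, (site, event)).

    Selects a vertex uniformly over all L^2 (border included; border
    selections stay empty), samples the exact outcome distribution, applies
    the event.  This path is the readable oracle; long runs use the compiled
    kernel in :func:`run`.
    """
    r = int(rng.integers(config.L))
    c = int(rng.integers(config.L))
    x = (r, c)
    if config.state[x] != EMPTY:
        dist = occupied_update_distribution(config, x, params)
    else:
        dist = empty_update_distribution(config, x, params)
    event = dist.sample(rng)
    apply_event(config, x, event)
    return config, (x, event)


@dataclass
class Trajectory:
    """Recorded step indices with per-type densities and their ratio."""

    steps: np.ndarray
    density1: np.ndarray
    density2: np.ndarray
    interior: bool = False

    @property
    def ratio(self) -> np.ndarray:
        """density2 / density1 with NaN sentinel where density1 == 0."""
        out = np.full(len(self.density1), np.nan)
        nz = self.density1 > 0
        out[nz] = self.density2[nz] / self.density1[nz]
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": self.steps,
                "density1": self.density1,
                "density2": self.density2,
                "ratio": self.ratio,
            }
        )


def _record_steps(n_steps: int, record_every: int) -> np.ndarray:
    steps = list(range(0, n_steps + 1, record_every))
    if steps[-1] != n_steps:
        steps.append(n_steps)
    return np.asarray(steps, dtype=np.int64)


def run(
    params: ModelParams,
    initial: Optional[LatticeConfig] = None,
    engine: str = "fast",
) -> tuple[Trajectory, dict[int, LatticeConfig]]:
    """Run the chain for ``params.n_steps`` steps from a seeded initial state.

    ``initial`` defaults to a random admissible configuration at the target
    densities (see :func:`exclusim.initial.random_admissible_init`).
    Densities are recorded at step 0, every ``record_every`` steps and at the
    final step; snapshots are taken at ``params.snapshot_steps``.

    ``engine='fast'`` uses the numba kernel; ``engine='reference'`` uses the
    pure-Python transition (identical law, different random stream) and is
    practical only for small step counts.
    """
    from .initial import InitSpec, random_admissible_init

    if initial is None:
        spec = InitSpec(
            density1=params.init_density[0], density2=params.init_density[1], seed=params.seed
        )
        config = random_admissible_init(params.L, params.rule, spec)
    else:
        config = initial.copy()

    record_steps = _record_steps(params.n_steps, params.record_every)
    snap_steps = sorted(set(int(s) for s in params.snapshot_steps))
    for s in snap_steps:
        if not (0 <= s <= params.n_steps):
            raise ValueError(f"snapshot step {s} outside [0, {params.n_steps}]")
    snapshots: dict[int, LatticeConfig] = {}
    denom = (params.L - 2) ** 2 if params.interior_density else params.L**2
    counts = np.zeros((len(record_steps), 2), dtype=np.int64)

    if engine == "fast":
        grid = config.state
        a, d, ro = params.rates.arrays()
        dmat = params.rule.as_matrix()
        kernels.seed_kernel_rng(params.seed % 2**31)
        boundaries = [0] + snap_steps + [params.n_steps]
        if 0 in snap_steps:
            snapshots[0] = config.copy()
        done = 0
        for b in boundaries[1:]:
            chunk = b - done
            # a zero-length chunk still records any due step-index entries
            kernels.run_chain(grid, dmat, a, d, ro, chunk, done, record_steps, counts)
            done = b
            if b in snap_steps:
                snapshots[b] = LatticeConfig(L=params.L, state=grid.copy())
    elif engine == "reference":
        rng = np.random.default_rng(params.seed)
        rec_i = 0
        for s in range(params.n_steps + 1):
            if s in snap_steps:
                snapshots[s] = config.copy()
            while rec_i < len(record_steps) and record_steps[rec_i] == s:
                n1, n2 = config.counts()
                counts[rec_i] = (n1, n2)
                rec_i += 1
            if s < params.n_steps:
                step(config, params, rng)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    traj = Trajectory(
        steps=record_steps,
        density1=counts[:, 0] / denom,
        density2=counts[:, 1] / denom,
        interior=params.interior_density,
    )
    return traj, snapshots


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def sweep_alpha_ratio(
    base_params: ModelParams,
    ratios: Sequence[float],
    n_reps: int,
    n_steps: Optional[int] = None,
):
    """Division-rate robustness sweep: vary alpha_2 / alpha_1, replicate, summarise.

    For each ratio the chain is run ``n_reps`` times with independent derived
    seeds (alpha_1 fixed at ``base_params.rates.alpha1``); the repetition mean
    and standard deviation of the final per-type densities are reported.

    Returns a pandas DataFrame with columns
    ratio, mean_density1, sd_density1, mean_density2, sd_density2, n_reps.
    With ``n_reps == 1`` the standard deviations are reported as NaN.
    """
    import pandas as pd

    steps = base_params.n_steps if n_steps is None else int(n_steps)
    seeds = derive_seeds(base_params.seed, len(ratios) * n_reps)
    rows = []
    k = 0
    for ratio in ratios:
        rates = replace(base_params.rates, alpha2=base_params.rates.alpha1 * ratio)
        finals = np.zeros((n_reps, 2))
        for rep in range(n_reps):
            p = replace(
                base_params,
                rates=rates,
                seed=seeds[k],
                n_steps=steps,
                record_every=max(steps, 1),
                snapshot_steps=(),
            )
            k += 1
            traj, _ = run(p)
            finals[rep] = (traj.density1[-1], traj.density2[-1])
        sd = finals.std(axis=0, ddof=1) if n_reps > 1 else np.array([np.nan, np.nan])
        rows.append(
            {
                "ratio": ratio,
                "mean_density1": finals[:, 0].mean(),
                "sd_density1": sd[0],
                "mean_density2": finals[:, 1].mean(),
                "sd_density2": sd[1],
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def equal_density_ratio(sweep_df) -> float:
    """The sweep ratio at which the repetition-mean final densities are closest.

    Operationalises "average densities approximately the same": the ratio
    minimising |mean_density2 - mean_density1| (smallest ratio on ties).
    """
    gap = (sweep_df["mean_density2"] - sweep_df["mean_density1"]).abs().to_numpy()
    return float(sweep_df["ratio"].iloc[int(np.argmin(gap))])


def first_prevalence_ratio(sweep_df) -> Optional[float]:
    """Smallest sweep ratio whose mean type-2 density strictly exceeds type 1's.

    None when the sparing (type-2) species never prevails within the sweep.
    """
    above = sweep_df[sweep_df["mean_density2"] > sweep_df["mean_density1"]]
    return float(above["ratio"].min()) if len(above) else None
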