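"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from exclusim.lattice import ExclusionRule, LatticeConfig, graph_distance


@pytest.fixture
def rule() -> ExclusionRule:
    """The co-culture exclusion table D = (1, 3, 2)."""
    return ExclusionRule(d11=1, d12=3, d22=2)


def brute_force_admissible(config: LatticeConfig, rule: ExclusionRule) -> bool:
    """All-pairs admissibility oracle (quadratic; test use only)."""
    s = config.state
    if s[0, :].any() or s[-1, :].any() or s[:, 0].any() or s[:, -1].any():
        return False
    cells = [(r, c, int(s[r, c])) for r, c in zip(*np.nonzero(s))]
    for (r1, c1, t1), (r2, c2, t2) in itertools.combinations(cells, 2):
        if graph_distance((r1, c1), (r2, c2)) < rule.d(t1, t2):
            return False
    return True


def random_state_grid(rng: np.random.Generator, L: int, p_occ: float = 0.2) -> LatticeConfig:
    """Random (usually inadmissible) grid with empty border."""
    state = rng.choice([0, 1, 2], size=(L, L), p=[1 - p_occ, p_occ / 2, p_occ / 2])
    state[0, :] = state[-1, :] = state[:, 0] = state[:, -1] = 0
    return LatticeConfig(L=L, state=state)


def random_admissible_small(
    rng: np.random.Generator, L: int, rule: ExclusionRule, n_attempts: int = 60
) -> LatticeConfig:
    """Small admissible configuration built by rejection insertion."""
    from exclusim.lattice import can_place

    config = LatticeConfig.empty(L)
    for _ in range(n_attempts):
        r = int(rng.integers(1, L - 1))
        c = int(rng.integers(1, L - 1))
        t = int(rng.integers(1, 3))
        if config.state[r, c] == 0 and can_place(config, (r, c), t, rule):
            config.state[r, c] = t
    return config
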