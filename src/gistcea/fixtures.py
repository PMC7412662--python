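"""Synthetic inputs: background-mortality table, toy chains, default config.

The national age-specific death rates the analysis relies on are not
redistributable here, so the default life table is a synthetic Gompertz
(exponential-in-age) hazard calibrated to plausible high-income-country
all-population values: q(60) ~ 0.005 rising to q(80) ~ 0.031.  Over the
modelled ages this background risk stays an order of magnitude below the
end-stage disease mortality, so the max-of-mortalities rule behaves as in
the published analysis.

Toy chains give the cohort engine small fixtures with closed-form totals
for oracle testing.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import RewardSchedule, State, StateSpace
from .parameters import LifeTable, ParameterSet, to_config_text

__all__ = [
    "LifeTableSpec",
    "default_life_table",
    "emit_default_config",
    "make_life_table",
    "make_toy_chain",
]


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz background mortality: ``q(age) = a * exp(b * age)``.

    Defaults give q(60) ~ 0.005 and q(80) ~ 0.031, an all-population
    schedule plausible for a high-income country.
    """

    a: float = 2.3e-5
    b: float = 0.09        # per year of age
    age_min: int = 30
    age_max: int = 100


def make_life_table(spec: LifeTableSpec = LifeTableSpec()) -> LifeTable:
    if spec.a <= 0 or spec.b <= 0:
        raise ValueError("Gompertz coefficients must be positive")
    if spec.age_min >= spec.age_max:
        raise ValueError("age span is empty")
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qx = spec.a * np.exp(spec.b * ages)
    if np.any(qx >= 1.0):
        raise ValueError("hazard reaches 1 within the age span; shrink a or b")
    return LifeTable(ages, qx)


def default_life_table() -> LifeTable:
    """The package's default synthetic background-mortality table."""
    return make_life_table(LifeTableSpec())


def make_toy_chain(matrix, utilities, costs, *, labels: Sequence[str] | None = None,
                   entry_costs=None, entry_mortality=None,
                   ) -> tuple[StateSpace, Callable[[int], np.ndarray], RewardSchedule]:
    """Build a small constant-matrix chain for the cohort engine.

    ``matrix`` must be row-stochastic with exactly one absorbing (identity)
    row, which becomes the Dead state.  Returns the triple expected by
    :class:`gistcea.model.MarkovCohortModel`.
    """
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError("matrix must be square")
    if np.any(M < 0) or np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("matrix rows must be stochastic")
    util = np.asarray(utilities, float)
    cost = np.asarray(costs, float)
    absorbing = [i for i in range(n)
                 if M[i, i] == 1.0 and np.all(np.delete(M[i], i) == 0.0)]
    if len(absorbing) > 1:
        # a stationary alive state is also an identity row; Dead is the
        # absorbing row carrying no rewards
        absorbing = [i for i in absorbing if util[i] == 0.0 and cost[i] == 0.0]
    if len(absorbing) != 1:
        raise ValueError("toy chain needs exactly one absorbing (Dead) row")
    idead = absorbing[0]
    if labels is None:
        labels = [f"S{i}" if i != idead else "Dead" for i in range(n)]
    states = tuple(
        State(uid=f"s{i}", label=labels[i], strategy="shared",
              absorbing=(i == idead))
        for i in range(n)
    )
    space = StateSpace("toy", states)
    rewards = RewardSchedule(
        util,
        cost,
        np.zeros(n) if entry_costs is None else np.asarray(entry_costs, float),
        np.zeros(n) if entry_mortality is None else np.asarray(entry_mortality, float),
    )
    if rewards.utility[idead] != 0 or rewards.annual_cost[idead] != 0:
        raise ValueError("absorbing state must carry zero rewards")
    return space, (lambda cycle: M), rewards


def emit_default_config() -> str:
    """Configuration text reproducing the base case (round-trip stable)."""
    return to_config_text(ParameterSet())


def packaged_default_config() -> str:
    """Contents of the base-case configuration file shipped with the package."""
    return (importlib.resources.files("gistcea") / "data" / "base_case.yaml").read_text()
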