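"""Deterministic sensitivity analysis: sweeps, thresholds, two-way surface.

One-way sweeps vary a single parameter over a grid with everything else at
base case.  Threshold finding runs bisection on any boolean predicate of
the strategy comparison (for example "CIUP is cheaper than UAPR" or "UAPR
has the higher NMB at WTP 50,000") to locate the parameter value where the
verdict flips.  The two-way surface evaluates the net-monetary-benefit
winner over a grid of two parameters simultaneously — in the published
analysis, the utility after abdominoperineal resection crossed with the
annual post-resection recurrence probability.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cea import CEAComparison, compare_strategies
from .model import StrategyOutcome
from .parameters import LifeTable, ParameterSet

__all__ = [
    "PREDICATES",
    "NmbSurface",
    "SweepResult",
    "ThresholdResult",
    "default_grid",
    "find_threshold",
    "one_way_dsa",
    "two_way_nmb_surface",
]

Predicate = Callable[[CEAComparison], bool]

#: Named predicates usable with :func:`find_threshold` and the CLI.
PREDICATES: dict[str, Predicate] = {
    "uapr_cheaper": lambda c: c.outcome("UAPR").cost < c.outcome("CIUP").cost,
    "ciup_cheaper": lambda c: c.outcome("CIUP").cost < c.outcome("UAPR").cost,
    "uapr_more_effective": lambda c: c.outcome("UAPR").qalys > c.outcome("CIUP").qalys,
    "ciup_more_effective": lambda c: c.outcome("CIUP").qalys > c.outcome("UAPR").qalys,
    "uapr_cost_effective": lambda c: c.cost_effective == "UAPR",
    "ciup_cost_effective": lambda c: c.cost_effective == "CIUP",
    "uapr_dominant": lambda c: (c.dominance == "reference dominant"
                                and c.reference.strategy == "UAPR"),
}

_UNIT_INTERVAL_PREFIXES = ("p_", "u_")


def _resolve_predicate(predicate: str | Predicate) -> tuple[str, Predicate]:
    if callable(predicate):
        return getattr(predicate, "__name__", "custom"), predicate
    try:
        return predicate, PREDICATES[predicate]
    except KeyError:
        raise KeyError(
            f"unknown predicate {predicate!r}; known: {sorted(PREDICATES)}"
        ) from None


def _check_param(params: ParameterSet, name: str) -> None:
    if name == "ranges" or not any(f.name == name for f in fields(params)):
        raise KeyError(f"unknown parameter {name!r}")


def default_grid(params: ParameterSet, name: str, n: int = 101) -> np.ndarray:
    """Evenly spaced grid over the parameter's sensitivity range."""
    lo, hi, _fam = params.ranges[name]
    return np.linspace(lo, hi, n)


def _clamp_grid(name: str, grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("grid must be a non-empty 1-d array")
    if name.startswith(_UNIT_INTERVAL_PREFIXES):
        g = np.clip(g, 0.0, 1.0)
    g = np.unique(g)  # sorted, strictly increasing
    return g


@dataclass
class SweepResult:
    """One-way sweep: per grid value, both outcomes and their comparison."""

    param: str
    values: np.ndarray
    uapr: list[StrategyOutcome]
    ciup: list[StrategyOutcome]
    comparisons: list[CEAComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, u, c, cmp_ in zip(self.values, self.uapr, self.ciup, self.comparisons):
            for o in (u, c):
                rows.append({
                    self.param: v,
                    "strategy": o.strategy,
                    "cost": o.cost,
                    "qalys": o.qalys,
                    "nmb": cmp_.nmb[o.strategy],
                    "icer": cmp_.icer,
                    "dominance": cmp_.dominance,
                    "cost_effective": cmp_.cost_effective,
                })
        return pd.DataFrame(rows)


def one_way_dsa(param_name: str, grid, params: ParameterSet,
                life_table: LifeTable, wtp: float | None = None) -> SweepResult:
    """Evaluate both strategies at each grid value of one parameter.

    Probability and utility grids are clamped to [0, 1]; scenario grids may
    extend beyond the tabulated sensitivity range.
    """
    _check_param(params, param_name)
    g = _clamp_grid(param_name, grid)
    uapr, ciup, comparisons = [], [], []
    for v in g:
        cmp_ = compare_strategies(params.with_value(param_name, float(v)),
                                  life_table, wtp=wtp)
        uapr.append(cmp_.outcome("UAPR"))
        ciup.append(cmp_.outcome("CIUP"))
        comparisons.append(cmp_)
    return SweepResult(param_name, g, uapr, ciup, comparisons)


@dataclass(frozen=True)
class ThresholdResult:
    """Bisection result; ``value`` is None when the predicate does not
    change over the bracket."""

    param: str
    predicate: str
    value: float | None
    bracket: tuple[float, float]
    tol: float
    at_lo: bool
    at_hi: bool

    @property
    def found(self) -> bool:
        return self.value is not None


def find_threshold(param_name: str, predicate: str | Predicate,
                   bracket: tuple[float, float], params: ParameterSet,
                   life_table: LifeTable, tol: float = 1e-4,
                   wtp: float | None = None,
                   overrides: dict[str, float] | None = None) -> ThresholdResult:
    """Bisect for the parameter value where ``predicate`` flips.

    ``overrides`` fixes other parameters away from base case for scenario
    thresholds (e.g. the recurrence threshold at a pessimistic utility).
    Returns the bracket midpoint once its width is below ``tol``.
    """
    _check_param(params, param_name)
    if tol <= 0:
        raise ValueError("tol must be positive")
    pred_name, pred = _resolve_predicate(predicate)
    base = params.with_values(**overrides) if overrides else params

    def verdict(v: float) -> bool:
        cmp_ = compare_strategies(base.with_value(param_name, v), life_table,
                                  wtp=wtp)
        return bool(pred(cmp_))

    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    at_lo, at_hi = verdict(lo), verdict(hi)
    if at_lo == at_hi:
        return ThresholdResult(param_name, pred_name, None, (lo, hi), tol,
                               at_lo, at_hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if verdict(mid) == at_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(param_name, pred_name, 0.5 * (lo + hi),
                           (float(bracket[0]), float(bracket[1])), tol,
                           at_lo, at_hi)


@dataclass
class NmbSurface:
    """Two-way NMB comparison: winner and NMB difference per grid cell.

    ``nmb_diff[i, j]`` is NMB(UAPR) - NMB(CIUP) at ``grid1[i]``,
    ``grid2[j]``; ``winner`` holds the strategy with the higher NMB (ties
    go to the cheaper strategy).
    """

    param1: str
    param2: str
    grid1: np.ndarray
    grid2: np.ndarray
    wtp: float
    nmb_diff: np.ndarray
    winner: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.grid1):
            for j, v2 in enumerate(self.grid2):
                rows.append({
                    self.param1: v1,
                    self.param2: v2,
                    "nmb_diff_uapr_minus_ciup": self.nmb_diff[i, j],
                    "winner": self.winner[i, j],
                })
        return pd.DataFrame(rows)


def two_way_nmb_surface(p1: str, grid1, p2: str, grid2, wtp: float,
                        params: ParameterSet,
                        life_table: LifeTable) -> NmbSurface:
    """Winner-by-NMB over a grid of two simultaneously varied parameters."""
    _check_param(params, p1)
    _check_param(params, p2)
    g1 = _clamp_grid(p1, grid1)
    g2 = _clamp_grid(p2, grid2)
    diff = np.zeros((g1.size, g2.size))
    winner = np.empty((g1.size, g2.size), dtype=object)
    for i, v1 in enumerate(g1):
        ps1 = params.with_value(p1, float(v1))
        for j, v2 in enumerate(g2):
            cmp_ = compare_strategies(ps1.with_value(p2, float(v2)),
                                      life_table, wtp=wtp)
            diff[i, j] = cmp_.nmb["UAPR"] - cmp_.nmb["CIUP"]
            winner[i, j] = cmp_.cost_effective
    return NmbSurface(p1, p2, g1, g2, wtp, diff, winner)
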