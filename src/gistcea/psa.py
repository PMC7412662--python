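"""Probabilistic sensitivity analysis.

Joint Monte Carlo sampling of every parameter with a tabulated
distribution (beta for probabilities and utilities, gamma for costs,
uniform for the conditional local-recurrence probability), independent
across parameters.  Each draw re-runs both strategy cohorts; the paired
incremental costs and QALYs feed the cost-effectiveness acceptability
curve: at each willingness-to-pay value, the fraction of draws in which a
strategy has the higher net monetary benefit.

Draw ``i`` uses its own counter-derived random stream, so individual draws
are reproducible and independent of the total number of draws requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import compute_icer
from .model import build_state_space, run_cohort
from .parameters import (
    DistributionSpec,
    LifeTable,
    ParameterSet,
    fit_distribution,
)

__all__ = [
    "CeacCurve",
    "PsaResult",
    "ceac_curve",
    "default_wtp_grid",
    "fit_psa_distributions",
    "run_psa",
    "sample_parameter_set",
]


def default_wtp_grid() -> np.ndarray:
    """WTP grid for acceptability curves: 0 to 100,000 SGD by 2,500."""
    return np.arange(0.0, 100000.0 + 1, 2500.0)


def fit_psa_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Fitted distribution for every PSA-sampled parameter."""
    return {name: fit_distribution(params.spec(name))
            for name in params.sampled_names()}


def sample_parameter_set(params: ParameterSet,
                         fitted: dict[str, DistributionSpec],
                         rng: np.random.Generator) -> ParameterSet:
    """One joint parameter draw.

    Parameters are sampled independently, each from its fitted marginal, in
    a fixed (sorted) order so a given generator state maps to one draw.
    The progression probability on continued imatinib is an alias of the
    first-line metastatic progression probability, so it follows that
    parameter's draw (likewise the CIUP local/distant split follows the
    conditional local-recurrence draw) — unless the user has decoupled the
    base values, in which case it stays fixed.
    """
    for name in params.sampled_names():
        if name not in fitted:
            raise KeyError(f"no fitted distribution for {name!r}")
    draws = {name: float(fitted[name].sample(rng)) for name in sorted(fitted)}
    out = params.with_values(**draws)
    if params.p_prog_ciup == params.p_prog1_met and "p_prog1_met" in draws:
        out = out.with_value("p_prog_ciup", draws["p_prog1_met"])
    if (params.p_local_given_prog_ciup == params.p_local_given_rec
            and "p_local_given_rec" in draws):
        out = out.with_value("p_local_given_prog_ciup", draws["p_local_given_rec"])
    return out


@dataclass
class PsaResult:
    """Paired per-draw outcomes of a probabilistic sensitivity analysis."""

    n_draws: int
    seed: int
    samples: pd.DataFrame           # one row per draw, sampled values
    cost_uapr: np.ndarray
    qaly_uapr: np.ndarray
    cost_ciup: np.ndarray
    qaly_ciup: np.ndarray

    @property
    def delta_cost(self) -> np.ndarray:
        """Incremental cost, UAPR minus CIUP."""
        return self.cost_uapr - self.cost_ciup

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qaly_uapr - self.qaly_ciup

    def nmb(self, strategy: str, wtp: float) -> np.ndarray:
        if strategy == "UAPR":
            return wtp * self.qaly_uapr - self.cost_uapr
        if strategy == "CIUP":
            return wtp * self.qaly_ciup - self.cost_ciup
        raise KeyError(strategy)

    def prob_cost_effective(self, strategy: str, wtp: float) -> float:
        """Fraction of draws where ``strategy`` has the higher NMB
        (ties to the cheaper strategy)."""
        nmb_u = self.nmb("UAPR", wtp)
        nmb_c = self.nmb("CIUP", wtp)
        uapr_wins = (nmb_u > nmb_c) | ((nmb_u == nmb_c)
                                       & (self.cost_uapr <= self.cost_ciup))
        p_uapr = float(np.mean(uapr_wins))
        if strategy == "UAPR":
            return p_uapr
        if strategy == "CIUP":
            return 1.0 - p_uapr
        raise KeyError(strategy)

    def to_frame(self, wtp: float = 50000.0) -> pd.DataFrame:
        nmb_u = self.nmb("UAPR", wtp)
        nmb_c = self.nmb("CIUP", wtp)
        return pd.DataFrame({
            "draw": np.arange(self.n_draws),
            "cost_UAPR": self.cost_uapr,
            "qalys_UAPR": self.qaly_uapr,
            "cost_CIUP": self.cost_ciup,
            "qalys_CIUP": self.qaly_ciup,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "nmb_winner": np.where(
                (nmb_u > nmb_c) | ((nmb_u == nmb_c)
                                   & (self.cost_uapr <= self.cost_ciup)),
                "UAPR", "CIUP"),
        })


def run_psa(n_draws: int, seed: int, params: ParameterSet,
            life_table: LifeTable) -> PsaResult:
    """Monte Carlo propagation: ``n_draws`` joint draws, both strategies.

    Reproducible: the same ``(n_draws, seed, params)`` give bit-identical
    results, and draw ``i`` does not depend on ``n_draws``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    fitted = fit_psa_distributions(params)
    space_u = build_state_space("UAPR", params)
    space_c = build_state_space("CIUP", params)
    cost_u = np.empty(n_draws)
    qaly_u = np.empty(n_draws)
    cost_c = np.empty(n_draws)
    qaly_c = np.empty(n_draws)
    rows = []
    sampled = sorted(fitted)
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        try:
            ps = sample_parameter_set(params, fitted, rng)
            u = run_cohort("UAPR", ps, life_table, space=space_u)
            c = run_cohort("CIUP", ps, life_table, space=space_c)
        except Exception as exc:
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        cost_u[i], qaly_u[i] = u.cost, u.qalys
        cost_c[i], qaly_c[i] = c.cost, c.qalys
        rows.append([getattr(ps, name) for name in sampled])
    samples = pd.DataFrame(rows, columns=sampled)
    return PsaResult(n_draws, seed, samples, cost_u, qaly_u, cost_c, qaly_c)


@dataclass
class CeacCurve:
    """Cost-effectiveness acceptability curve on an ordered WTP grid."""

    wtp: np.ndarray
    p_uapr: np.ndarray
    p_ciup: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wtp": self.wtp,
            "p_cost_effective_UAPR": self.p_uapr,
            "p_cost_effective_CIUP": self.p_ciup,
        })


def ceac_curve(psa: PsaResult, wtp_grid=None) -> CeacCurve:
    """Acceptability curve: per WTP, the fraction of draws each strategy
    has the higher NMB (ties split to the cheaper strategy)."""
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("WTP grid must be non-negative and increasing")
    p_uapr = np.array([psa.prob_cost_effective("UAPR", w) for w in grid])
    return CeacCurve(grid, p_uapr, 1.0 - p_uapr)
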