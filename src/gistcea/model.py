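"""Markov cohort engine for the two treatment strategies.

The model follows a hypothetical cohort of 60-year-old rectal-GIST patients
who completed one year of neoadjuvant imatinib without progression, through
one of two strategies:

* **UAPR** — upfront abdominoperineal resection, two further years of
  adjuvant imatinib, surveillance thereafter.  A first local recurrence
  after adjuvant therapy is treated with salvage surgery plus three years
  of adjuvant imatinib (allowed once, encoded with tunnel states); distant
  or post-salvage recurrence enters the palliative pathway at first-line
  imatinib ("1st DR").
* **CIUP** — continued imatinib until progression.  Local progression is
  resected (APR, no further imatinib); a subsequent local recurrence gets
  salvage surgery only; distant progression or any later recurrence enters
  the palliative pathway directly at escalated-dose imatinib ("mets 1st
  PD") because first-line imatinib has already failed.

Both arms share the metastatic chain 1st DR -> mets 1st PD -> 2nd PD ->
3rd PD -> Dead, with disease death only after regorafenib failure.  In
every state the per-cycle death probability is the maximum of the
state-specific disease mortality and the age-specific background mortality;
the remaining transitions are scaled proportionally into the surviving
mass, keeping each row stochastic.

Cycles are annual and cycle 0 is undiscounted.  By default annual rewards
use the trapezoid (half-cycle-corrected) rule — half weight on the first
and last cycle boundaries, the convention of the decision-analytic software
this class of model is usually built in; setting
``half_cycle_correction=False`` credits each full year at the occupancy of
the cycle's start instead.  One-time surgery costs and the 0.5% operative
mortality are applied on entry into a surgical state; entry rewards earned
during the transition from cycle t to t+1 are discounted at cycle t+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    LifeTable,
    ParameterSet,
    background_mortality,
    derive_secondary,
    hard_violations,
)

__all__ = [
    "CohortTrace",
    "MarkovCohortModel",
    "RewardSchedule",
    "State",
    "StateSpace",
    "StrategyOutcome",
    "build_rewards",
    "build_state_space",
    "build_transition_matrix",
    "discount_factor",
    "run_cohort",
    "STRATEGIES",
]

STRATEGIES = ("UAPR", "CIUP")
DEAD_LABEL = "Dead"

_ROW_TOL = 1e-12
_MASS_TOL = 1e-10


@dataclass(frozen=True)
class State:
    """One expanded Markov state.

    ``label`` is the reporting label (one of the twelve published health
    states); tunnel-expanded states share a label.  ``tunnel`` numbers the
    year within a tunnel sequence (0 = not a tunnel year).
    """

    uid: str
    label: str
    strategy: str  # "UAPR" | "CIUP" | "shared"
    tunnel: int = 0
    absorbing: bool = False


@dataclass(frozen=True)
class StateSpace:
    strategy: str
    states: tuple[State, ...]

    def __post_init__(self) -> None:
        uids = [s.uid for s in self.states]
        if len(set(uids)) != len(uids):
            raise ValueError("state identifiers must be unique")
        absorbing = [s for s in self.states if s.absorbing]
        if len(absorbing) != 1:
            raise ValueError("state space needs exactly one absorbing state")

    def __len__(self) -> int:
        return len(self.states)

    def index(self, uid: str) -> int:
        for i, s in enumerate(self.states):
            if s.uid == uid:
                return i
        raise KeyError(uid)

    @property
    def dead_index(self) -> int:
        return next(i for i, s in enumerate(self.states) if s.absorbing)

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct reporting labels in state order."""
        seen: list[str] = []
        for s in self.states:
            if s.label not in seen:
                seen.append(s.label)
        return tuple(seen)


@dataclass(frozen=True)
class RewardSchedule:
    """Per-state rewards: annual utility and cost, plus one-time entry
    cost and entry (operative) mortality for surgical states."""

    utility: np.ndarray
    annual_cost: np.ndarray
    entry_cost: np.ndarray
    entry_mortality: np.ndarray

    def __post_init__(self) -> None:
        for name in ("utility", "annual_cost", "entry_cost", "entry_mortality"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.utility < 0) or np.any(self.utility > 1):
            raise ValueError("utilities must lie in [0, 1]")
        if np.any(self.annual_cost < 0) or np.any(self.entry_cost < 0):
            raise ValueError("costs must be non-negative")
        if np.any(self.entry_mortality < 0) or np.any(self.entry_mortality > 1):
            raise ValueError("entry mortality must lie in [0, 1]")


def build_state_space(strategy: str, params: ParameterSet) -> StateSpace:
    """Expanded state space for one strategy.

    Tunnel states implement the once-only salvage surgery: the salvage
    reporting state is expanded into one state per adjuvant year plus a
    terminal surveillance year that may self-loop.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    states: list[State] = []
    if strategy == "UAPR":
        n_adj = params.adjuvant_years_uapr
        for i in range(1, n_adj + 1):
            states.append(State(f"uapr_yr{i}", f"UAPR_Yr{i}", "UAPR", tunnel=i))
        plus = f"UAPR_Yr{n_adj + 1}+"
        states.append(State("uapr_surveillance", plus, "UAPR"))
        m = params.adjuvant_years_post_salvage
        slabel = f"Salvage Sx following LR1 post {plus}"
        for i in range(1, m + 1):
            states.append(State(f"salvage_uapr_yr{i}", slabel, "UAPR", tunnel=i))
        states.append(State("salvage_uapr_surveillance", slabel, "UAPR"))
    else:
        states.append(State("ciup", "CIUP", "CIUP"))
        states.append(State("apr_on_ciup", "APR following LR on CIUP", "CIUP"))
        slabel = "Salvage Sx following LR1 post CIUP"
        states.append(State("salvage_ciup_yr1", slabel, "CIUP", tunnel=1))
        states.append(State("salvage_ciup_surveillance", slabel, "CIUP"))
    states.append(State("first_dr", "1st DR", "shared"))
    states.append(State("mets_pd1", "Mets disease 1st PD", "shared"))
    states.append(State("mets_pd2", "Mets disease 2nd PD", "shared"))
    states.append(State("mets_pd3", "Mets disease 3rd PD", "shared"))
    states.append(State("dead", DEAD_LABEL, "shared", absorbing=True))
    return StateSpace(strategy, tuple(states))


def build_rewards(space: StateSpace, params: ParameterSet) -> RewardSchedule:
    """Reward schedule for a strategy state space.

    Drug costs by state: imatinib 400 mg while on adjuvant or continued
    imatinib and at first-line palliative therapy (1st DR); escalated
    imatinib (dose-proportional cost) at mets 1st PD; sunitinib at 2nd PD;
    regorafenib at 3rd PD.  Every alive state carries the annual follow-up
    cost.  Surgery costs and operative mortality attach to entry into the
    three surgical states.
    """
    d = derive_secondary(params)
    n = len(space)
    u = np.zeros(n)
    c = np.zeros(n)
    ec = np.zeros(n)
    em = np.zeros(n)
    imatinib = params.c_imatinib400
    fup = params.c_followup
    for i, s in enumerate(space.states):
        uid = s.uid
        if uid == "dead":
            continue
        if uid.startswith("uapr_yr"):
            u[i], c[i] = params.u_post_apr, imatinib + fup
            if uid == "uapr_yr1":
                ec[i], em[i] = params.c_apr, params.p_surgical_mortality
        elif uid == "uapr_surveillance":
            u[i], c[i] = params.u_post_apr, fup
        elif uid.startswith("salvage_uapr_yr"):
            u[i], c[i] = params.u_recurrence, imatinib + fup
            if s.tunnel == 1:
                ec[i], em[i] = params.c_salvage, params.p_surgical_mortality
        elif uid == "salvage_uapr_surveillance":
            u[i], c[i] = params.u_recurrence, fup
        elif uid == "ciup":
            u[i], c[i] = params.u_ciup, imatinib + fup
        elif uid == "apr_on_ciup":
            u[i], c[i] = params.u_post_apr, fup
            ec[i], em[i] = params.c_apr, params.p_surgical_mortality
        elif uid == "salvage_ciup_yr1":
            u[i], c[i] = params.u_recurrence, fup
            ec[i], em[i] = params.c_salvage, params.p_surgical_mortality
        elif uid == "salvage_ciup_surveillance":
            u[i], c[i] = params.u_recurrence, fup
        elif uid == "first_dr":
            u[i], c[i] = params.u_recurrence, imatinib + fup
        elif uid == "mets_pd1":
            u[i], c[i] = params.u_met_pd, d["c_imatinib800"] + fup
        elif uid == "mets_pd2":
            u[i], c[i] = params.u_met_pd, params.c_sunitinib + fup
        elif uid == "mets_pd3":
            u[i], c[i] = params.u_met_pd, params.c_regorafenib + fup
        else:  # pragma: no cover - construction and rewards move together
            raise ValueError(f"no rewards defined for state {uid!r}")
    return RewardSchedule(u, c, ec, em)


def discount_factor(cycle: int, rate: float) -> float:
    """Discount weight ``(1 + rate) ** -cycle``; cycle 0 is undiscounted."""
    if rate <= -1.0:
        raise ValueError("discount rate must exceed -1")
    return float((1.0 + rate) ** (-cycle))


def _fill_row(M: np.ndarray, i: int, idead: int, death: float,
              moves: Sequence[tuple[int, float]], stay: int) -> None:
    """Write one row: fixed death mass, event transitions scaled into the
    surviving mass, remainder to ``stay``."""
    surv = 1.0 - death
    M[i, idead] += death
    total = 0.0
    for j, p in moves:
        M[i, j] += p * surv
        total += p
    if total > 1.0 + 1e-12:
        raise ValueError(f"event probabilities exceed 1 in row {i}")
    M[i, stay] += (1.0 - total) * surv


def _transition_matrix(space: StateSpace, params: ParameterSet, cycle: int,
                       life_table: LifeTable) -> np.ndarray:
    d = derive_secondary(params)
    q = background_mortality(life_table, params.start_age + cycle)
    n = len(space)
    idx = {s.uid: i for i, s in enumerate(space.states)}
    idead = idx["dead"]
    M = np.zeros((n, n))
    p_rec = params.p_rec_post_apr

    if space.strategy == "UAPR":
        n_adj = params.adjuvant_years_uapr
        # adjuvant years: any progression (local or distant) -> mets 1st PD
        for i_yr in range(1, n_adj + 1):
            src = idx[f"uapr_yr{i_yr}"]
            nxt = (idx[f"uapr_yr{i_yr + 1}"] if i_yr < n_adj
                   else idx["uapr_surveillance"])
            _fill_row(M, src, idead, q, [(idx["mets_pd1"], p_rec)], nxt)
        # surveillance: local -> salvage tunnel, distant -> 1st DR
        _fill_row(M, idx["uapr_surveillance"], idead, q,
                  [(idx["salvage_uapr_yr1"], d["p_local_post_apr"]),
                   (idx["first_dr"], d["p_distant_post_apr"])],
                  idx["uapr_surveillance"])
        # salvage tunnel: any recurrence -> 1st DR, else advance
        m = params.adjuvant_years_post_salvage
        for t in range(1, m + 1):
            src = idx[f"salvage_uapr_yr{t}"]
            nxt = (idx[f"salvage_uapr_yr{t + 1}"] if t < m
                   else idx["salvage_uapr_surveillance"])
            _fill_row(M, src, idead, q, [(idx["first_dr"], p_rec)], nxt)
        _fill_row(M, idx["salvage_uapr_surveillance"], idead, q,
                  [(idx["first_dr"], p_rec)], idx["salvage_uapr_surveillance"])
    else:
        # continued imatinib: local progression -> APR, distant -> mets 1st PD
        _fill_row(M, idx["ciup"], idead, q,
                  [(idx["apr_on_ciup"], d["p_local_ciup"]),
                   (idx["mets_pd1"], d["p_distant_ciup"])],
                  idx["ciup"])
        # post-APR (no adjuvant): first local recurrence -> salvage (once),
        # distant -> mets 1st PD
        _fill_row(M, idx["apr_on_ciup"], idead, q,
                  [(idx["salvage_ciup_yr1"], p_rec * params.p_local_given_rec),
                   (idx["mets_pd1"], p_rec * (1.0 - params.p_local_given_rec))],
                  idx["apr_on_ciup"])
        _fill_row(M, idx["salvage_ciup_yr1"], idead, q,
                  [(idx["mets_pd1"], p_rec)], idx["salvage_ciup_surveillance"])
        _fill_row(M, idx["salvage_ciup_surveillance"], idead, q,
                  [(idx["mets_pd1"], p_rec)], idx["salvage_ciup_surveillance"])

    # shared palliative chain
    _fill_row(M, idx["first_dr"], idead, q,
              [(idx["mets_pd1"], params.p_prog1_met)], idx["first_dr"])
    _fill_row(M, idx["mets_pd1"], idead, q,
              [(idx["mets_pd2"], params.p_prog2_met)], idx["mets_pd1"])
    _fill_row(M, idx["mets_pd2"], idead, q,
              [(idx["mets_pd3"], params.p_prog3_met)], idx["mets_pd2"])
    # disease death only after regorafenib failure; max-of-mortalities rule
    _fill_row(M, idx["mets_pd3"], idead,
              max(params.p_death_post_regorafenib, q), [], idx["mets_pd3"])
    M[idead, idead] = 1.0

    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > _ROW_TOL) or np.any(M < 0):
        raise ValueError("transition matrix failed stochasticity check")
    return M


def build_transition_matrix(strategy: str, params: ParameterSet, cycle: int,
                            life_table: LifeTable,
                            space: StateSpace | None = None) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix at ``cycle``.

    Operative mortality on entry into surgical states is not encoded here;
    the cohort engine applies it to entry flows (see
    :class:`MarkovCohortModel`), keeping this matrix purely the disease /
    background-mortality process.
    """
    if space is None:
        space = build_state_space(strategy, params)
    return _transition_matrix(space, params, cycle, life_table)


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``
    (rows ``0 .. horizon``).  Increment arrays are indexed by the cycle at
    which the reward is discounted; entry rewards earned in the transition
    ``t -> t+1`` appear at index ``t+1``.
    """

    occupancy: np.ndarray
    cost_disc: np.ndarray
    qaly_disc: np.ndarray
    cost_undisc: np.ndarray
    qaly_undisc: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_disc.sum())

    def to_frame(self, space: StateSpace) -> pd.DataFrame:
        """Trace as a DataFrame with one column per reporting label."""
        cols: dict[str, np.ndarray] = {}
        for label in space.labels:
            sel = [i for i, s in enumerate(space.states) if s.label == label]
            cols[label] = self.occupancy[:, sel].sum(axis=1)
        df = pd.DataFrame(cols)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["cost_discounted"] = self.cost_disc
        df["qaly_discounted"] = self.qaly_disc
        df["cost_undiscounted"] = self.cost_undisc
        df["qaly_undiscounted"] = self.qaly_undisc
        return df


@dataclass
class StrategyOutcome:
    """Total discounted cost and QALYs for one strategy, with its trace."""

    strategy: str
    cost: float
    qalys: float
    trace: CohortTrace
    space: StateSpace

    def net_monetary_benefit(self, wtp: float) -> float:
        return wtp * self.qalys - self.cost

    def summary(self) -> str:
        lines = [
            f"Strategy: {self.strategy}",
            f"  total discounted cost : SGD {self.cost:,.0f}",
            f"  total discounted QALYs: {self.qalys:.2f}",
        ]
        return "\n".join(lines)


class MarkovCohortModel:
    """Expected-value cohort simulation of an annual-cycle Markov chain.

    Parameters
    ----------
    space : StateSpace
    transition_fn : callable
        ``transition_fn(cycle) -> (n, n)`` row-stochastic matrix.
    rewards : RewardSchedule
    horizon : int
        Number of one-year cycles.
    discount_rate : float
    entry_state : str
        uid of the state the full cohort starts in; its one-time entry cost
        and entry mortality are applied at cycle 0.
    strategy : str
        Name used in reporting.
    half_cycle_correction : bool
        Trapezoid weighting of annual rewards (half weight at cycles 0 and
        ``horizon``) when True; start-of-cycle crediting when False.
    """

    def __init__(self, space: StateSpace, transition_fn: Callable[[int], np.ndarray],
                 rewards: RewardSchedule, *, horizon: int, discount_rate: float,
                 entry_state: str, strategy: str | None = None,
                 half_cycle_correction: bool = False) -> None:
        self.space = space
        self.transition_fn = transition_fn
        self.rewards = rewards
        self.horizon = int(horizon)
        self.discount_rate = float(discount_rate)
        self.entry_index = space.index(entry_state)
        self.strategy = strategy or space.strategy
        self.half_cycle_correction = bool(half_cycle_correction)

    @classmethod
    def from_strategy(cls, strategy: str, params: ParameterSet,
                      life_table: LifeTable,
                      space: StateSpace | None = None) -> "MarkovCohortModel":
        bad = hard_violations(params)
        if bad:
            raise ValueError("invalid parameters: " + "; ".join(bad))
        lo, hi = life_table.span
        if lo > params.start_age or hi < params.start_age + params.horizon:
            raise ValueError(
                f"life table span [{lo}, {hi}] does not cover model ages "
                f"[{params.start_age}, {params.start_age + params.horizon}]")
        if space is None:
            space = build_state_space(strategy, params)
        rewards = build_rewards(space, params)
        entry = "uapr_yr1" if strategy == "UAPR" else "ciup"

        def transition_fn(cycle: int) -> np.ndarray:
            return _transition_matrix(space, params, cycle, life_table)

        return cls(space, transition_fn, rewards, horizon=params.horizon,
                   discount_rate=params.discount_rate, entry_state=entry,
                   strategy=strategy,
                   half_cycle_correction=params.half_cycle_correction)

    def run(self) -> StrategyOutcome:
        n = len(self.space)
        idead = self.space.dead_index
        H = self.horizon
        rw = self.rewards
        occupancy = np.zeros((H + 1, n))
        cost_d = np.zeros(H + 1)
        qaly_d = np.zeros(H + 1)
        cost_u = np.zeros(H + 1)
        qaly_u = np.zeros(H + 1)

        # initial entry: the whole cohort undergoes the entry event (cost
        # charged to everyone operated on, deaths moved before cycle 0)
        x = np.zeros(n)
        x[self.entry_index] = 1.0 - rw.entry_mortality[self.entry_index]
        x[idead] = rw.entry_mortality[self.entry_index]
        cost_d[0] += rw.entry_cost[self.entry_index]
        cost_u[0] += rw.entry_cost[self.entry_index]
        occupancy[0] = x

        # annual-reward weight per cycle boundary: trapezoid rule when
        # half-cycle corrected, start-of-cycle crediting otherwise
        weight = np.ones(H + 1)
        if self.half_cycle_correction:
            weight[0] = weight[H] = 0.5
        else:
            weight[H] = 0.0

        for t in range(H):
            df = discount_factor(t, self.discount_rate)
            annual_cost = float(x @ rw.annual_cost)
            annual_qaly = float(x @ rw.utility)
            cost_d[t] += weight[t] * df * annual_cost
            qaly_d[t] += weight[t] * df * annual_qaly
            cost_u[t] += weight[t] * annual_cost
            qaly_u[t] += weight[t] * annual_qaly

            M = self.transition_fn(t)
            if M.shape != (n, n):
                raise ValueError("transition matrix has wrong shape")
            if np.any(M < 0) or np.any(np.abs(M.sum(axis=1) - 1.0) > _ROW_TOL):
                raise ValueError("transition matrix failed stochasticity check")
            flow = x[:, None] * M
            entry_flow = flow.sum(axis=0) - np.diag(flow)
            x = x @ M
            # operative mortality on entry into surgical states
            extra_dead = rw.entry_mortality * entry_flow
            x = x - extra_dead
            x[idead] += extra_dead.sum()
            dfn = discount_factor(t + 1, self.discount_rate)
            entry_cost = float(entry_flow @ rw.entry_cost)
            cost_d[t + 1] += dfn * entry_cost
            cost_u[t + 1] += entry_cost
            if abs(x.sum() - 1.0) > _MASS_TOL:
                raise ValueError(f"cohort mass not conserved at cycle {t + 1}")
            occupancy[t + 1] = x

        if weight[H] > 0.0:
            df = discount_factor(H, self.discount_rate)
            cost_d[H] += weight[H] * df * float(x @ rw.annual_cost)
            qaly_d[H] += weight[H] * df * float(x @ rw.utility)
            cost_u[H] += weight[H] * float(x @ rw.annual_cost)
            qaly_u[H] += weight[H] * float(x @ rw.utility)

        trace = CohortTrace(occupancy, cost_d, qaly_d, cost_u, qaly_u)
        return StrategyOutcome(self.strategy, trace.total_cost,
                               trace.total_qalys, trace, self.space)


def run_cohort(strategy: str, params: ParameterSet, life_table: LifeTable,
               space: StateSpace | None = None) -> StrategyOutcome:
    """Run the full cohort simulation for one strategy (convenience)."""
    return MarkovCohortModel.from_strategy(strategy, params, life_table,
                                           space=space).run()
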